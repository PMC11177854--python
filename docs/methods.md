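# Methods

## Scope

`flashkin` models the first mechanically stimulated flash of bioluminescent
plankton as recorded by a flow-through bathyphotometer with an integrating
chamber and a 60 Hz PMT, and everything downstream of that record:
parameter extraction, descriptive/inferential statistics, and species
identification. It does not model shear-stress physics, multi-flash
exhaustion kinetics (TMSL), spectral properties, or the separation of
overlapping flashes from multiple organisms.

## The waveform model

A flash is a piecewise photon-rate curve over its above-threshold support
FD = RT + DT (time in ms from onset):

1. linear rise 0 → PI over RT (the peak is attained at the end of the rise);
2. optional plateau at PI of length p ≥ 0;
3. decay segment A: exponential with τ₁ = EF, so the curve passes through
   PI/e exactly EF after the plateau;
4. decay segment B: exponential with τ₂ = (DT − p − EF) / ln((PI/e)/T),
   so the curve reaches the detection threshold T exactly DT after the peak,
   where the flash ends.

The six FFKPs over-determine any single-exponential shape; this is the
minimal family that realizes all six definitions exactly where they are
mutually consistent. The plateau is the remaining degree of freedom and is
solved so the support integral equals FF-MSL; the integral is *linear* in p,
so the solve is closed-form (verified against adaptive quadrature in the
tests). When no p ∈ [0, DT − EF) reaches the requested FF-MSL the plateau is
dropped and a warning carrying the realized integral is attached.

Two consequences worth knowing:

- a plateau-topped flash *genuinely* crosses PI/e later than EF, so the
  extracted e-folding time of strongly plateaued species (the two
  *Pyrocystis*, *M. leidyi*) exceeds the library's nominal EF;
- when PI/e falls below the detection floor the EF anchor is unrealizable;
  the waveform degrades to a single decay reaching the floor at DT and is
  flagged, mirroring the extractor's EF = DT convention.

## Sampling model (what the generator emulates)

Per species the library stores mean and SD of each FFKP from single-organism
laboratory measurements. Marginals are moment-matched lognormals — every
measured FFKP distribution failed normality screening and all quantities are
positive (a zero-truncated normal family is available). Joint structure is
deliberately minimal, because the library carries no joint moments:

- **EF and DT are comonotone** (one shared latent normal). Both measure
  decay speed; the coupling preserves both printed means exactly *and*
  guarantees EF ≤ DT for every library entry. The alternative — redraw DT
  until it exceeds EF — inflates the DT mean by up to ~6% for fast-decay
  species, which would break moment recovery.
- **FD = RT + DT** by construction; RT and PI are independent of the rest.
- **FF-MSL = PI × L**, with L an effective emission duration (seconds)
  clamped into [0.5·EF/1000, FD/1000]. L is a mean-1 lognormal scaled by a
  per-species constant calibrated deterministically (Gauss–Hermite
  quadrature + Brent root find) so the post-clamp mean matches the printed
  FF-MSL mean whenever feasible; its CV is the residual needed for
  Var(PI·L) to match the printed FF-MSL SD (zero when the printed FF-MSL CV
  is below the PI CV). Rationale: a flash's photon total is dominated by its
  peak brightness times how long it effectively stays near it, which is why
  measured PI and FF-MSL correlate at r ≈ 0.998 across species. Sampling
  FF-MSL independently of PI provably caps the pooled correlation near
  0.74 and cannot reproduce the measured structure.

**Feasibility-limited entries.** For five of the seven species the printed
FF-MSL mean exceeds the hard bound E[PI]·E[FD]/1000 (a flash cannot emit
more photons than its peak rate sustained over its entire duration). These
entries are flagged; the printed value is stored untouched and the simulator
emits the brightest feasible flashes (L at the FD cap) instead of silently
rescaling published numbers. For flagged species the simulated FF-MSL mean
is therefore *below* the printed one by construction.

## Acquisition model

Instantaneous sampling of the summed waveforms on the 1/60 s grid; one
multiplicative collection-efficiency factor per flash drawn uniformly from
[0.7, 1] (organism position/orientation in the integrating cavity changes
PMT collection by up to 30%; timing is unaffected); additive Gaussian
dark-count noise (SD 2×10⁶ photons/s) truncated at zero; rounding to the
quantization step (5×10⁶ photons/s), which produces the characteristic
"broken" decay of dim species whose peaks sit near the noise floor.
Simulated traces are in raw instrument units — library intensities are
divided by the 2.5× calibration factor before synthesis — so extraction
with the default configuration round-trips to library units. The generator
rejects draws with PI ≤ e·T (raw) so the PI/e anchor is resolvable.

## Extraction conventions

Flashes are maximal runs of samples strictly above the threshold; runs
shorter than 2 samples are discarded as noise spikes. Boundaries are linear
interpolations to the threshold crossing between the bracketing sub-/supra-
threshold samples (edge runs use the edge sample time). The peak is the
first maximal sample; EF is the first post-peak interpolated PI/e crossing
(EF = DT, flagged, if none exists); FF-MSL is the trapezoidal integral with
threshold-valued endpoints (a rectangle sum is available for comparison
with legacy processing). DT is measured to the threshold crossing, not to
zero — the stated detection floor operationalizes "baseline". Intensities
are multiplied by the calibration factor inside extraction.

Discretization behaviour, measured on noiseless mixed cohorts: median
absolute timing errors are below one sample period (16.7 ms) with median
signed errors within half a period. Mean (not median) extracted RT of
heavily plateaued species is biased high by ~0.5–1 sample because the
sub-threshold neighbor of a sharp onset sits at zero (early start) and the
first maximal sample of a flat top trails the true peak; under the default
noisy configuration, near-ties along a plateau move the detected peak
further into the plateau. This is inherent to the stated peak/boundary
definitions, not an implementation artifact.

## Statistics

Percentile bootstrap (500 resamples, 95%) of the sample mean — the minimal
reading of "non-parametric bootstrapping"; BCa was deliberately not used.
An exhaustive enumeration mode exists for tiny n. Pairwise species
comparisons use two-group tie-corrected Kruskal–Wallis (asymptotically a
Mann–Whitney; ties are real because intensities are quantized); the k-group
omnibus test is exposed too. No multiplicity correction by default, matching
the raw p < 0.05 reading of the field analysis; Holm is available. Species
with fewer than 3 records are skipped with a warning. Degenerate inputs:
all-identical pooled values give H = 0, p = 1; Shapiro–Wilk raises on
constant input rather than returning NaN.

## Classification

"Factor analysis" is operationalized as greedy correlation-redundancy
pruning in the fixed priority order (PI, FD, RT, EF, DT, FF-MSL) at
|r| > 0.95 on log values; on simulated cohorts this reproducibly drops
FF-MSL (collinear with PI) and DT (collinear with FD), leaving the
published four-feature set. Features are log₁₀-transformed (intensities
span six orders of magnitude across species; times are right-skewed) and
z-standardized on training data; raw-scale mode is retained for sensitivity
analysis. Priors are uniform — field abundances are unknown. Clustering of
species mean signatures uses z-standardized log₁₀ means, Euclidean
distance, average linkage, with rows sorted by species name for
deterministic ties. LDA is fitted from the between/within generalized
eigenproblem with a 10⁻⁸ ridge fallback (flagged) if the pooled covariance
is not positive definite; posterior ties break alphabetically. The
validation experiment uses a stratified 70/30 split.

## What a green test does (and does not) establish

The generator reproduces the *marginal moments* of the reference species
library, the instrument's discretization/noise phenomenology, and the
PI–FF-MSL coupling. It does not emulate: within-species correlations among
timing parameters beyond EF–DT, body-size and physiological-state
covariates (the dominant source of ctenophore scatter in real data),
pre-stimulation light loss at the instrument intake, multiple flash forms
per species, or measurement outliers. Synthetic cohorts are therefore
somewhat *more* separable than live-organism data: the 25-replicate
discriminant experiment averages ~85% species accuracy versus the ~73%
observed in the field (genus accuracy ~89% vs 82%; LD1+LD2 ≈ 99.6% vs
99.36% are close). The printed PI SD of *P. noctiluca* (3.7×10⁸ on a
1.8×10¹⁰ mean, CV ≈ 2%) contributes: it makes that species nearly
noiseless in log-PI. It is stored as printed.

## Numerical choices

- Lognormal moment match: σ² = ln(1 + (SD/mean)²), exact; truncated-normal
  family uses naive truncation of N(mean, SD) at 0 (adequate at CV ≪ 1).
- FF-MSL scale calibration: 25-node Gauss–Hermite product grid over
  (RT, DT, ε), Brent root find to xtol 10⁻¹²; deterministic, cached per
  entry.
- Plateau solve: closed form from the linearity of the integral in p.
- Grid regularity: relative tolerance 10⁻⁶ on sample spacing; trace CSVs
  store time to 9 decimal places so round trips preserve regularity.
- Seeds: a single `numpy` Generator drives each simulation; identical
  (library, spec, config, seed) reruns are bit-identical.
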