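"""Simulate bathyphotometer traces for two species and extract their FFKPs.

Builds ten single-flash 60 Hz traces per species from the built-in library,
runs the first-flash extractor, and prints extracted vs ground-truth kinetic
parameters for the first few flashes. Timing parameters should round-trip to
within about one sample period (16.7 ms); intensities carry the up-to-30%
collection-efficiency jitter of the integrating cavity.
"""

import flashkin as fk

library = fk.default_library()
spec = [("Pyrocystis fusiformis", 10), ("Lingulodinium polyedra", 10)]
traces, truth = fk.simulate_cohort(spec, library, fk.AcquisitionConfig(), seed=1)
records = fk.extract_first_flash(traces)

print(f"{len(traces)} traces simulated, {len(records)} flashes extracted\n")
merged = records.merge(truth, on="trace_id", suffixes=("_est", "_true"))
cols = ["trace_id", "rt_ms_est", "rt_ms_true", "ef_ms_est", "ef_ms_true",
        "pi_photons_s_est", "pi_photons_s_true"]
print(merged[cols].head(6).to_string(index=False, float_format="%.3g"))
print(
    "\nTiming parameters track the simulated truth to within the 60 Hz "
    "discretization, except that flat-topped (plateau) flashes push the "
    "measured e-folding time past the nominal decay constant — the PI/e "
    "crossing genuinely happens later. Extracted peak intensity sits below "
    "truth because each organism's light is partially lost to cavity "
    "geometry (collection jitter)."
)
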