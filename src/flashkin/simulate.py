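"""Ground-truthed synthetic flash cohorts.

Sampling model
--------------
Marginals for RT, EF, DT and PI are moment-matched lognormals (the printed
FFKP distributions are positive and uniformly non-normal; a zero-truncated
normal family is available as an option). EF and DT share a single latent
standard normal (comonotone coupling): both parameters measure how fast the
flash decays, and the shared latent preserves both printed means exactly
while guaranteeing EF <= DT for every library entry (an independent-redraw
scheme would inflate the DT mean by several percent for fast-decay species).
RT and PI are independent of everything else. FD = RT + DT by construction.

FF-MSL is generated as PI times an effective emission duration
``L = clamp(L0 * eps, 0.5 * EF / 1000, FD / 1000)`` (seconds): a flash's
photon total is overwhelmingly set by how bright its peak is and how long it
effectively stays near it, which is why measured PI and FF-MSL correlate at
r ~ 0.998 across species. ``eps`` is a mean-1 lognormal whose CV is the
residual needed for Var(PI * L) to match the printed FF-MSL SD (zero when
the printed FF-MSL CV is below the PI CV), and the scale ``L0`` is
calibrated deterministically (Gauss-Hermite quadrature + root find) so the
post-clamp mean matches the printed FF-MSL mean whenever that mean is
feasible. Entries whose printed FF-MSL mean exceeds the physical bound
E[PI] * E[FD] / 1000 are flagged ``feasibility_limited``; for them every
draw sits at the clamp and the realized mean is the brightest feasible one.
"""

from __future__ import annotations

import math
from dataclasses import replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._moments import from_z, lognormal_mu_sigma
from .acquisition import AcquisitionConfig, PMTTrace, acquire_trace
from .library import SpeciesEntry, SpeciesLibrary, default_library
from .waveform import FlashParams, build_waveform

_E = math.e


# --------------------------------------------------------------------------
# FF-MSL effective-duration calibration
# --------------------------------------------------------------------------

def _residual_cv(entry_cv_pi: float, entry_cv_ff: float) -> float:
    """CV of the multiplicative duration noise so Var(PI*L) matches the table."""
    num = 1.0 + entry_cv_ff**2
    den = 1.0 + entry_cv_pi**2
    return math.sqrt(max(0.0, num / den - 1.0))


@lru_cache(maxsize=128)
def _ffmsl_scale(key: tuple) -> tuple[float, float, bool]:
    """Solve for (L0, cv_eps, limited) from an entry's moment tuple.

    Deterministic: expectation of the clamped duration is evaluated on a
    Gauss-Hermite product grid over (RT, DT, eps).
    """
    (rt_m, rt_s, dt_m, dt_s, pi_m, pi_s, ff_m, ff_s, family) = key
    ratio = ff_m / pi_m  # target mean effective duration, seconds
    cv_eps = _residual_cv(pi_s / pi_m, ff_s / ff_m)

    nodes, weights = np.polynomial.hermite_e.hermegauss(25)
    weights = weights / weights.sum()
    rt = from_z(nodes, rt_m, rt_s, family)[:, None, None]
    dt = from_z(nodes, dt_m, dt_s, family)[None, :, None]
    eps = from_z(nodes, 1.0, cv_eps, "lognormal")[None, None, :]
    w = (
        weights[:, None, None]
        * weights[None, :, None]
        * weights[None, None, :]
    )
    cap = (rt + dt) / 1000.0  # FD in seconds

    def clamped_mean(l0: float) -> float:
        return float(np.sum(w * np.minimum(l0 * eps, cap)))

    cap_mean = float(np.sum(w * cap))
    if ratio >= cap_mean * (1.0 - 1e-9):
        return math.inf, cv_eps, True
    lo, hi = 1e-12, ratio
    while clamped_mean(hi) < ratio:
        hi *= 2.0
    l0 = brentq(lambda v: clamped_mean(v) - ratio, lo, hi, xtol=1e-12)
    return float(l0), cv_eps, False


def _entry_key(entry: SpeciesEntry) -> tuple:
    m, s = entry.means, entry.sds
    return (
        m["rt"], s["rt"], m["dt"], s["dt"],
        m["pi"], s["pi"], m["ffmsl"], s["ffmsl"],
        entry.distribution_family,
    )


# --------------------------------------------------------------------------
# Parameter sampling
# --------------------------------------------------------------------------

def sample_flash_params(
    entry: SpeciesEntry,
    n: int,
    rng: np.random.Generator,
    min_pi: float = 0.0,
    max_retries: int = 100,
) -> list[FlashParams]:
    """Draw ``n`` ground-truth flash parameter tuples for one species."""
    if n < 1:
        raise ValueError("n must be >= 1")
    entry.validate()
    m, s, fam = entry.means, entry.sds, entry.distribution_family

    rt = from_z(rng.standard_normal(n), m["rt"], s["rt"], fam)

    # shared latent for the two decay-speed parameters
    z = rng.standard_normal(n)
    ef = from_z(z, m["ef"], s["ef"], fam)
    dt = from_z(z, m["dt"], s["dt"], fam)
    for attempt in range(max_retries + 1):
        bad = ~(dt > ef)
        if not bad.any():
            break
        if attempt == max_retries:
            raise RuntimeError(
                f"{entry.species_name}: could not draw DT > EF after "
                f"{max_retries} retries"
            )
        z_new = rng.standard_normal(int(bad.sum()))
        ef[bad] = from_z(z_new, m["ef"], s["ef"], fam)
        dt[bad] = from_z(z_new, m["dt"], s["dt"], fam)

    pi = from_z(rng.standard_normal(n), m["pi"], s["pi"], fam)
    for attempt in range(max_retries + 1):
        bad = pi <= min_pi
        if not bad.any():
            break
        if attempt == max_retries:
            raise RuntimeError(
                f"{entry.species_name}: PI stuck below floor {min_pi:g} after "
                f"{max_retries} retries"
            )
        pi[bad] = from_z(
            rng.standard_normal(int(bad.sum())), m["pi"], s["pi"], fam
        )

    fd = rt + dt

    l0, cv_eps, limited = _ffmsl_scale(_entry_key(entry))
    if cv_eps > 0:
        eps = from_z(rng.standard_normal(n), 1.0, cv_eps, "lognormal")
    else:
        eps = np.ones(n)
    if math.isinf(l0):
        dur = fd / 1000.0
    else:
        dur = np.minimum(l0 * eps, fd / 1000.0)
    dur = np.maximum(dur, 0.5 * ef / 1000.0)
    ffmsl = pi * dur

    return [
        FlashParams(
            rt_ms=float(rt[i]), dt_ms=float(dt[i]), fd_ms=float(fd[i]),
            ef_ms=float(ef[i]), pi=float(pi[i]), ffmsl=float(ffmsl[i]),
            species_truth=entry.species_name,
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(
    spec: Sequence[tuple[str, int]],
    library: Optional[SpeciesLibrary] = None,
    config: Optional[AcquisitionConfig] = None,
    seed: int = 0,
) -> tuple[list[PMTTrace], pd.DataFrame]:
    """One single-flash trace per requested organism, plus a truth table.

    Traces are synthesized in raw instrument units (library intensities are
    divided by the calibration factor), so running the extractor with the
    same config round-trips to library units. Onsets are uniform in
    [0.5, trace_length - FD - 0.5] s. Fully reproducible from ``seed``.
    """
    library = library if library is not None else default_library()
    config = config if config is not None else AcquisitionConfig()
    config.validate()
    for name, _ in spec:
        if name not in library.species:
            raise KeyError(f"unknown species: {name}")

    rng = np.random.default_rng(seed)
    scale = 1.0 / config.calibration_factor
    # only emit flashes whose PI/e anchor clears the detection floor
    min_pi = _E * config.detection_threshold * config.calibration_factor

    traces: list[PMTTrace] = []
    rows: list[dict] = []
    idx = 0
    for name, n in spec:
        if n == 0:
            continue
        entry = library[name]
        params_list = sample_flash_params(entry, n, rng, min_pi=min_pi)
        for params in params_list:
            raw = params.scaled(scale)
            wf = build_waveform(raw, config.detection_threshold)
            fd_s = wf.duration_ms / 1000.0
            lo = 0.5
            hi = max(lo, config.trace_length_s - fd_s - 0.5)
            onset = float(rng.uniform(lo, hi)) if hi > lo else lo
            trace_id = f"t{idx:04d}"
            trace = acquire_trace(
                [(wf, onset)], config, rng,
                trace_id=trace_id, species_truth=name,
            )
            traces.append(trace)
            rows.append(
                {
                    "trace_id": trace_id,
                    "species": name,
                    "onset_s": onset,
                    "rt_ms": params.rt_ms,
                    "dt_ms": params.dt_ms,
                    "fd_ms": params.fd_ms,
                    "ef_ms": params.ef_ms,
                    "pi_photons_s": params.pi,
                    "ffmsl_photons": params.ffmsl,
                    "plateau_ms": wf.plateau_ms,
                    "waveform_warnings": ";".join(wf.warnings),
                }
            )
            idx += 1

    truth = pd.DataFrame(
        rows,
        columns=[
            "trace_id", "species", "onset_s", "rt_ms", "dt_ms", "fd_ms",
            "ef_ms", "pi_photons_s", "ffmsl_photons", "plateau_ms",
            "waveform_warnings",
        ],
    )
    return traces, truth
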