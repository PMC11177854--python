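"""Continuous first-flash waveform model.

A flash is a piecewise photon-rate curve anchored exactly at the field's
kinetic-parameter definitions (time t in ms from flash onset):

* linear rise from 0 to PI over RT;
* optional plateau at PI of length p >= 0;
* decay segment A: exponential with time constant tau1 = EF, so the curve
  passes through PI/e exactly EF after the plateau ends;
* decay segment B: exponential with time constant
  tau2 = (DT - p - EF) / ln((PI/e)/threshold), so the curve reaches the
  detection threshold exactly DT after the peak; the flash ends there.

The plateau length is the one degree of freedom left by the six parameters
and is solved so the integral over the flash support equals FF-MSL. The
integral is linear in p, so the solve is closed-form; when no
p in [0, DT - EF) can realize the requested FF-MSL the plateau is dropped
(p = 0) and a feasibility warning carrying the realized integral is attached.

Table-style parameter sets are over-determined under any single-exponential
decay; this two-segment construction is the minimal shape that realizes all
six definitions simultaneously where they are mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

_E = math.e


@dataclass
class FlashParams:
    """Ground-truth six-parameter description of a single flash.

    Times in ms, ``pi`` in photons/s, ``ffmsl`` in photons/flash.
    """

    rt_ms: float
    dt_ms: float
    fd_ms: float
    ef_ms: float
    pi: float
    ffmsl: float
    species_truth: str = ""

    def validate(self) -> None:
        for name in ("rt_ms", "dt_ms", "fd_ms", "ef_ms", "pi", "ffmsl"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(self.fd_ms - (self.rt_ms + self.dt_ms)) > 1e-6:
            raise ValueError("FD must equal RT + DT")
        if self.ef_ms > self.dt_ms:
            raise ValueError("EF must not exceed DT")
        if self.ffmsl > self.pi * self.fd_ms / 1000.0 * (1 + 1e-9):
            raise ValueError("FF-MSL cannot exceed PI * FD (peak times duration)")

    def scaled(self, factor: float) -> "FlashParams":
        """Same flash with intensities multiplied by ``factor`` (timing fixed)."""
        return replace(self, pi=self.pi * factor, ffmsl=self.ffmsl * factor)


@dataclass
class Waveform:
    """Piecewise evaluator for one flash; time argument in seconds from onset."""

    params: FlashParams
    threshold: float
    plateau_ms: float
    tau1_ms: float
    tau2_ms: float
    decay_a_ms: float  # span of the first decay segment (EF, normally)
    warnings: tuple[str, ...] = ()

    @property
    def duration_ms(self) -> float:
        """Above-threshold support: RT + DT = FD."""
        return self.params.rt_ms + self.params.dt_ms

    def __call__(self, t_s):
        """Photon rate (photons/s) at time(s) ``t_s`` seconds after onset."""
        p = self.params
        t = np.asarray(t_s, dtype=float) * 1000.0  # ms
        out = np.zeros_like(t)

        rise_end = p.rt_ms
        plat_end = rise_end + self.plateau_ms
        a_end = plat_end + self.decay_a_ms
        end = rise_end + p.dt_ms

        m = (t >= 0) & (t < rise_end)
        out[m] = p.pi * t[m] / p.rt_ms
        m = (t >= rise_end) & (t < plat_end)
        out[m] = p.pi
        m = (t >= plat_end) & (t < a_end)
        out[m] = p.pi * np.exp(-(t[m] - plat_end) / self.tau1_ms)
        if self.tau2_ms > 0:
            m = (t >= a_end) & (t <= end)
            out[m] = (p.pi / _E) * np.exp(-(t[m] - a_end) / self.tau2_ms)
        return out if out.ndim else float(out)

    def integral_photons(self) -> float:
        """Closed-form integral of the waveform over its support (photons)."""
        p = self.params
        rise = p.pi * p.rt_ms / 2.0
        plat = p.pi * self.plateau_ms
        seg_a = p.pi * self.tau1_ms * (1.0 - math.exp(-self.decay_a_ms / self.tau1_ms))
        if self.tau2_ms > 0:
            seg_b = self.tau2_ms * (p.pi / _E - self.threshold)
        else:
            seg_b = 0.0
        return (rise + plat + seg_a + seg_b) / 1000.0

    def realized_params(self) -> FlashParams:
        """FFKPs the continuous waveform actually encodes.

        RT/DT/FD equal the requested values by construction; the realized
        e-folding time is plateau + EF (first PI/e crossing measured from the
        peak; DT when the PI/e level sits under the detection floor) and the
        realized FF-MSL is the achieved integral, which differs from the
        requested one only when a feasibility warning is attached.
        """
        p = self.params
        if "ef_below_threshold" in self.warnings:
            ef = p.dt_ms
        else:
            ef = self.plateau_ms + self.decay_a_ms
        return replace(p, ef_ms=ef, ffmsl=self.integral_photons())


def build_waveform(params: FlashParams, threshold: float) -> Waveform:
    """Construct the piecewise waveform realizing ``params`` above ``threshold``."""
    params.validate()
    p = params
    if p.pi <= threshold:
        raise ValueError("flash below detection floor (PI <= threshold)")
    if p.dt_ms <= p.ef_ms:
        raise ValueError("DT must exceed EF")

    warnings: list[str] = []
    pi_e = p.pi / _E
    if pi_e <= threshold:
        # e-folding level is under the detection floor: single decay from PI
        # to threshold over DT; the EF anchor cannot be realized.
        tau1 = p.dt_ms / math.log(p.pi / threshold)
        return Waveform(
            p, threshold, 0.0, tau1, 0.0, p.dt_ms, ("ef_below_threshold",)
        )

    log_ratio = math.log(pi_e / threshold)

    def make(plateau: float) -> Waveform:
        tau2 = (p.dt_ms - plateau - p.ef_ms) / log_ratio
        return Waveform(
            p, threshold, plateau, p.ef_ms, tau2, p.ef_ms, tuple(warnings)
        )

    # integral is linear in the plateau length: I(p*) = i0 + slope * p*
    i0 = make(0.0).integral_photons()
    slope = (p.pi - (pi_e - threshold) / log_ratio) / 1000.0  # photons per ms
    p_max = p.dt_ms - p.ef_ms
    plateau = (p.ffmsl - i0) / slope
    if plateau < 0.0 or plateau >= p_max:
        plateau = 0.0
        wf = make(0.0)
        warnings.append(f"ffmsl_unreachable:realized={wf.integral_photons():.6g}")
        return make(0.0)
    return make(plateau)
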