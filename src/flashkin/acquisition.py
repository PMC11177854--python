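"""Bathyphotometer acquisition model: 60 Hz PMT sampling of flash waveforms.

Emulates how a flow-through bathyphotometer turns continuous photon-rate
waveforms into a discrete trace: instantaneous sampling on a regular grid,
one multiplicative collection-efficiency factor per flash (the organism's
position and orientation inside the integrating cavity change how much of
its light reaches the PMT, observed to vary by up to 30%), additive
dark-count noise truncated at zero, and quantization of the digitized
photon-rate values, which produces the characteristic "broken" decay steps
on flashes whose peaks sit close to the noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

from .waveform import FlashParams, Waveform


@dataclass
class AcquisitionConfig:
    """Instrument/acquisition settings, all in raw (uncalibrated) units."""

    sampling_rate_hz: float = 60.0
    detection_threshold: float = 1.5e7  # photons/s, noise-filtering floor
    baseline_mean: float = 0.0
    baseline_sd: float = 2e6
    quantization_step: float = 5e6  # photons/s per count; 0 disables
    collection_jitter_max: float = 0.30  # fraction; 0 disables
    calibration_factor: float = 2.5  # radiometric correction applied downstream
    trace_length_s: float = 10.0  # residence time in the mixing chamber
    rng_seed: Optional[int] = None

    def validate(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not self.calibration_factor > 0:
            raise ValueError("calibration_factor must be > 0")
        if not (0 <= self.collection_jitter_max < 1):
            raise ValueError("collection_jitter_max must be in [0, 1)")
        if self.trace_length_s <= 0:
            raise ValueError("trace_length_s must be > 0")

    @classmethod
    def noiseless(cls, **overrides) -> "AcquisitionConfig":
        """High-SNR configuration: no noise, no quantization, no jitter."""
        cfg = cls(baseline_sd=0.0, quantization_step=0.0, collection_jitter_max=0.0)
        return replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PMTTrace:
    """Regularly sampled photon-rate series with acquisition metadata."""

    times: np.ndarray  # seconds, regular grid from 0
    values: np.ndarray  # photons/s, non-negative, raw instrument units
    config: AcquisitionConfig
    trace_id: str = ""
    species_truth: Optional[str] = None
    truth: Optional[list[FlashParams]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.config.sampling_rate_hz

    def __len__(self) -> int:
        return len(self.times)


def sample_grid(config: AcquisitionConfig) -> np.ndarray:
    n = int(round(config.trace_length_s * config.sampling_rate_hz))
    return np.arange(n) / config.sampling_rate_hz


def acquire_trace(
    waveforms: Sequence[tuple[Waveform, float]],
    config: AcquisitionConfig,
    rng: np.random.Generator,
    trace_id: str = "",
    species_truth: Optional[str] = None,
) -> PMTTrace:
    """Sample the sum of ``(waveform, onset_s)`` flashes on the PMT grid.

    Each flash gets one collection-efficiency factor drawn uniformly from
    [1 - jitter_max, 1]; an empty waveform list yields a pure-noise trace.
    """
    config.validate()
    times = sample_grid(config)
    for _, onset in waveforms:
        if not (0 <= onset < config.trace_length_s):
            raise ValueError(f"onset {onset} outside [0, trace_length)")

    values = np.full(times.shape, float(config.baseline_mean))
    truth: list[FlashParams] = []
    for wf, onset in waveforms:
        if config.collection_jitter_max > 0:
            eff = rng.uniform(1.0 - config.collection_jitter_max, 1.0)
        else:
            eff = 1.0
        values += eff * wf(times - onset)
        truth.append(wf.realized_params())

    if config.baseline_sd > 0:
        values = values + rng.normal(0.0, config.baseline_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    if config.quantization_step > 0:
        step = config.quantization_step
        values = np.round(values / step) * step

    return PMTTrace(
        times=times,
        values=values,
        config=config,
        trace_id=trace_id,
        species_truth=species_truth,
        truth=truth or None,
    )
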