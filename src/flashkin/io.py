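"""Trace/record file formats, run configuration and the pipeline driver.

Trace files are plain CSV with a ``time_s,photons_per_s`` header preceded by
``#``-prefixed metadata lines (``# key=json-value``). Record tables use the
flash-record column layout. All writers emit locale-independent decimal
points and fixed column orders: scientific notation for intensities,
fixed-point ms for times, so reruns of the same configuration are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionConfig, PMTTrace
from .extract import RECORD_COLUMNS, extract_first_flash
from .library import SpeciesLibrary, default_library

logger = logging.getLogger("flashkin")

_TRACE_HEADER = "time_s,photons_per_s"


def write_trace(trace: PMTTrace, path: str | Path) -> None:
    lines = []
    meta = {
        "trace_id": trace.trace_id,
        "species_truth": trace.species_truth,
        "config": trace.config.to_dict(),
    }
    for key, value in meta.items():
        lines.append(f"# {key}={json.dumps(value)}")
    lines.append(_TRACE_HEADER)
    for t, v in zip(trace.times, trace.values):
        lines.append(f"{t:.9f},{v:.6e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> PMTTrace:
    """Parse a trace CSV; validates grid regularity (rtol 1e-6)."""
    text = Path(path).read_text()
    meta: dict = {}
    times: list[float] = []
    values: list[float] = []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                try:
                    meta[key.strip()] = json.loads(raw)
                except json.JSONDecodeError:
                    meta[key.strip()] = raw
            continue
        if not header_seen:
            if line != _TRACE_HEADER:
                raise ValueError("unrecognized trace format (missing header)")
            header_seen = True
            continue
        t_str, _, v_str = line.partition(",")
        times.append(float(t_str))
        values.append(float(v_str))
    if not header_seen or not times:
        raise ValueError("unrecognized trace format (empty file)")

    t = np.asarray(times)
    diffs = np.diff(t)
    if len(diffs):
        bad = np.nonzero(np.abs(diffs - diffs[0]) > 1e-6 * abs(diffs[0]))[0]
        if bad.size:
            raise ValueError(f"non-uniform sampling at index {int(bad[0]) + 1}")

    cfg_dict = meta.get("config")
    config = AcquisitionConfig(**cfg_dict) if cfg_dict else AcquisitionConfig()
    return PMTTrace(
        times=t,
        values=np.asarray(values),
        config=config,
        trace_id=meta.get("trace_id", Path(path).stem) or Path(path).stem,
        species_truth=meta.get("species_truth"),
    )


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Flash-record CSV with the canonical column order and formats."""
    df = records[RECORD_COLUMNS].copy()
    for col in ("pi_photons_s", "ffmsl_photons"):
        df[col] = df[col].map(lambda v: f"{v:.6e}")
    for col in ("rt_ms", "dt_ms", "fd_ms", "ef_ms"):
        df[col] = df[col].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"flags": str}, keep_default_na=False)
    for col in ("pi_photons_s", "rt_ms", "dt_ms", "fd_ms", "ef_ms",
                "ffmsl_photons"):
        df[col] = df[col].astype(float)
    df["calibrated"] = df["calibrated"].astype(bool)
    return df


@dataclass
class RunConfig:
    """End-to-end pipeline settings; the seed covers every stochastic stage."""

    seed: int
    simulation_spec: list[tuple[str, int]] = field(default_factory=list)
    library_path: str = "builtin"
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    split_fraction: float = 0.3
    alpha: float = 0.05
    redundancy_threshold: float = 0.95
    features: Optional[list[str]] = None  # None = automatic pruning
    excluded_species: list[str] = field(default_factory=list)
    output_dir: str = "flashkin_run"
    n_boot: int = 500

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be set")
        for name, val in (
            ("split_fraction", self.split_fraction),
            ("alpha", self.alpha),
            ("redundancy_threshold", self.redundancy_threshold),
        ):
            if not (0 < val < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        self.acquisition.validate()

    def library(self) -> SpeciesLibrary:
        if self.library_path == "builtin":
            return default_library()
        return SpeciesLibrary.load(self.library_path)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation_spec"] = [list(x) for x in self.simulation_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionConfig(**d["acquisition"])
        if "simulation_spec" in d:
            d["simulation_spec"] = [tuple(x) for x in d["simulation_spec"]]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        if str(path).endswith((".yaml", ".yml")):
            Path(path).write_text(yaml.safe_dump(self.to_dict()))
        else:
            Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> extract -> describe -> compare -> train -> validate.

    Writes every table plus a reproducibility manifest (config, seed,
    versions, stage timings) to ``config.output_dir`` and returns the
    in-memory results keyed by stage name.
    """
    from . import classify, simulate, stats

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = config.library()
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                logger.info("stage %s finished in %.2fs", name, timings[name])

        return _Timer()

    with stage("simulate"):
        traces, truth = simulate.simulate_cohort(
            config.simulation_spec, library, config.acquisition, config.seed
        )
        truth.to_csv(out / "truth.csv", index=False)
    with stage("extract"):
        records = extract_first_flash(traces, config.acquisition)
        write_records(records, out / "records.csv")
    with stage("describe"):
        described = stats.describe_table(
            records, n_boot=config.n_boot, seed=config.seed
        )
        described.to_csv(out / "describe.csv", index=False)
    with stage("compare"):
        matrix = stats.significance_matrix(records, alpha=config.alpha)
        matrix.table.to_csv(out / "significance.csv", index=False)
    with stage("cluster"):
        cluster = classify.hierarchical_cluster(
            classify.species_mean_table(records)
        )
        (out / "dendrogram.json").write_text(
            json.dumps({"species": list(cluster.species),
                        "merges": cluster.merges}, indent=2)
        )
    with stage("train"):
        if config.features is None:
            transform = classify.select_features(
                records, redundancy_threshold=config.redundancy_threshold
            )
        else:
            transform = classify.FeatureTransform.make(config.features)
        train, test = classify.split_train_test(
            records, config.split_fraction, seed=config.seed
        )
        transform.fit(train[~train["species"].isin(config.excluded_species)])
        model = classify.train_lda(
            train, transform, excluded_species=config.excluded_species,
            genus_map=library.genus_map,
        )
        model.save(out / "model.json")
    with stage("validate"):
        test_eval = test[~test["species"].isin(config.excluded_species)]
        confusion = classify.validate(model, test_eval)
        confusion.counts.to_csv(out / "confusion.csv")
        classify.prediction_table(model, test_eval).to_csv(
            out / "posteriors.csv", index=False
        )

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "flashkin": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": timings,
        "n_traces": len(traces),
        "n_records": len(records),
        "overall_accuracy": confusion.overall_accuracy,
        "genus_accuracy": confusion.genus_accuracy,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    results.update(
        traces=traces, truth=truth, records=records, describe=described,
        significance=matrix, cluster=cluster, model=model,
        confusion=confusion, manifest=manifest,
    )
    return results
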