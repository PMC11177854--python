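"""Descriptive and inferential statistics over flash-record tables.

The printed per-species FFKP distributions are uniformly non-normal, so the
toolkit here is deliberately nonparametric: percentile bootstrap confidence
intervals for the mean (500 iterations by default), Shapiro-Wilk normality
screening, and tie-corrected Kruskal-Wallis rank tests, including the
pairwise species x parameter significance matrix used to decide which
kinetics can separate which species.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: record-table column for each canonical parameter name
PARAM_COLUMNS = {
    "PI": "pi_photons_s",
    "FF-MSL": "ffmsl_photons",
    "RT": "rt_ms",
    "DT": "dt_ms",
    "FD": "fd_ms",
    "EF": "ef_ms",
}
DEFAULT_PARAMETERS = ("PI", "FF-MSL", "RT", "DT", "FD", "EF")


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 500
    statistic: str = "mean"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 500,
    level: float = 0.95,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> BootstrapCI:
    """Percentile bootstrap CI for the sample mean.

    ``exhaustive=True`` enumerates all n**n equally likely resamples instead
    of drawing ``n_boot`` random ones (only sensible for tiny n; guarded at
    n <= 8).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0

    if exhaustive:
        if x.size > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        means = np.array(
            [np.mean(c) for c in itertools.product(x, repeat=x.size)]
        )
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        means = x[idx].mean(axis=1)

    lower, upper = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        lower=float(lower), upper=float(upper), level=level,
        n_boot=len(means), seed=seed,
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value; raises on degenerate input."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for identical values")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class SignificanceMatrix:
    """Pairwise species x parameter Kruskal-Wallis p-values and flags."""

    table: pd.DataFrame  # one row per unordered pair
    alpha: float = 0.05
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS
    correction: Optional[str] = None
    skipped: tuple[str, ...] = ()

    def pair(self, species_a: str, species_b: str) -> pd.Series:
        a, b = sorted((species_a, species_b))
        match = self.table[
            (self.table["species_a"] == a) & (self.table["species_b"] == b)
        ]
        if match.empty:
            raise KeyError((species_a, species_b))
        return match.iloc[0]

    def significant_parameters(self, species_a: str, species_b: str) -> list[str]:
        row = self.pair(species_a, species_b)
        return [p for p in self.parameters if row[f"sig_{p}"]]


def significance_matrix(
    records: pd.DataFrame,
    alpha: float = 0.05,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    correction: Optional[str] = None,
    min_records: int = 3,
) -> SignificanceMatrix:
    """Two-group Kruskal-Wallis tests for every species pair and parameter.

    Raw p-values are flagged at ``alpha`` by default (no multiplicity
    correction); ``correction="holm"`` applies a Holm adjustment within each
    parameter across pairs.
    """
    species = sorted(records["species"].unique())
    if len(species) < 2:
        raise ValueError("need records from at least two species")
    counts = records["species"].value_counts()
    usable = [s for s in species if counts[s] >= min_records]
    skipped = [s for s in species if counts[s] < min_records]
    for s in skipped:
        _warnings.warn(
            f"species {s!r} has fewer than {min_records} records; pairs skipped"
        )

    rows = []
    for a, b in itertools.combinations(usable, 2):
        row: dict = {"species_a": a, "species_b": b}
        ga = records[records["species"] == a]
        gb = records[records["species"] == b]
        for param in parameters:
            col = PARAM_COLUMNS[param]
            _, p = kruskal_wallis([ga[col].to_numpy(), gb[col].to_numpy()])
            row[f"p_{param}"] = p
        rows.append(row)
    table = pd.DataFrame(rows)

    if correction is None:
        for param in parameters:
            table[f"sig_{param}"] = table[f"p_{param}"] < alpha
    elif correction == "holm":
        from statsmodels.stats.multitest import multipletests

        for param in parameters:
            reject, p_adj, _, _ = multipletests(
                table[f"p_{param}"], alpha=alpha, method="holm"
            )
            table[f"p_{param}"] = p_adj
            table[f"sig_{param}"] = reject
    else:
        raise ValueError(f"unknown correction: {correction!r}")

    return SignificanceMatrix(
        table=table, alpha=alpha, parameters=tuple(parameters),
        correction=correction, skipped=tuple(skipped),
    )


def describe_table(
    records: pd.DataFrame,
    n_boot: int = 500,
    level: float = 0.95,
    seed: Optional[int] = None,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Library-style summary: per species and parameter, n/mean/sd/CI."""
    rows = []
    rng = np.random.default_rng(seed)
    for species, group in records.groupby("species", sort=True):
        for param in parameters:
            x = group[PARAM_COLUMNS[param]].to_numpy(dtype=float)
            ci = bootstrap_ci(
                x, n_boot=n_boot, level=level,
                seed=int(rng.integers(2**31)),
            )
            rows.append(
                {
                    "species": species,
                    "parameter": param,
                    "n": x.size,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                }
            )
    return pd.DataFrame(rows)
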