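"""Species identification from flash kinetics.

Pipeline: correlation-based redundancy pruning of the six FFKPs (peak
intensity and flash total are near-collinear, as are decay time and flash
duration), hierarchical clustering of species mean signatures, and a
pooled-covariance linear discriminant model that returns per-species
posterior probabilities with a genus-level rollup.

Feature space: intensities span six orders of magnitude across species and
every FFKP is positive and right-skewed, so the default transform is log10
followed by z-standardization fitted on training data (raw-scale mode is
retained for sensitivity analysis). The discriminant axes come from the
generalized eigenproblem between the between-class and pooled within-class
scatter; posteriors are Gaussian class conditionals with the shared pooled
covariance and uniform priors unless stated otherwise.
"""

from __future__ import annotations

import itertools
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .stats import PARAM_COLUMNS
from .library import default_library

#: fixed pruning priority: most species-separating parameters first
FEATURE_PRIORITY = ("PI", "FD", "RT", "EF", "DT", "FF-MSL")


# --------------------------------------------------------------------------
# Feature transform
# --------------------------------------------------------------------------

@dataclass
class FeatureTransform:
    """Per-feature transform (identity or log10) + z-standardization."""

    features: tuple[str, ...]
    transforms: dict[str, str]
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("at least one feature required")
        for f in self.features:
            if self.transforms.get(f, "identity") not in ("identity", "log10"):
                raise ValueError(f"unknown transform for {f}")

    @classmethod
    def make(
        cls, features: Sequence[str], log_transform: bool = True
    ) -> "FeatureTransform":
        return cls(
            features=tuple(features),
            transforms={
                f: ("log10" if log_transform else "identity") for f in features
            },
        )

    def _raw(self, records: pd.DataFrame, feature: str) -> np.ndarray:
        x = records[PARAM_COLUMNS[feature]].to_numpy(dtype=float)
        if self.transforms.get(feature, "identity") == "log10":
            if np.any(x <= 0):
                raise ValueError(f"non-positive values in {feature}; cannot log")
            x = np.log10(x)
        return x

    def fit(self, records: pd.DataFrame) -> "FeatureTransform":
        for f in self.features:
            x = self._raw(records, f)
            s = float(x.std(ddof=1))
            if not s > 0:
                raise ValueError(f"feature {f} has zero variance")
            self.center[f] = float(x.mean())
            self.scale[f] = s
        return self

    def apply(self, records: pd.DataFrame) -> np.ndarray:
        if not self.center:
            raise RuntimeError("transform not fitted")
        cols = []
        for f in self.features:
            x = self._raw(records, f)
            cols.append((x - self.center[f]) / self.scale[f])
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "transforms": dict(self.transforms),
            "center": dict(self.center),
            "scale": dict(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTransform":
        return cls(
            features=tuple(d["features"]),
            transforms=dict(d["transforms"]),
            center=dict(d["center"]),
            scale=dict(d["scale"]),
        )


# --------------------------------------------------------------------------
# Correlation-based feature pruning
# --------------------------------------------------------------------------

def correlation(
    records: pd.DataFrame,
    feature_a: str,
    feature_b: str,
    transformed: bool = False,
) -> float:
    """Pearson r between two FFKPs, on raw or log10 values."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    xa = records[PARAM_COLUMNS[feature_a]].to_numpy(dtype=float)
    xb = records[PARAM_COLUMNS[feature_b]].to_numpy(dtype=float)
    if transformed:
        xa, xb = np.log10(xa), np.log10(xb)
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("zero variance feature")
    return float(np.corrcoef(xa, xb)[0, 1])


def select_features(
    records: pd.DataFrame,
    candidates: Sequence[str] = FEATURE_PRIORITY,
    redundancy_threshold: float = 0.95,
    log_transform: bool = True,
) -> FeatureTransform:
    """Greedy redundancy pruning in fixed priority order.

    A candidate is kept unless its |Pearson r| (on transformed values,
    pooled across species) with an already-kept feature exceeds the
    threshold; constant features are excluded with a warning. Returns the
    fitted transform over the kept set.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate features")
    if records["species"].nunique() < 2:
        raise ValueError("records must span at least two species")

    kept: list[str] = []
    for cand in candidates:
        x = records[PARAM_COLUMNS[cand]].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            _warnings.warn(f"feature {cand} is constant; excluded")
            continue
        redundant = False
        for prev in kept:
            r = correlation(records, prev, cand, transformed=log_transform)
            if abs(r) > redundancy_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    return FeatureTransform.make(kept, log_transform=log_transform).fit(records)


# --------------------------------------------------------------------------
# Species mean signatures and hierarchical clustering
# --------------------------------------------------------------------------

def species_mean_table(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic per-species means of the six FFKPs (raw units)."""
    cols = list(PARAM_COLUMNS.values())
    return records.groupby("species", sort=True)[cols].mean()


@dataclass
class ClusterResult:
    """Dendrogram as a merge list; heights are linkage distances."""

    species: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    merges: list[tuple[int, int, float, int]]

    def merge_order(self) -> list[set[str]]:
        """Leaf-name sets merged at each step, in height order."""
        clusters: dict[int, set[str]] = {
            i: {name} for i, name in enumerate(self.species)
        }
        out = []
        n = len(self.species)
        for k, (i, j, _, _) in enumerate(self.merges):
            merged = clusters[int(i)] | clusters[int(j)]
            clusters[n + k] = merged
            out.append(merged)
        return out

    def last_joining_leaf(self) -> str:
        """Leaf that only joins the tree at the final merge, if unique."""
        final_i, final_j, _, _ = self.merges[-1]
        n = len(self.species)
        for side in (int(final_i), int(final_j)):
            if side < n:
                return self.species[side]
        # otherwise the smaller of the two final clusters
        order = self.merge_order()
        last = order[-1]
        prev = order[-2]
        remainder = last - prev
        if len(remainder) == 1:
            return next(iter(remainder))
        raise ValueError("no unique last-joining leaf")


def hierarchical_cluster(
    mean_table: pd.DataFrame,
    metric: str = "euclidean",
    linkage_method: str = "average",
    log_transform: bool = True,
    standardize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of species mean FFKP signatures.

    Defaults: z-standardized log10 means, Euclidean distance, average
    linkage. Rows are sorted by species name first so ties break
    deterministically.
    """
    if len(mean_table) < 2:
        raise ValueError("need at least two species")
    table = mean_table.sort_index()
    x = table.to_numpy(dtype=float)
    if log_transform:
        if np.any(x <= 0):
            raise ValueError("non-positive means; cannot log-transform")
        x = np.log10(x)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    z = sch.linkage(pdist(x, metric=metric), method=linkage_method)
    merges = [
        (int(row[0]), int(row[1]), float(row[2]), int(row[3])) for row in z
    ]
    return ClusterResult(
        species=tuple(table.index), linkage=z, merges=merges
    )


# --------------------------------------------------------------------------
# Linear discriminant model
# --------------------------------------------------------------------------

@dataclass
class LDAModel:
    classes: tuple[str, ...]
    excluded_species: tuple[str, ...]
    priors: np.ndarray
    class_means: np.ndarray  # (k, f) in transformed feature space
    pooled_cov: np.ndarray  # (f, f)
    axes: np.ndarray  # (f, m) discriminant directions, columns
    explained_variance: np.ndarray  # (m,) fractions summing to 1
    transform: FeatureTransform
    genus_map: dict[str, str] = field(default_factory=dict)
    ridge_applied: bool = False

    def genus_of(self, species: str) -> str:
        return self.genus_map.get(species, species.split()[0])

    def save(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "excluded_species": list(self.excluded_species),
            "priors": self.priors.tolist(),
            "class_means": self.class_means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "axes": self.axes.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "transform": self.transform.to_dict(),
            "genus_map": self.genus_map,
            "ridge_applied": self.ridge_applied,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(d["classes"]),
            excluded_species=tuple(d["excluded_species"]),
            priors=np.asarray(d["priors"], dtype=float),
            class_means=np.asarray(d["class_means"], dtype=float),
            pooled_cov=np.asarray(d["pooled_cov"], dtype=float),
            axes=np.asarray(d["axes"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            transform=FeatureTransform.from_dict(d["transform"]),
            genus_map=dict(d["genus_map"]),
            ridge_applied=bool(d["ridge_applied"]),
        )


def train_lda(
    records: pd.DataFrame,
    transform: FeatureTransform,
    excluded_species: Sequence[str] = (),
    priors: Optional[dict[str, float]] = None,
    genus_map: Optional[dict[str, str]] = None,
    ridge: float = 1e-8,
) -> LDAModel:
    """Fit the pooled-covariance discriminant model.

    Axes solve the between/within generalized eigenproblem, ordered by
    eigenvalue; explained-variance fractions are eigenvalue shares over the
    retained min(#features, #classes - 1) axes.
    """
    data = records[~records["species"].isin(excluded_species)]
    classes = tuple(sorted(data["species"].unique()))
    if len(classes) < 2:
        raise ValueError("need at least two classes after exclusion")
    x = transform.apply(data)
    y = data["species"].to_numpy()
    n, f = x.shape
    for c in classes:
        if (y == c).sum() < f + 1:
            raise ValueError(f"class {c!r} has fewer than n_features+1 records")

    means = np.vstack([x[y == c].mean(axis=0) for c in classes])
    grand = x.mean(axis=0)

    sw = np.zeros((f, f))
    sb = np.zeros((f, f))
    for i, c in enumerate(classes):
        xc = x[y == c]
        d = xc - means[i]
        sw += d.T @ d
        dm = (means[i] - grand)[:, None]
        sb += len(xc) * (dm @ dm.T)
    pooled_cov = sw / (n - len(classes))

    ridge_applied = False
    sw_solve = pooled_cov
    try:
        np.linalg.cholesky(sw_solve)
    except np.linalg.LinAlgError:
        sw_solve = pooled_cov + ridge * np.eye(f)
        ridge_applied = True
        try:
            np.linalg.cholesky(sw_solve)
        except np.linalg.LinAlgError as exc:
            raise ValueError("pooled covariance singular after ridge") from exc

    eigvals, eigvecs = sla.eigh(sb / (n - len(classes)), sw_solve)
    order = np.argsort(eigvals)[::-1]
    m = min(f, len(classes) - 1)
    eigvals = np.clip(eigvals[order][:m], 0.0, None)
    axes = eigvecs[:, order][:, :m]
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.full(m, 1.0 / m)

    if priors is None:
        prior_vec = np.full(len(classes), 1.0 / len(classes))
    else:
        prior_vec = np.array([priors[c] for c in classes], dtype=float)
        prior_vec = prior_vec / prior_vec.sum()

    if genus_map is None:
        genus_map = default_library().genus_map

    return LDAModel(
        classes=classes,
        excluded_species=tuple(excluded_species),
        priors=prior_vec,
        class_means=means,
        pooled_cov=pooled_cov,
        axes=axes,
        explained_variance=explained,
        transform=transform,
        genus_map={c: genus_map.get(c, c.split()[0]) for c in classes},
        ridge_applied=ridge_applied,
    )


@dataclass
class PredictionResult:
    """Posterior table plus per-record rankings and genus rollup."""

    posteriors: pd.DataFrame  # rows = records, columns = species
    genus_posteriors: pd.DataFrame
    predicted_species: pd.Series
    predicted_genus: pd.Series

    @property
    def top_probability(self) -> pd.Series:
        return self.posteriors.max(axis=1)

    def ranked(self, row: int = 0) -> list[tuple[str, float]]:
        s = self.posteriors.iloc[row].sort_values(ascending=False)
        return list(zip(s.index, s.to_numpy()))


def predict_posteriors(model: LDAModel, records: pd.DataFrame) -> PredictionResult:
    """Gaussian shared-covariance posteriors for each record.

    Ties on the maximum posterior break alphabetically (class order).
    """
    for f in model.transform.features:
        if PARAM_COLUMNS[f] not in records.columns:
            raise ValueError(f"missing feature column for {f}")
    x = model.transform.apply(records)
    cov_inv = np.linalg.inv(model.pooled_cov)
    log_post = np.empty((len(x), len(model.classes)))
    for i, _ in enumerate(model.classes):
        d = x - model.class_means[i]
        maha = np.einsum("ij,jk,ik->i", d, cov_inv, d)
        log_post[:, i] = -0.5 * maha + np.log(model.priors[i])
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)

    posteriors = pd.DataFrame(
        post, columns=list(model.classes), index=records.index
    )
    genus_names = sorted({model.genus_of(c) for c in model.classes})
    genus_post = pd.DataFrame(
        0.0, columns=genus_names, index=records.index
    )
    for c in model.classes:
        genus_post[model.genus_of(c)] += posteriors[c]

    pred_idx = post.argmax(axis=1)  # first (alphabetical) class on ties
    predicted = pd.Series(
        [model.classes[i] for i in pred_idx], index=records.index,
        name="predicted_species",
    )
    predicted_genus = predicted.map(model.genus_of).rename("predicted_genus")
    return PredictionResult(
        posteriors=posteriors,
        genus_posteriors=genus_post,
        predicted_species=predicted,
        predicted_genus=predicted_genus,
    )


def prediction_table(model: LDAModel, records: pd.DataFrame) -> pd.DataFrame:
    """One row per record: posterior per species + prediction summary."""
    res = predict_posteriors(model, records)
    out = res.posteriors.copy()
    out.insert(0, "trace_id", records["trace_id"].to_numpy())
    out["predicted_species"] = res.predicted_species
    out["predicted_genus"] = res.predicted_genus
    out["top_probability"] = res.top_probability
    return out


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # rows = truth, columns = prediction
    overall_accuracy: float
    genus_accuracy: float

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def validate(model: LDAModel, test_records: pd.DataFrame) -> ConfusionMatrix:
    """Argmax-posterior confusion matrix with species and genus accuracy."""
    if len(test_records) == 0:
        raise ValueError("empty test set")
    if "species" not in test_records.columns or (
        test_records["species"].astype(str) == ""
    ).any():
        raise ValueError("labels required for validation")
    res = predict_posteriors(model, test_records)
    truth = test_records["species"].to_numpy()
    pred = res.predicted_species.to_numpy()

    labels = sorted(set(truth) | set(model.classes))
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(truth, pred):
        counts.loc[t, p] += 1

    overall = float(np.mean(pred == truth))
    genus_truth = np.array([model.genus_of(t) for t in truth])
    genus_pred = np.array([model.genus_of(p) for p in pred])
    genus_acc = float(np.mean(genus_pred == genus_truth))
    return ConfusionMatrix(
        counts=counts, overall_accuracy=overall, genus_accuracy=genus_acc
    )


def split_train_test(
    records: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-species train/test split (at least one test record per
    species when the species has >= 2 records)."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for _, group in records.groupby("species", sort=True):
        n_test = int(round(len(group) * test_fraction))
        if len(group) >= 2:
            n_test = min(max(n_test, 1), len(group) - 1)
        perm = rng.permutation(len(group))
        test_idx.extend(group.index[perm[:n_test]])
    test_mask = records.index.isin(test_idx)
    return records[~test_mask].copy(), records[test_mask].copy()
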