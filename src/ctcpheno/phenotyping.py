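"""CTC phenotype clustering.

CTC morphology/intensity features are standardized (z-scored with population
standard deviation) and partitioned by k-means into k=5 phenotypic clusters,
following the published analysis of 19k CTCs.  Cluster labels are 1-based.
CD45-derived features are excluded by default (CTCs are CD45-negative by
gate, so they carry no phenotypic information).

The k-means fit itself is delegated to scikit-learn's Lloyd implementation
(best of ``n_restarts`` by inertia, deterministic given seed); assignment is
done here by explicit nearest-centroid with lowest-index tie-breaking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingModel", "ClusterModel", "standardize", "fit_kmeans", "assign",
    "compare_centroid_distances", "cluster_presence", "select_k_silhouette",
]


class FeatureMismatchError(ValueError):
    """Feature names of the input do not match the fitted model."""


@dataclass
class ScalingModel:
    """Per-feature location/scale learned on the CTC training set.

    Zero-variance features are dropped (with a logged warning) rather than
    producing infinities; ``feature_names`` lists the retained features.
    """

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise FeatureMismatchError(f"missing feature column(s): {', '.join(missing)}")
        x = table[self.feature_names].to_numpy(dtype=float)
        return (x - self.means) / self.scales

    def to_dict(self) -> dict:
        return {"feature_names": self.feature_names,
                "means": self.means.tolist(), "scales": self.scales.tolist()}


@dataclass
class ClusterModel:
    """k-means result: centroids in standardized space plus the scaler."""

    k: int
    centroids: np.ndarray
    scaling: ScalingModel
    inertia: float
    seed: int
    n_restarts: int = 10

    @property
    def feature_names(self) -> list[str]:
        return self.scaling.feature_names

    def save(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "scaling": self.scaling.to_dict(),
            "inertia": self.inertia,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        scaling = ScalingModel(feature_names=d["scaling"]["feature_names"],
                               means=np.asarray(d["scaling"]["means"]),
                               scales=np.asarray(d["scaling"]["scales"]))
        return cls(k=d["k"], centroids=np.asarray(d["centroids"]), scaling=scaling,
                   inertia=d["inertia"], seed=d["seed"], n_restarts=d["n_restarts"])


def standardize(ctc_features: pd.DataFrame,
                feature_names: list[str] | None = None) -> tuple[ScalingModel, np.ndarray]:
    """Z-score features to mean 0 / sd 1 using the population-sd convention.

    Constant (zero-variance) columns are dropped with a warning; if every
    column is constant, raises ``ValueError``.
    """
    if feature_names is None:
        feature_names = list(ctc_features.columns)
    if len(ctc_features) < 2:
        raise ValueError("standardization needs at least 2 CTCs")
    x = ctc_features[feature_names].to_numpy(dtype=float)
    means = x.mean(axis=0)
    scales = x.std(axis=0)  # ddof=0: population sd
    keep = scales > 0
    if not keep.any():
        raise ValueError("all features are zero-variance; nothing to cluster on")
    dropped = [f for f, k in zip(feature_names, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance feature(s): %s", ", ".join(dropped))
    kept = [f for f, k in zip(feature_names, keep) if k]
    model = ScalingModel(feature_names=kept, means=means[keep], scales=scales[keep])
    return model, (x[:, keep] - means[keep]) / scales[keep]


def fit_kmeans(z: np.ndarray, scaling: ScalingModel, k: int = 5, seed: int = 0,
               n_restarts: int = 10) -> ClusterModel:
    """Lloyd k-means, best of ``n_restarts`` by inertia, deterministic given seed."""
    n = z.shape[0]
    if n < k:
        raise ValueError(f"cannot fit k={k} clusters on {n} points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd", tol=1e-10)
    km.fit(z)
    return ClusterModel(k=k, centroids=km.cluster_centers_.copy(), scaling=scaling,
                        inertia=float(km.inertia_), seed=seed, n_restarts=n_restarts)


def assign(model: ClusterModel, z: np.ndarray,
           event_ids: pd.Series | np.ndarray | None = None) -> pd.DataFrame:
    """Nearest-centroid assignment (1-based labels, ties -> lowest index).

    Returns columns event_id (if given), cluster, distance_to_centroid.
    """
    if z.ndim != 2 or z.shape[1] != model.centroids.shape[1]:
        raise FeatureMismatchError(
            f"input has {z.shape[1] if z.ndim == 2 else '?'} features, "
            f"model expects {model.centroids.shape[1]}")
    d = np.linalg.norm(z[:, None, :] - model.centroids[None, :, :], axis=2)
    labels = d.argmin(axis=1)  # argmin takes the lowest index on ties
    out = pd.DataFrame({
        "cluster": labels + 1,
        "distance_to_centroid": d[np.arange(len(labels)), labels],
    })
    if event_ids is not None:
        out.insert(0, "event_id", np.asarray(event_ids))
    return out


def compare_centroid_distances(assignments: pd.DataFrame, sample_counts: pd.DataFrame,
                               count_split: float | None = None) -> dict:
    """Are CTCs from high-count samples closer to their centroids?

    Mann-Whitney U (two-sided) on per-CTC centroid distances between CTCs
    from high- vs low-CTC-count samples.  ``count_split``: samples with
    ``n_ctc > count_split`` are "high"; default is the median count over
    CTC-positive samples.  A non-significant p supports that the clusters
    represent CTCs from both groups equally well.
    """
    if "sample_id" not in assignments.columns:
        raise ValueError("assignments must carry sample_id to join sample counts")
    merged = assignments.merge(sample_counts[["sample_id", "n_ctc"]], on="sample_id")
    if count_split is None:
        count_split = float(merged.drop_duplicates("sample_id")["n_ctc"].median())
    high = merged.loc[merged["n_ctc"] > count_split, "distance_to_centroid"]
    low = merged.loc[merged["n_ctc"] <= count_split, "distance_to_centroid"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(f"count_split={count_split} leaves an empty group")
    u, p = mannwhitneyu(low, high, alternative="two-sided")
    return {
        "u_statistic": float(u),
        "p_value": float(p),
        "count_split": count_split,
        "median_distance_low": float(low.median()),
        "median_distance_high": float(high.median()),
        "n_low": int(len(low)),
        "n_high": int(len(high)),
    }


def cluster_presence(assignments: pd.DataFrame, samples: pd.DataFrame,
                     k: int = 5) -> pd.DataFrame:
    """Per-sample cluster composition: counts, fractions, presence flags.

    Zero-CTC samples get all-absent presence and NaN fractions (flagged by
    ``n_ctc == 0``); fractions sum to 1 for every CTC-positive sample.
    """
    counts = np.zeros((len(samples), k), dtype=np.int64)
    sample_index = {s: i for i, s in enumerate(samples["sample_id"])}
    if len(assignments):
        grouped = assignments.groupby(["sample_id", "cluster"]).size()
        for (sid, cl), n in grouped.items():
            if sid in sample_index and 1 <= cl <= k:
                counts[sample_index[sid], cl - 1] = n
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total[:, None] > 0, counts / np.maximum(total[:, None], 1), np.nan)
    out = pd.DataFrame({"sample_id": samples["sample_id"].to_numpy(), "n_ctc": total})
    for j in range(k):
        out[f"n_cluster_{j+1}"] = counts[:, j]
    for j in range(k):
        out[f"frac_cluster_{j+1}"] = frac[:, j]
    for j in range(k):
        out[f"present_cluster_{j+1}"] = counts[:, j] > 0
    return out


def select_k_silhouette(z: np.ndarray, scaling: ScalingModel, k_range=range(2, 9),
                        seed: int = 0, n_restarts: int = 5,
                        max_points: int = 5000) -> pd.DataFrame:
    """Silhouette-score helper for choosing k (not used by the default pipeline)."""
    rng = np.random.default_rng(seed)
    if z.shape[0] > max_points:
        z = z[rng.choice(z.shape[0], max_points, replace=False)]
    rows = []
    for k in k_range:
        if z.shape[0] <= k:
            continue
        model = fit_kmeans(z, scaling, k=k, seed=seed, n_restarts=n_restarts)
        labels = assign(model, z)["cluster"].to_numpy()
        rows.append({"k": k, "silhouette": float(silhouette_score(z, labels)),
                     "inertia": model.inertia})
    return pd.DataFrame(rows)
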