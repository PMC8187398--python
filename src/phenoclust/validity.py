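"""Internal validity and bootstrap stability for comparing clusterings.

Silhouette, cluster-size balance and entropy diagnostics, plus Hennig-style
cluster-wise Jaccard stability under n-of-n bootstrap resampling, which also
drives selection of the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .baselines import DistanceMatrix

__all__ = [
    "ValidityReport",
    "StabilityReport",
    "silhouette",
    "size_distribution",
    "entropy_score",
    "jaccard",
    "bootstrap_stability",
    "select_k",
    "validity_report",
]


@dataclass
class ValidityReport:
    silhouette_mean: float
    silhouette_per_sample: np.ndarray
    size_proportions: np.ndarray
    largest_share: float
    entropy: float

    def to_dict(self) -> dict:
        return {
            "silhouette_mean": self.silhouette_mean,
            "size_proportions": self.size_proportions.tolist(),
            "largest_share": self.largest_share,
            "entropy": self.entropy,
        }


@dataclass
class StabilityReport:
    per_cluster_jaccard: np.ndarray
    B: int
    k: int
    mean_jaccard: float
    n_failed_resamples: int = 0

    def to_dict(self) -> dict:
        return {
            "per_cluster_jaccard": self.per_cluster_jaccard.tolist(),
            "B": self.B,
            "k": self.k,
            "mean_jaccard": self.mean_jaccard,
            "n_failed_resamples": self.n_failed_resamples,
        }


def silhouette(dm: DistanceMatrix | np.ndarray, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette s(i) = (b - a) / max(a, b) and its mean.

    ``a`` is the mean intra-cluster distance excluding self; ``b`` the
    smallest mean distance to another cluster. Singleton clusters get 0.
    """
    D = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    masks = {c: labels == c for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        own = masks[labels[i]]
        n_own = int(own.sum())
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s, float(s.mean())


def size_distribution(labels) -> tuple[np.ndarray, float]:
    """Descending-sorted cluster proportions and the largest share."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    _, counts = np.unique(labels, return_counts=True)
    props = np.sort(counts / labels.size)[::-1]
    return props, float(props[0])


def entropy_score(labels) -> float:
    """Shannon entropy (natural log) of the cluster-size distribution."""
    props, _ = size_distribution(labels)
    props = props[props > 0]
    return float(-(props * np.log(props)).sum())


def jaccard(A: Iterable, B: Iterable) -> float:
    """|A intersect B| / |A union B| over id sets."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("jaccard undefined for two empty sets")
    return len(A & B) / len(A | B)


def validity_report(dm, labels) -> ValidityReport:
    per_sample, mean = silhouette(dm, labels)
    props, largest = size_distribution(labels)
    return ValidityReport(
        silhouette_mean=mean,
        silhouette_per_sample=per_sample,
        size_proportions=props,
        largest_share=largest,
        entropy=entropy_score(labels),
    )


def _clusters_as_sets(labels: np.ndarray, ids: np.ndarray) -> list[set]:
    return [set(ids[labels == c].tolist()) for c in np.unique(labels)]


def bootstrap_stability(
    data,
    reference,
    clusterer: Callable[[np.ndarray, int], np.ndarray],
    B: int = 100,
    seed: int = 0,
    resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> StabilityReport:
    """Cluster-wise Jaccard stability under n-of-n bootstrap resampling.

    ``clusterer(values, seed) -> labels`` is re-run on each resample; every
    reference cluster is scored by its best Jaccard match among the resample
    clusters, restricted to the resampled ids (duplicates counted once), and
    averaged over the B resamples.
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    ref_labels = np.asarray(getattr(reference, "labels", reference))
    n = X.shape[0]
    if ref_labels.size != n:
        raise ValueError("reference labels must match data rows")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    ref_sets = _clusters_as_sets(ref_labels, all_idx)
    k = len(ref_sets)
    sums = np.zeros(k)
    counts = np.zeros(k)
    n_failed = 0
    for b in range(B):
        idx = resampler(rng, n) if resampler is not None else rng.integers(0, n, n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            new_labels = np.asarray(clusterer(X[idx], sub_seed))
        except Exception:
            n_failed += 1
            continue
        resampled = np.unique(idx)
        resampled_set = set(resampled.tolist())
        new_sets = [
            set(np.unique(idx[new_labels == c]).tolist())
            for c in np.unique(new_labels)
        ]
        for j, ref in enumerate(ref_sets):
            restricted = ref & resampled_set
            if not restricted:
                continue
            best = max(jaccard(restricted, s) for s in new_sets)
            sums[j] += best
            counts[j] += 1
    per_cluster = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return StabilityReport(
        per_cluster_jaccard=per_cluster,
        B=B,
        k=k,
        mean_jaccard=float(np.nanmean(per_cluster)),
        n_failed_resamples=n_failed,
    )


def select_k(
    data,
    clusterer: Callable[[np.ndarray, int, int], np.ndarray],
    k_range: Sequence[int],
    B: int = 100,
    seed: int = 0,
) -> tuple[int, dict[int, StabilityReport]]:
    """Pick the k maximizing mean bootstrap Jaccard stability (ties -> smaller k).

    ``clusterer(values, k, seed) -> labels``.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be nonempty")
    X = np.asarray(getattr(data, "values", data), dtype=float)
    reports: dict[int, StabilityReport] = {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        ref_seed = int(rng.integers(0, 2**31 - 1))
        boot_seed = int(rng.integers(0, 2**31 - 1))
        ref_labels = np.asarray(clusterer(X, k, ref_seed))
        reports[k] = bootstrap_stability(
            X, ref_labels, lambda values, s, _k=k: clusterer(values, _k, s),
            B=B, seed=boot_seed,
        )
    best_k = k_range[0]
    best_val = -np.inf
    for k in k_range:  # ascending, so ties resolve to the smaller k
        if reports[k].mean_jaccard > best_val + 1e-12:
            best_val = reports[k].mean_jaccard
            best_k = k
    return best_k, reports
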