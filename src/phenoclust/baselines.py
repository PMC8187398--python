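"""Comparator clusterers: k-means, agglomerative HC, and HC on DTW distances.

k-means is implemented directly (k-means++ seeding, Lloyd iterations with a
recorded inertia trace, best of ``n_init`` restarts) so the iteration-level
behaviour is inspectable; hierarchical clustering delegates to SciPy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .preprocess import FeatureMatrix
from .synth import Cohort

try:  # optional JIT for the DTW dynamic program
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ClusteringResult",
    "DistanceMatrix",
    "kmeans_cluster",
    "hier_cluster",
    "dtw_distance",
    "pairwise_dtw",
    "hc_dtw_cluster",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    algorithm: str
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric: str  # euclidean | dtw
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(D < 0):
            raise ValueError("distances must be nonnegative")
        if np.max(np.abs(D - D.T)) > 1e-10:
            raise ValueError("distance matrix must be symmetric (tol 1e-10)")
        if np.max(np.abs(np.diag(D))) > 0:
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = (D + D.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_array(fm) -> np.ndarray:
    return fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)


def _kmeans_pp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)  # argmin breaks ties at lowest index
        inertia = float(d2[np.arange(X.shape[0]), new_labels].sum())
        trace.append(inertia)
        for j in range(centers.shape[0]):
            mask = new_labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                centers[j] = X[int(np.argmax(d2[np.arange(X.shape[0]), new_labels]))]
        if np.array_equal(new_labels, labels) and len(trace) > 1:
            labels = new_labels
            break
        labels = new_labels
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    trace.append(inertia)
    return labels, centers, inertia, trace


def kmeans_cluster(
    fm, k: int, seed: int = 0, n_init: int = 10, max_iter: int = 300
) -> ClusteringResult:
    """Best-of-``n_init`` Lloyd k-means with k-means++ seeding."""
    X = _as_array(fm)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, n={n}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_init, 1)):
        centers = _kmeans_pp(X, k, rng)
        labels, centers, inertia, trace = _lloyd(X, centers, max_iter, rng)
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centers, inertia, trace)
    labels, centers, inertia, trace = best
    return ClusteringResult(
        labels=labels,
        k=k,
        algorithm="kmeans",
        seed=seed,
        diagnostics={"inertia": inertia, "inertia_trace": trace, "centers": centers},
    )


def hier_cluster(dm_or_fm, k: int, linkage: str = "ward") -> ClusteringResult:
    """Agglomerative clustering cut at ``k`` clusters.

    Accepts a FeatureMatrix / raw array (euclidean) or a precomputed
    DistanceMatrix; Ward linkage is only valid on euclidean feature vectors.
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValueError("linkage must be one of ward/average/complete")
    if isinstance(dm_or_fm, DistanceMatrix):
        if linkage == "ward" and dm_or_fm.metric != "euclidean":
            raise ValueError("ward linkage requires euclidean feature vectors")
        n = dm_or_fm.n
        Z = _scipy_linkage(squareform(dm_or_fm.values, checks=False), method=linkage)
    else:
        X = _as_array(dm_or_fm)
        n = X.shape[0]
        Z = _scipy_linkage(X, method=linkage)
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return ClusteringResult(
        labels=labels,
        k=int(labels.max()) + 1 if k > 1 else 1,
        algorithm=f"hc_{linkage}",
        diagnostics={"merge_heights": Z[:, 2].tolist()},
    )


def _dtw_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.size, b.size
    D = np.full((n, m), np.inf)
    D[0, 0] = abs(a[0] - b[0])
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, D[i - 1, j])
            if j > 0:
                best = min(best, D[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1])
            D[i, j] = abs(a[i] - b[j]) + best
    return float(D[n - 1, m - 1])


if _HAVE_NUMBA:
    _dtw_jit = _njit(cache=False)(_dtw_py)
else:  # pragma: no cover
    _dtw_jit = _dtw_py


def dtw_distance(a, b) -> float:
    """Unconstrained dynamic time warping with |a_i - b_j| local cost."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires nonempty sequences")
    return float(_dtw_jit(a, b))


def pairwise_dtw(
    cohort: Cohort, variable_weights: Sequence[float] | None = None
) -> DistanceMatrix:
    """Mean over lab variables of per-variable DTW distance between patients."""
    variables = cohort.variable_names
    if variable_weights is None:
        w = np.full(len(variables), 1.0 / len(variables))
    else:
        w = np.asarray(variable_weights, dtype=float)
        if w.size != len(variables):
            raise ValueError("variable_weights length must match roster")
        w = w / w.sum()
    series = []
    for p in cohort.patients:
        by_var = {s.variable: s for s in p.labs}
        row = []
        for v in variables:
            s = by_var.get(v)
            if s is None or s.empty:
                raise ValueError(
                    f"patient {p.patient_id} has no values for {v!r}; impute first"
                )
            row.append(s.values)
        series.append(row)
    n = len(series)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.0
            for v in range(len(variables)):
                d += w[v] * dtw_distance(series[i][v], series[j][v])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, metric="dtw", ids=cohort.patient_ids)


def hc_dtw_cluster(
    cohort: Cohort,
    k: int,
    variable_weights: Sequence[float] | None = None,
    linkage: str = "average",
) -> ClusteringResult:
    """Hierarchical clustering on the per-patient mean-DTW distance matrix."""
    if linkage == "ward":
        raise ValueError("ward linkage is not valid on DTW distances")
    dm = pairwise_dtw(cohort, variable_weights)
    result = hier_cluster(dm, k=k, linkage=linkage)
    result.algorithm = "hc_dtw"
    return result
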