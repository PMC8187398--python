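"""Missingness screening, imputation, and fixed-length feature extraction.

Each patient is reduced to statics plus the per-variable mean and variance of
the full-stay laboratory series; distance-based methods and the autoencoder
consume the standardized (optionally PCA-reduced) matrix.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .synth import Cohort, LabSeries

__all__ = [
    "ScreenReport",
    "FeatureMatrix",
    "screen_patients",
    "daily_grid",
    "rolling_mean_impute",
    "impute_cohort",
    "iterative_impute",
    "extract_features",
    "standardize",
    "reduce_pca",
]


@dataclass
class ScreenReport:
    included_ids: list[str]
    excluded_ids: list[str]
    missing_fraction: dict[str, float]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "included_ids": self.included_ids,
            "excluded_ids": self.excluded_ids,
            "missing_fraction": self.missing_fraction,
        }


@dataclass
class FeatureMatrix:
    """An n x p numeric matrix with named columns and row patient ids."""

    values: np.ndarray
    feature_names: list[str]
    patient_ids: list[str]
    scaling: str = "raw"  # raw | standardized | pca
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal n columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length must equal n rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


def screen_patients(
    cohort: Cohort, threshold: float = 0.10
) -> tuple[Cohort, ScreenReport]:
    """Drop patients whose fraction of never-measured lab variables exceeds ``threshold``.

    The fraction counts variables with an entirely empty series (or absent
    from the patient's lab list) over the cohort roster; gaps inside a
    measured series do not count. Exclusion uses a strict inequality.
    """
    if not cohort.patients:
        raise ValueError("cohort is empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    roster = cohort.variable_names
    if not roster:
        raise ValueError("cohort has no lab variables to screen on")
    fractions: dict[str, float] = {}
    keep, drop = [], []
    for p in cohort.patients:
        measured = {s.variable for s in p.labs if not s.empty}
        n_empty = sum(1 for v in roster if v not in measured)
        frac = n_empty / len(roster)
        fractions[p.patient_id] = frac
        (drop if frac > threshold else keep).append(p)
    screened = Cohort(
        patients=copy.deepcopy(keep),
        variable_names=list(roster),
        config=cohort.config,
    )
    report = ScreenReport(
        included_ids=[p.patient_id for p in keep],
        excluded_ids=[p.patient_id for p in drop],
        missing_fraction=fractions,
        threshold=threshold,
    )
    return screened, report


def daily_grid(horizon_hours: float, step_hours: float = 24.0) -> np.ndarray:
    """Slot start times 0, step, 2*step, ... covering [0, horizon_hours)."""
    if horizon_hours <= 0:
        return np.array([0.0])
    return np.arange(0.0, horizon_hours, step_hours)


def rolling_mean_impute(
    series: LabSeries,
    grid: np.ndarray,
    window: int = 3,
    population_mean: float = np.nan,
) -> LabSeries:
    """Fill empty daily slots with the rolling mean of recent values.

    A grid slot with no observation receives the mean of up to ``window``
    most recent values (observed or previously imputed, in time order);
    slots before the first observation fall back to ``population_mean``.
    Observed measurements are passed through unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if series.empty and not np.isfinite(population_mean):
        raise ValueError(
            f"series {series.variable!r} is empty and population_mean is not finite"
        )
    step = grid[1] - grid[0] if grid.size > 1 else 24.0
    edges = np.append(grid, grid[-1] + step)
    slot_of = np.clip(np.searchsorted(edges, series.times, side="right") - 1,
                      0, grid.size - 1)
    times_out: list[float] = []
    values_out: list[float] = []
    history: list[float] = []
    for s in range(grid.size):
        in_slot = np.nonzero(slot_of == s)[0]
        if in_slot.size:
            for idx in in_slot:
                times_out.append(float(series.times[idx]))
                values_out.append(float(series.values[idx]))
                history.append(float(series.values[idx]))
        else:
            if history:
                fill = float(np.mean(history[-window:]))
            else:
                fill = float(population_mean)
            times_out.append(float(grid[s]))
            values_out.append(fill)
            history.append(fill)
    return LabSeries(series.variable, np.asarray(times_out), np.asarray(values_out))


def impute_cohort(
    cohort: Cohort, window: int = 3, step_hours: float = 24.0
) -> Cohort:
    """Apply rolling-mean imputation per patient and variable over a daily grid.

    Cohort-level per-variable means (pooled over all measured values) serve as
    the cold-start fallback for slots preceding the first observation and for
    entirely empty series.
    """
    pooled: dict[str, list[float]] = {v: [] for v in cohort.variable_names}
    for p in cohort.patients:
        for s in p.labs:
            pooled[s.variable].extend(s.values.tolist())
    pop_mean = {
        v: (float(np.mean(vals)) if vals else np.nan) for v, vals in pooled.items()
    }
    out = copy.deepcopy(cohort)
    for p in out.patients:
        horizon = max(p.outcome.icu_los_days * 24.0, step_hours)
        grid = daily_grid(horizon, step_hours)
        by_var = {s.variable: s for s in p.labs}
        new_labs = []
        for v in cohort.variable_names:
            s = by_var.get(v, LabSeries(v, np.empty(0), np.empty(0)))
            new_labs.append(
                rolling_mean_impute(s, grid, window=window, population_mean=pop_mean[v])
            )
        p.labs = new_labs
    return out


def iterative_impute(
    X: np.ndarray, n_iter: int = 10, seed: int = 0, return_info: bool = False
):
    """Chained-equation style imputation with per-column OLS sweeps.

    Missing cells (NaN) are initialized with the column mean (mode for
    binary columns) and then refined for ``n_iter`` sweeps: each incomplete
    column is regressed on all other columns over its observed rows and its
    missing cells replaced with the fitted predictions. Deterministic.
    """
    X = np.array(X, dtype=float, copy=True)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, q = X.shape
    miss = ~np.isfinite(X)
    if not miss.any():
        return (X, {"max_last_change": 0.0}) if return_info else X
    for j in range(q):
        col_obs = X[~miss[:, j], j]
        if col_obs.size == 0:
            raise ValueError(f"column {j} has no observed values")
        obs_vals = np.unique(col_obs)
        if set(obs_vals.tolist()) <= {0.0, 1.0}:
            init = 1.0 if col_obs.mean() >= 0.5 else 0.0  # mode for binary
        else:
            init = float(col_obs.mean())
        X[miss[:, j], j] = init
    incomplete = [j for j in range(q) if miss[:, j].any()]
    max_change = np.inf
    for _ in range(max(n_iter, 0)):
        max_change = 0.0
        for j in incomplete:
            rows_obs = ~miss[:, j]
            others = np.delete(np.arange(q), j)
            A = np.column_stack([np.ones(int(rows_obs.sum())), X[rows_obs][:, others]])
            beta, *_ = np.linalg.lstsq(A, X[rows_obs, j], rcond=None)
            A_miss = np.column_stack(
                [np.ones(int(miss[:, j].sum())), X[miss[:, j]][:, others]]
            )
            pred = A_miss @ beta
            max_change = max(max_change, float(np.max(np.abs(pred - X[miss[:, j], j]))))
            X[miss[:, j], j] = pred
    if not np.all(np.isfinite(X)):
        raise ValueError("iterative imputation produced non-finite values")
    if return_info:
        return X, {"max_last_change": max_change}
    return X


def extract_features(cohort: Cohort) -> FeatureMatrix:
    """Statics plus per-lab-variable (mean, variance) of the full-stay series.

    Variance uses the n-1 divisor and is defined as 0 for single-measurement
    series. Requires a screened, imputed cohort (no empty series).
    """
    if not cohort.variable_names:
        raise ValueError("cohort has an empty lab-variable roster")
    if not cohort.patients:
        raise ValueError("cohort is empty")
    static_names = cohort.static_names
    names = list(static_names)
    for v in cohort.variable_names:
        names += [f"{v}__mean", f"{v}__var"]
    rows = []
    for p in cohort.patients:
        if set(p.statics.keys()) != set(static_names):
            raise ValueError(f"patient {p.patient_id} has inconsistent static features")
        row = [float(p.statics[s]) for s in static_names]
        by_var = {s.variable: s for s in p.labs}
        for v in cohort.variable_names:
            s = by_var.get(v)
            if s is None or s.empty:
                raise ValueError(
                    f"patient {p.patient_id} variable {v!r} has no values; "
                    "impute before feature extraction"
                )
            row.append(float(np.mean(s.values)))
            row.append(float(np.var(s.values, ddof=1)) if len(s) > 1 else 0.0)
        rows.append(row)
    values = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values after extraction")
    return FeatureMatrix(values, names, cohort.patient_ids, scaling="raw")


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise (x - mean) / SD with population SD; constant columns -> 0."""
    if fm.n < 2:
        raise ValueError("standardize requires n >= 2")
    mu = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0)  # ddof=0 by convention
    safe = np.where(sd > 0, sd, 1.0)
    z = (fm.values - mu) / safe
    z[:, sd == 0] = 0.0
    return FeatureMatrix(
        z, list(fm.feature_names), list(fm.patient_ids), scaling="standardized",
        meta={"center": mu, "scale": sd},
    )


def reduce_pca(fm: FeatureMatrix, n_components: int, seed: int = 0) -> FeatureMatrix:
    """Project the standardized matrix onto its top principal axes.

    Component signs follow the largest-absolute-loading-positive convention,
    which makes the projection deterministic. Explained-variance ratios are
    stored under ``meta['explained_variance_ratio']``.
    """
    if not 1 <= n_components <= min(fm.n, fm.p):
        raise ValueError("n_components out of range")
    base = fm if fm.scaling == "standardized" else standardize(fm)
    X = base.values - base.values.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = X @ Vt[:n_components].T
    ev = S**2
    evr = ev / ev.sum() if ev.sum() > 0 else np.zeros_like(ev)
    return FeatureMatrix(
        scores,
        [f"pc{i + 1}" for i in range(n_components)],
        list(fm.patient_ids),
        scaling="pca",
        meta={
            "explained_variance_ratio": evr[:n_components],
            "components": Vt[:n_components],
        },
    )
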