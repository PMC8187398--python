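"""Per-cluster outcome contrasts: Kaplan-Meier, log-rank, hazard ratios.

The product-limit estimator and the Mantel-Haenszel log-rank tabulation are
implemented directly from their defining formulas (they also supply the O/E
counts the hazard-ratio estimator needs); feature-level contrasts use
one-way ANOVA and Pearson chi-squared without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "HazardEstimate",
    "km_estimate",
    "logrank_test",
    "cluster_hazard_ratios",
    "between_cluster_tests",
]


@dataclass
class SurvivalData:
    times: np.ndarray  # days
    events: np.ndarray  # 1 = death, 0 = censored
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != self.times.shape:
                raise ValueError("groups must match times length")

    def truncated(self, horizon: float) -> "SurvivalData":
        """Administratively censor everything after ``horizon``."""
        t = np.minimum(self.times, horizon)
        e = np.where(self.times <= horizon, self.events, 0)
        return SurvivalData(t, e, self.groups)


@dataclass
class KMCurve:
    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class HazardEstimate:
    cluster: int | str
    hr: float
    ci95: tuple[float, float]
    p_logrank: float
    o_in: float
    e_in: float
    o_out: float
    e_out: float
    defined: bool = True
    note: str = ""


def km_estimate(sd: SurvivalData) -> KMCurve:
    """Product-limit estimator; at tied times deaths precede censorings."""
    if sd.times.size == 0:
        raise ValueError("survival data is empty")
    t, e = sd.times, sd.events
    event_times = np.unique(t[e == 1])
    t_sorted = np.sort(t)
    at_risk = t.size - np.searchsorted(t_sorted, event_times, side="left")
    idx = np.searchsorted(event_times, t[e == 1])
    deaths = np.bincount(idx, minlength=event_times.size)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(
        times=event_times,
        at_risk=at_risk.astype(int),
        events=deaths.astype(int),
        survival=surv,
    )


def _logrank_tables(sd: SurvivalData) -> dict:
    """O/E/V tabulation of the two-group Mantel-Haenszel log-rank test."""
    groups = np.unique(sd.groups)
    if groups.size != 2:
        raise ValueError("logrank_test requires exactly 2 groups")
    g = sd.groups == groups[1]  # group 1 indicator
    t, e = sd.times, sd.events
    event_times = np.unique(t[e == 1])
    t_sorted = np.sort(t)
    t1_sorted = np.sort(t[g])
    n_i = t.size - np.searchsorted(t_sorted, event_times, side="left")
    n1 = t1_sorted.size - np.searchsorted(t1_sorted, event_times, side="left")
    n0 = n_i - n1
    idx = np.searchsorted(event_times, t[e == 1])
    d_i = np.bincount(idx, minlength=event_times.size).astype(float)
    d1 = np.bincount(
        np.searchsorted(event_times, t[(e == 1) & g]), minlength=event_times.size
    ).astype(float)
    d0 = d_i - d1
    E1 = float(np.sum(d_i * n1 / n_i))
    E0 = float(np.sum(d_i * n0 / n_i))
    ok = n_i > 1
    V = float(np.sum(
        d_i[ok] * (n1[ok] / n_i[ok]) * (n0[ok] / n_i[ok])
        * (n_i[ok] - d_i[ok]) / (n_i[ok] - 1)
    ))
    return {"O1": float(d1.sum()), "E1": E1, "O0": float(d0.sum()), "E0": E0,
            "V": V, "n_events": float((e == 1).sum())}


def logrank_test(sd: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""
    tab = _logrank_tables(sd)
    if tab["n_events"] == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    if tab["V"] <= 0:
        return 0.0, 1.0
    chi2 = (tab["O1"] - tab["E1"]) ** 2 / tab["V"]
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cluster_hazard_ratios(
    sd: SurvivalData, labels=None, horizon: float | None = None
) -> list[HazardEstimate]:
    """Per-cluster hazard ratio of the cluster against its complement.

    HR = (O_in/E_in) / (O_out/E_out) from the log-rank O/E tabulation;
    95% CI = exp(log HR +/- 1.96 * sqrt(1/O_in + 1/O_out)). Clusters with
    zero events on either side are flagged undefined, not dropped.
    """
    labels = np.asarray(labels if labels is not None else sd.groups)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters")
    base = sd.truncated(horizon) if horizon is not None else sd
    out = []
    for c in clusters:
        member = (labels == c).astype(int)
        two = SurvivalData(base.times, base.events, member)
        try:
            tab = _logrank_tables(two)
            chi2, p = logrank_test(two)
        except ValueError as exc:
            out.append(HazardEstimate(c, np.nan, (np.nan, np.nan), np.nan,
                                      0, 0, 0, 0, defined=False, note=str(exc)))
            continue
        o_in, e_in = tab["O1"], tab["E1"]
        o_out, e_out = tab["O0"], tab["E0"]
        if o_in == 0 or o_out == 0 or e_in == 0 or e_out == 0:
            out.append(HazardEstimate(c, np.nan, (np.nan, np.nan), p,
                                      o_in, e_in, o_out, e_out, defined=False,
                                      note="zero observed/expected events on one side"))
            continue
        hr = (o_in / e_in) / (o_out / e_out)
        se = np.sqrt(1.0 / o_in + 1.0 / o_out)
        lo, hi = np.exp(np.log(hr) - 1.96 * se), np.exp(np.log(hr) + 1.96 * se)
        out.append(HazardEstimate(c, float(hr), (float(lo), float(hi)), p,
                                  o_in, e_in, o_out, e_out))
    return out


def between_cluster_tests(
    fm, labels, binary_features: list[str] | None = None
) -> pd.DataFrame:
    """One-way ANOVA per continuous feature, chi-squared per binary feature.

    A feature is treated as binary when its observed values are a subset of
    {0, 1} or it is listed in ``binary_features``. Chi-squared uses expected
    counts from the margins and no continuity correction. Zero-variance
    continuous features are skipped with a reason.
    """
    X = np.asarray(getattr(fm, "values", fm), dtype=float)
    names = (
        list(fm.feature_names)
        if hasattr(fm, "feature_names")
        else [f"x{i}" for i in range(X.shape[1])]
    )
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters")
    binary_features = set(binary_features or [])
    rows = []
    for j, name in enumerate(names):
        col = X[:, j]
        is_binary = name in binary_features or set(np.unique(col)) <= {0.0, 1.0}
        if is_binary:
            table = np.array(
                [
                    [np.sum((labels == c) & (col == v)) for v in (0.0, 1.0)]
                    for c in clusters
                ]
            )
            nz = table.sum(axis=0) > 0
            if nz.sum() < 2:
                rows.append((name, "chi2", np.nan, np.nan, "constant binary feature"))
                continue
            chi2, p, _, _ = stats.chi2_contingency(table[:, nz], correction=False)
            rows.append((name, "chi2", float(chi2), float(p), ""))
        else:
            groups = [col[labels == c] for c in clusters]
            if np.var(col) == 0:
                rows.append((name, "anova", np.nan, np.nan, "zero-variance feature"))
                continue
            f, p = stats.f_oneway(*groups)
            rows.append((name, "anova", float(f), float(p), ""))
    return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p", "note"])
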