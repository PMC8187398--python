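"""Seeded synthetic ICU-style cohorts with latent cluster structure.

Generates per-patient static features, irregular laboratory time-series and
survival/outcome labels whose distributions are conditioned on a latent
cluster assignment, so that every downstream stage of the pipeline can be
exercised and scored against known ground truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CohortConfig",
    "LabSeries",
    "OutcomeRecord",
    "PatientRecord",
    "Cohort",
    "generate_cohort",
    "inject_missingness",
    "simulate_survival",
    "DEFAULT_LAB_NAMES",
]

# Routine chemistry / haematology panel plus arterial point-of-care values;
# purely cosmetic defaults for the lab-variable roster.
DEFAULT_LAB_NAMES: tuple[str, ...] = (
    "alat", "asat", "albumin", "amylase", "alp", "bilirubin_total",
    "gamma_gt", "ck", "crp", "calcium", "chloride", "magnesium", "mcv",
    "sodium", "phosphate", "potassium", "fibrinogen", "hemoglobin",
    "hematocrit", "creatinine", "ldh", "leukocytes", "thrombocytes",
    "troponin_t", "total_protein", "urea", "inr",
    "poc_ionized_calcium", "poc_glucose", "poc_hemoglobin", "poc_potassium",
    "poc_lactate", "poc_sodium", "poc_hco3", "poc_pco2", "poc_ph", "poc_po2",
    "poc_saturation", "poc_methb", "poc_hbco",
)

_STATIC_CONTINUOUS_NAMES: tuple[str, ...] = (
    "age", "apache_iv", "saps_ii", "bmi", "heart_rate", "map", "sbp", "dbp",
    "resp_rate", "urine_output_6h", "cvp", "emv_score", "tidal_volume",
    "peep", "cardiac_index", "fio2_lowest",
)

_STATIC_BINARY_NAMES: tuple[str, ...] = (
    "surgical_admission", "previous_icu_admission", "mech_vent_admission",
    "mech_vent_24h", "mottling_severe", "atrial_fibrillation",
    "crt_prolonged", "worsened_resp_24h", "hist_cvd", "hist_ckd",
    "hist_cirrhosis", "hist_copd", "hist_diabetes", "hist_hematological",
    "hist_metastatic", "hist_mi", "hist_resp_insufficiency", "hist_aids",
    "hist_immune_insufficiency", "previous_dialysis",
)


def _named_roster(defaults: Sequence[str], n: int, prefix: str) -> list[str]:
    names = list(defaults[:n])
    names += [f"{prefix}_{i}" for i in range(len(names), n)]
    return names


@dataclass(frozen=True)
class CohortConfig:
    """Parameters controlling the synthetic cohort generator."""

    n_patients: int = 600
    n_clusters: int = 6
    cluster_proportions: tuple[float, ...] | None = None
    n_lab_variables: int = 40
    mean_measurements_per_variable: float = 21.0
    n_static_continuous: int = 8
    n_static_binary: int = 8
    cluster_mean_shift: float = 3.0
    n_informative_features: int = 10
    missing_variable_rate: float = 0.0
    hazard_ratios: tuple[float, ...] | None = None
    baseline_hazard: float = 0.004
    followup_horizons: tuple[float, ...] = (30.0, 90.0)
    aki_probs: tuple[float, ...] | None = None
    mean_los_days: float = 6.0
    outlier_patient_rate: float = 0.0
    outlier_scale: float = 10.0
    noise_skew_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive")
        if self.n_clusters > self.n_patients:
            raise ValueError("n_clusters may not exceed n_patients")
        props = self.cluster_proportions
        if props is None:
            props = tuple([1.0 / self.n_clusters] * self.n_clusters)
            object.__setattr__(self, "cluster_proportions", props)
        if len(props) != self.n_clusters:
            raise ValueError("cluster_proportions length must equal n_clusters")
        if any(p < 0 for p in props):
            raise ValueError("cluster_proportions must be nonnegative")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must sum to 1")
        hrs = self.hazard_ratios
        if hrs is None:
            hrs = tuple([1.0] * self.n_clusters)
            object.__setattr__(self, "hazard_ratios", hrs)
        if len(hrs) != self.n_clusters:
            raise ValueError("hazard_ratios length must equal n_clusters")
        if any(h <= 0 for h in hrs):
            raise ValueError("hazard_ratios must be positive")
        aki = self.aki_probs
        if aki is None:
            aki = tuple([0.3] * self.n_clusters)
            object.__setattr__(self, "aki_probs", aki)
        if len(aki) != self.n_clusters:
            raise ValueError("aki_probs length must equal n_clusters")
        if any(not 0.0 <= a <= 1.0 for a in aki):
            raise ValueError("aki_probs must lie in [0, 1]")
        for name in ("missing_variable_rate", "outlier_patient_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cluster_mean_shift < 0:
            raise ValueError("cluster_mean_shift must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.mean_measurements_per_variable <= 0:
            raise ValueError("mean_measurements_per_variable must be positive")


@dataclass
class LabSeries:
    """One laboratory variable's irregular time-series for one patient."""

    variable: str
    times: np.ndarray  # hours from admission, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing ({self.variable})")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be nonnegative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def empty(self) -> bool:
        return self.times.size == 0


@dataclass
class OutcomeRecord:
    time_to_event_days: float
    event: int
    icu_death: int
    death_30d: int
    death_90d: int
    aki_stage: int
    icu_los_days: float
    rrt: int
    shock: int
    vasoactive: int

    def validate(self) -> None:
        if self.time_to_event_days < 0:
            raise ValueError("time_to_event_days must be nonnegative")
        if self.death_30d and not self.death_90d:
            raise ValueError("death_30d=1 requires death_90d=1")
        if self.death_90d and not self.event:
            raise ValueError("horizon death flags require event=1")
        if self.aki_stage not in (0, 1, 2, 3):
            raise ValueError("aki_stage must be in {0,1,2,3}")


@dataclass
class PatientRecord:
    patient_id: str
    statics: dict[str, float]
    labs: list[LabSeries]
    outcome: OutcomeRecord
    true_cluster: int | None = None

    def lab(self, variable: str) -> LabSeries | None:
        for s in self.labs:
            if s.variable == variable:
                return s
        return None


@dataclass
class Cohort:
    patients: list[PatientRecord]
    variable_names: list[str]
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique")
        roster = set(self.variable_names)
        for p in self.patients:
            for s in p.labs:
                if s.variable not in roster:
                    raise ValueError(
                        f"series variable {s.variable!r} not in cohort roster"
                    )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def static_names(self) -> list[str]:
        return list(self.patients[0].statics.keys()) if self.patients else []

    def true_clusters(self) -> np.ndarray:
        return np.array([p.true_cluster for p in self.patients])


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by rejection."""
    out = rng.poisson(lam, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def _strictly_increasing(times: np.ndarray) -> np.ndarray:
    times = np.sort(times)
    # break exact ties (measure-zero but possible in floats) deterministically
    times += np.arange(times.size) * 1e-9
    return times


def _simplex_offsets(k: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """k cluster-offset vectors in R^m, pairwise equidistant (regular simplex).

    Equidistant centres keep every pair of clusters equally separated, so no
    merge of clusters is privileged when fewer than k groups are requested.
    Requires m >= k - 1; the simplex is randomly rotated so the separation is
    spread over all m features. Rows are scaled to unit pairwise distance.
    """
    if m < k - 1:
        raise ValueError("need at least k-1 informative features for k clusters")
    E = np.eye(k) - 1.0 / k
    # orthonormal basis of the simplex's (k-1)-dim affine hull
    U, S, _ = np.linalg.svd(E, full_matrices=False)
    V = U[:, : k - 1] * S[: k - 1]  # k x (k-1), pairwise distance sqrt(2)
    coords = np.zeros((k, m))
    coords[:, : k - 1] = V / np.sqrt(2.0)
    Q, _ = np.linalg.qr(rng.normal(size=(m, m)))
    return coords @ Q.T


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort, reproducible from ``config.seed``.

    Cluster assignments are multinomial with ``cluster_proportions``; the
    first ``n_informative_features`` lab variables carry cluster-specific
    means (offset scale ``cluster_mean_shift`` in SD units) and variances;
    event times are exponential with cluster-conditional hazards, censored
    administratively at the last follow-up horizon.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, K = cfg.n_patients, cfg.n_clusters
    V = cfg.n_lab_variables
    lab_names = _named_roster(DEFAULT_LAB_NAMES, V, "lab")
    cont_names = _named_roster(_STATIC_CONTINUOUS_NAMES, cfg.n_static_continuous, "static_c")
    bin_names = _named_roster(_STATIC_BINARY_NAMES, cfg.n_static_binary, "comorbidity")

    clusters = rng.choice(K, size=n, p=np.asarray(cfg.cluster_proportions))

    shift = cfg.cluster_mean_shift
    n_info_labs = min(cfg.n_informative_features, V)
    n_info_cont = min(max(cfg.n_informative_features - V, 0), cfg.n_static_continuous)

    # per-(cluster, variable) structure: mean offsets and SD factors
    lab_base_mu = rng.normal(0.0, 1.0, size=V)
    lab_base_sd = np.full(V, 1.0)
    lab_mu = np.tile(lab_base_mu, (K, 1))
    lab_sd = np.tile(lab_base_sd, (K, 1))
    if shift > 0 and n_info_labs:
        # equidistant cluster centres: pairwise distance shift * sqrt(m) in SD
        # units across the informative block (~ shift per informative feature)
        offs = _simplex_offsets(K, n_info_labs, rng) * shift * np.sqrt(n_info_labs)
        lab_mu[:, :n_info_labs] += offs * lab_base_sd[:n_info_labs]
        gate = min(shift, 1.0)
        lab_sd[:, :n_info_labs] *= np.exp(
            0.25 * gate * rng.normal(0.0, 1.0, size=(K, n_info_labs))
        )
    cont_base_mu = rng.normal(0.0, 1.0, size=cfg.n_static_continuous)
    cont_mu = np.tile(cont_base_mu, (K, 1))
    if shift > 0 and n_info_cont:
        cont_mu[:, :n_info_cont] += shift * rng.normal(0.0, 1.0, size=(K, n_info_cont))
    bin_base = rng.uniform(0.1, 0.5, size=cfg.n_static_binary)
    bin_rate = np.tile(bin_base, (K, 1))
    if shift > 0 and cfg.n_static_binary:
        gate = min(shift, 1.0)
        bin_rate = np.clip(
            bin_rate + 0.15 * gate * rng.normal(0.0, 1.0, size=(K, cfg.n_static_binary)),
            0.05, 0.95,
        )

    outlier_mask = rng.random(n) < cfg.outlier_patient_rate
    horizon = max(cfg.followup_horizons)
    hrs = np.asarray(cfg.hazard_ratios)

    patients: list[PatientRecord] = []
    for i in range(n):
        c = int(clusters[i])
        los = max(0.5, rng.exponential(cfg.mean_los_days))
        statics: dict[str, float] = {}
        for j, name in enumerate(cont_names):
            statics[name] = float(rng.normal(cont_mu[c, j], 1.0))
        for j, name in enumerate(bin_names):
            statics[name] = float(rng.random() < bin_rate[c, j])

        labs: list[LabSeries] = []
        for v, name in enumerate(lab_names):
            m = int(_truncated_poisson(rng, cfg.mean_measurements_per_variable, 1)[0])
            times = _strictly_increasing(rng.uniform(0.0, los * 24.0, size=m))
            if cfg.noise_skew_sigma > 0 and v >= n_info_labs:
                # heavy-tailed (lognormal) measurement distribution for the
                # non-informative labs, mimicking skewed clinical markers
                values = np.exp(cfg.noise_skew_sigma * rng.normal(0.0, 1.0, size=m))
            else:
                values = rng.normal(lab_mu[c, v], lab_sd[c, v], size=m)
            if outlier_mask[i] and (v >= n_info_labs or n_info_labs == V):
                # heavy-tailed (clipped-t) contamination of the non-informative
                # labs: outliers dominate the distance geometry while the
                # clip keeps column scales bounded, so standardization cannot
                # collapse the informative bulk structure
                off = float(np.clip(rng.standard_t(3), -5.0, 5.0))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                values = values * cfg.outlier_scale \
                    + sign * (1.0 + abs(off)) * cfg.outlier_scale
            labs.append(LabSeries(name, times, values))

        t_event = rng.exponential(1.0 / (cfg.baseline_hazard * hrs[c]))
        event = int(t_event <= horizon)
        t_obs = min(t_event, horizon)
        aki_severe = rng.random() < cfg.aki_probs[c]
        if aki_severe:
            aki_stage = int(rng.choice([2, 3]))
        else:
            aki_stage = int(rng.choice([0, 1], p=[0.6, 0.4]))
        rrt = int(rng.random() < (0.25 if aki_severe else 0.03))
        shock = int(rng.random() < (0.35 + 0.3 * aki_severe))
        vaso = int(rng.random() < (0.4 + 0.3 * shock))
        outcome = OutcomeRecord(
            time_to_event_days=float(t_obs),
            event=event,
            icu_death=int(event and t_event <= los),
            death_30d=int(t_event <= min(30.0, horizon)),
            death_90d=int(t_event <= horizon),
            aki_stage=aki_stage,
            icu_los_days=float(los),
            rrt=rrt,
            shock=shock,
            vasoactive=vaso,
        )
        outcome.validate()
        patients.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                statics=statics,
                labs=labs,
                outcome=outcome,
                true_cluster=c,
            )
        )

    cohort = Cohort(patients=patients, variable_names=lab_names, config=cfg)
    if cfg.missing_variable_rate > 0:
        cohort = inject_missingness(
            cohort, cfg.missing_variable_rate, seed=cfg.seed + 1
        )
    return cohort


def inject_missingness(cohort: Cohort, rate: float, seed: int) -> Cohort:
    """Empty each patient x variable series independently with probability ``rate``.

    Returns a new cohort; the input is left unmodified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(cohort)
    for p in out.patients:
        for s in p.labs:
            if rng.random() < rate:
                s.times = np.empty(0)
                s.values = np.empty(0)
    return out


def simulate_survival(
    n: int,
    hazards: Sequence[float],
    proportions: Sequence[float] | None = None,
    censor_at: float = 90.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Light-weight grouped exponential survival draws (times, events, groups)."""
    rng = np.random.default_rng(seed)
    hazards = np.asarray(hazards, dtype=float)
    k = hazards.size
    p = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions)
    groups = rng.choice(k, size=n, p=p / p.sum())
    t = rng.exponential(1.0 / hazards[groups])
    events = (t <= censor_at).astype(int)
    times = np.minimum(t, censor_at)
    return times, events, groups
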