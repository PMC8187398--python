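"""End-to-end pipeline driver: screen, impute, extract, cluster, validate,
stabilize, characterize, and contrast outcomes, with a run manifest.

A single master seed fans out deterministically to every stochastic stage, so
two runs with the same configuration produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .baselines import hc_dtw_cluster, hier_cluster, kmeans_cluster
from .characterize import (crossval_classifier, rank_features, select_best_run,
                           shapley_attributions)
from .dec import AutoencoderSpec, run_dec_ensemble, train_dec
from .outcomes import SurvivalData, between_cluster_tests, cluster_hazard_ratios, km_estimate
from .preprocess import extract_features, impute_cohort, screen_patients, standardize
from .synth import Cohort, CohortConfig, generate_cohort
from .validity import select_k, validity_report
from scipy.spatial.distance import pdist, squareform

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

ALGORITHMS = ("kmeans", "hc", "hcdtw", "dec")


@dataclass
class RunConfig:
    out_dir: str
    cohort_dir: str | None = None  # existing three-CSV cohort; else synthesize
    synth: CohortConfig | None = None
    algorithms: tuple[str, ...] = ("kmeans", "hc", "dec")
    k: int | None = None  # fixed k; if None, chosen by select_k
    k_range: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    screen_threshold: float = 0.10
    B: int = 100
    n_runs: int = 100
    n_folds: int = 10
    seed: int = 0
    fast_mode: bool = False

    def __post_init__(self) -> None:
        bad = [a for a in self.algorithms if a not in ALGORITHMS]
        if bad:
            raise ValueError(f"unknown algorithms {bad}; choose from {ALGORITHMS}")
        if not self.algorithms:
            raise ValueError("algorithm set must be nonempty")
        if self.cohort_dir is None and self.synth is None:
            self.synth = CohortConfig(seed=self.seed)

    def effective(self) -> "RunConfig":
        """Fast-mode shrinks the expensive stage budgets."""
        if not self.fast_mode:
            return self
        cfg = RunConfig(**{**asdict_shallow(self)})
        cfg.B = min(self.B, 10)
        cfg.n_runs = min(self.n_runs, 3)
        return cfg


def asdict_shallow(cfg: RunConfig) -> dict:
    d = dict(cfg.__dict__)
    return d


@dataclass
class RunManifest:
    config: dict
    version: str = "0.1.0"
    stages: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, **info) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), **info}

    def add_file(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = digest

    def write(self, path: Path) -> None:
        cfg = dict(self.config)
        if isinstance(cfg.get("synth"), CohortConfig):
            cfg["synth"] = asdict(cfg["synth"])
        path.write_text(json.dumps(
            {"config": cfg, "version": self.version,
             "stages": self.stages, "files": self.files}, indent=1, default=str))


def _dec_spec(cfg: RunConfig, seed: int) -> AutoencoderSpec:
    if cfg.fast_mode:
        return AutoencoderSpec(pretrain_epochs=40, learning_rate=0.05, seed=seed)
    return AutoencoderSpec(seed=seed)


def _dec_train_kwargs(cfg: RunConfig) -> dict:
    if cfg.fast_mode:
        return {"max_iter": 800, "update_interval": 80}
    return {"max_iter": 8000, "update_interval": 140}


def run_pipeline(config: RunConfig) -> RunManifest:
    cfg = config.effective()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict_shallow(config))
    manifest_path = out / "manifest.json"
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("kmeans", "select_k", "dec", "classifier", "shap")}
    written: list[Path] = []

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc_type is not None:
                    manifest.record(name, dt, status="failed", error=str(exc))
                    manifest.write(manifest_path)  # preserve partial manifest
                else:
                    manifest.record(name, dt, status="ok")
                return False

        return _Stage()

    # --- cohort -------------------------------------------------------------
    with stage("cohort"):
        if cfg.cohort_dir is not None:
            d = Path(cfg.cohort_dir)
            cohort = pio.load_cohort(
                d / "statics.csv", d / "labs.csv", d / "outcomes.csv")
        else:
            cohort = generate_cohort(cfg.synth)
            pio.write_cohort(cohort, out / "cohort")

    # --- preprocess ---------------------------------------------------------
    with stage("preprocess"):
        screened, report = screen_patients(cohort, cfg.screen_threshold)
        (out / "screen_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        written.append(out / "screen_report.json")
        imputed = impute_cohort(screened)
        fm_raw = extract_features(imputed)
        fm = standardize(fm_raw)
        df = pd.DataFrame(fm_raw.values, columns=fm_raw.feature_names)
        df.insert(0, "patient_id", fm_raw.patient_ids)
        df.to_csv(out / "features.csv", index=False)
        written.append(out / "features.csv")

    dm_euclid = squareform(pdist(fm.values))

    # --- model selection ----------------------------------------------------
    with stage("select_k"):
        if cfg.k is not None:
            k_star = cfg.k
            stab_reports = {}
        else:
            if "dec" in cfg.algorithms:
                # stability of the DEC labels themselves, as in the analysis
                def _clusterer(values, k, s):
                    _, res, _ = train_dec(
                        values, k, spec=_dec_spec(cfg, s), **_dec_train_kwargs(cfg))
                    return res.labels
            else:
                def _clusterer(values, k, s):
                    return kmeans_cluster(values, k=k, seed=s, n_init=1).labels

            k_star, stab_reports = select_k(
                fm, _clusterer, cfg.k_range, B=cfg.B, seed=seeds["select_k"])
        (out / "stability_report.json").write_text(json.dumps(
            {str(k): r.to_dict() for k, r in stab_reports.items()}, indent=1))
        written.append(out / "stability_report.json")

    # --- clustering ---------------------------------------------------------
    results = {}
    with stage("cluster"):
        if "kmeans" in cfg.algorithms:
            results["kmeans"] = kmeans_cluster(fm, k=k_star, seed=seeds["kmeans"])
        if "hc" in cfg.algorithms:
            results["hc"] = hier_cluster(fm, k=k_star, linkage="ward")
        if "hcdtw" in cfg.algorithms:
            results["hcdtw"] = hc_dtw_cluster(imputed, k=k_star)
        dec_models = None
        if "dec" in cfg.algorithms:
            ensemble = run_dec_ensemble(
                fm, k=k_star, n_runs=cfg.n_runs, base_seed=seeds["dec"],
                spec=_dec_spec(cfg, seeds["dec"]), **_dec_train_kwargs(cfg))
            dec_models = ensemble
            results["dec"] = ensemble[0][1]
        for name, res in results.items():
            df = pd.DataFrame({"patient_id": fm.patient_ids, "label": res.labels})
            df.to_csv(out / f"clusters_{name}.csv", index=False)
            written.append(out / f"clusters_{name}.csv")

    # --- validity -----------------------------------------------------------
    with stage("validity"):
        validity = {
            name: validity_report(dm_euclid, res.labels).to_dict()
            for name, res in results.items()
        }
        (out / "validity_report.json").write_text(json.dumps(validity, indent=1))
        written.append(out / "validity_report.json")

    # --- characterization (DEC runs only) ------------------------------------
    chosen = None
    if dec_models is not None:
        with stage("characterize"):
            hp = {"n_estimators": 50, "max_depth": 3} if cfg.fast_mode else None
            reports = []
            fitted = {}
            for run_id, (_, res) in enumerate(dec_models):
                if np.unique(res.labels).size < 2:
                    continue
                model, rep = crossval_classifier(
                    fm, res.labels, n_folds=cfg.n_folds,
                    seed=seeds["classifier"], hyperparams=hp, run_id=run_id)
                reports.append(rep)
                fitted[run_id] = model
            best = select_best_run(reports)
            chosen = dec_models[best][1]
            (out / "classifier_report.json").write_text(json.dumps(
                {"best_run": best,
                 "runs": [r.to_dict() for r in reports]}, indent=1))
            written.append(out / "classifier_report.json")
            attr = shapley_attributions(
                fitted[best], fm, seed=seeds["shap"],
                max_background=50 if cfg.fast_mode else 100)
            rankings = {
                str(c): [
                    {"feature": f, "mean_abs_shap": m, "direction": d}
                    for f, m, d in rank_features(attr, c, top_m=15)
                ]
                for c in np.unique(chosen.labels)
            }
            (out / "rankings.json").write_text(json.dumps(rankings, indent=1))
            written.append(out / "rankings.json")
    if chosen is None:
        chosen = next(iter(results.values()))

    # --- outcomes -----------------------------------------------------------
    with stage("outcomes"):
        kept = {p.patient_id for p in screened.patients}
        patients = [p for p in cohort.patients if p.patient_id in kept]
        sd = SurvivalData(
            np.array([p.outcome.time_to_event_days for p in patients]),
            np.array([p.outcome.event for p in patients]),
        )
        labels = chosen.labels
        km_rows = []
        for c in np.unique(labels):
            mask = labels == c
            curve = km_estimate(SurvivalData(sd.times[mask], sd.events[mask]))
            for t, nr, d, s in zip(curve.times, curve.at_risk, curve.events,
                                   curve.survival):
                km_rows.append((int(c), float(t), int(nr), int(d), float(s)))
        pd.DataFrame(
            km_rows, columns=["cluster", "time", "at_risk", "events", "survival"]
        ).to_csv(out / "km_curves.csv", index=False)
        written.append(out / "km_curves.csv")

        hr_rows = []
        for horizon in (30.0, 90.0):
            for est in cluster_hazard_ratios(sd, labels, horizon=horizon):
                hr_rows.append((
                    est.cluster, horizon, est.hr, est.ci95[0], est.ci95[1],
                    est.p_logrank, est.defined))
        pd.DataFrame(
            hr_rows,
            columns=["cluster", "horizon_days", "hr", "ci_lo", "ci_hi", "p", "defined"],
        ).to_csv(out / "hazard_table.csv", index=False)
        written.append(out / "hazard_table.csv")

        tests = between_cluster_tests(fm_raw, labels)
        tests.to_csv(out / "tests.csv", index=False)
        written.append(out / "tests.csv")

    for path in written:
        manifest.add_file(path)
    manifest.write(manifest_path)
    for name in manifest.files:  # declared == produced
        assert (out / name).exists()
    return manifest
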