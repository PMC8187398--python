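"""Cohort readers and writers for the three-CSV on-disk layout.

statics.csv   wide: patient_id + one column per static feature
labs.csv      long: patient_id, variable, time_hours, value
outcomes.csv  one row per patient with survival times and event flags
variables.json  declared lab-variable roster (so never-measured variables
                survive a round trip); truth.csv holds generator labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Cohort, CohortConfig, LabSeries, OutcomeRecord, PatientRecord

__all__ = ["write_cohort", "load_cohort"]

_OUTCOME_COLS = [
    "time_to_event_days", "event", "icu_death", "death_30d", "death_90d",
    "aki_stage", "icu_los_days", "rrt", "shock", "vasoactive",
]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write statics/labs/outcomes CSVs plus the roster and truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    static_rows = []
    lab_rows = []
    outcome_rows = []
    truth_rows = []
    for p in cohort.patients:
        static_rows.append({"patient_id": p.patient_id, **p.statics})
        for s in p.labs:
            for t, v in zip(s.times, s.values):
                lab_rows.append(
                    {"patient_id": p.patient_id, "variable": s.variable,
                     "time_hours": t, "value": v}
                )
        outcome_rows.append(
            {"patient_id": p.patient_id,
             **{c: getattr(p.outcome, c) for c in _OUTCOME_COLS}}
        )
        if p.true_cluster is not None:
            truth_rows.append({"patient_id": p.patient_id,
                               "true_cluster": p.true_cluster})
    paths = {
        "statics": out / "statics.csv",
        "labs": out / "labs.csv",
        "outcomes": out / "outcomes.csv",
        "variables": out / "variables.json",
    }
    pd.DataFrame(static_rows).to_csv(paths["statics"], index=False)
    lab_cols = ["patient_id", "variable", "time_hours", "value"]
    pd.DataFrame(lab_rows, columns=lab_cols).to_csv(paths["labs"], index=False)
    pd.DataFrame(outcome_rows).to_csv(paths["outcomes"], index=False)
    paths["variables"].write_text(json.dumps(list(cohort.variable_names), indent=1))
    if truth_rows:
        paths["truth"] = out / "truth.csv"
        pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    return paths


def load_cohort(
    statics_path: str | Path,
    labs_path: str | Path,
    outcomes_path: str | Path,
    variable_names: list[str] | None = None,
) -> Cohort:
    """Read and validate the three-CSV layout back into a Cohort.

    The lab roster is taken from ``variable_names``, else a variables.json
    next to labs.csv, else the set of variables present in labs.csv. Lab rows
    referencing unknown patients or variables, and duplicate timestamps
    within a series, are rejected with the offending identifier.
    """
    statics = pd.read_csv(statics_path)
    labs = pd.read_csv(labs_path)
    outcomes = pd.read_csv(outcomes_path)
    for df, path, cols in (
        (statics, statics_path, ["patient_id"]),
        (labs, labs_path, ["patient_id", "variable", "time_hours", "value"]),
        (outcomes, outcomes_path, ["patient_id", *_OUTCOME_COLS]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")

    ids = statics["patient_id"].astype(str).tolist()
    if len(ids) != len(set(ids)):
        raise ValueError("statics.csv contains duplicate patient ids")
    id_set = set(ids)
    out_ids = set(outcomes["patient_id"].astype(str))
    if out_ids != id_set:
        diff = sorted(id_set ^ out_ids)[:5]
        raise ValueError(f"outcomes/statics patient id mismatch (e.g. {diff})")

    if variable_names is None:
        sidecar = Path(labs_path).with_name("variables.json")
        if sidecar.exists():
            variable_names = json.loads(sidecar.read_text())
        else:
            variable_names = sorted(labs["variable"].astype(str).unique().tolist())
    roster = set(variable_names)

    series_map: dict[str, dict[str, list[tuple[float, float]]]] = {
        pid: {} for pid in ids
    }
    for row_number, row in enumerate(labs.itertuples(index=False), start=2):
        pid = str(row.patient_id)
        if pid not in id_set:
            raise ValueError(
                f"labs.csv row {row_number}: unknown patient_id {pid!r}"
            )
        var = str(row.variable)
        if var not in roster:
            raise ValueError(
                f"labs.csv row {row_number}: unknown variable {var!r}"
            )
        series_map[pid].setdefault(var, []).append(
            (float(row.time_hours), float(row.value))
        )

    outcomes_by_id = {
        str(r["patient_id"]): r for _, r in outcomes.iterrows()
    }
    static_cols = [c for c in statics.columns if c != "patient_id"]
    patients = []
    for _, srow in statics.iterrows():
        pid = str(srow["patient_id"])
        labs_list = []
        for var, pairs in sorted(series_map[pid].items()):
            pairs.sort(key=lambda tv: tv[0])
            times = np.array([t for t, _ in pairs])
            if np.any(np.diff(times) == 0):
                raise ValueError(
                    f"duplicate timestamp for patient {pid!r} variable {var!r}"
                )
            labs_list.append(
                LabSeries(var, times, np.array([v for _, v in pairs]))
            )
        orow = outcomes_by_id[pid]
        outcome = OutcomeRecord(
            time_to_event_days=float(orow["time_to_event_days"]),
            event=int(orow["event"]),
            icu_death=int(orow["icu_death"]),
            death_30d=int(orow["death_30d"]),
            death_90d=int(orow["death_90d"]),
            aki_stage=int(orow["aki_stage"]),
            icu_los_days=float(orow["icu_los_days"]),
            rrt=int(orow["rrt"]),
            shock=int(orow["shock"]),
            vasoactive=int(orow["vasoactive"]),
        )
        outcome.validate()
        patients.append(
            PatientRecord(
                patient_id=pid,
                statics={c: float(srow[c]) for c in static_cols},
                labs=labs_list,
                outcome=outcome,
            )
        )
    return Cohort(patients=patients, variable_names=list(variable_names))
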