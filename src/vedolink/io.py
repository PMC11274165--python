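"""Configuration and tabular input/output.

All tabular data is long-format delimited text (UTF-8, header row, '.'
decimal separator); phases are coded literally t0/t1/t2 and missing
values are empty fields.  Floats are serialized with 9 significant
digits so round trips are lossless at report precision.  Configuration
is YAML with sections that are independently optional; defaults
reproduce the standard model constants and dosing schedule.
"""

from __future__ import annotations

import copy
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clinical_stats import ENDPOINTS, PHASES, PatientRecord
from .pkpd import (
    DAYS_PER_WEEK,
    DEFAULT_DOSE_WEEKS,
    DoseEvent,
    PDParameters,
    PKParameters,
    Trajectory,
)

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "model_from_config",
    "write_trajectory",
    "read_trajectory",
    "write_cohort",
    "read_cohort",
    "write_report",
]

FLOAT_FMT = "%.9g"

DEFAULT_CONFIG: dict = {
    "model": {
        "pk": {"qb": 0.12, "v1": 3.12, "v2": 1.65, "k": 0.0368},
        "pd": {"m0": 2.23e-2, "emax": 0.956, "gamma": 0.3512, "e50": 0.093},
        # week-0 event sets C1 directly to 60 mg/L; later doses add dose_mg/V1
        "schedule": [
            {"week": 0, "c1_increment": 60.0},
            *[{"week": w, "dose_mg": 300.0} for w in DEFAULT_DOSE_WEEKS[1:]],
        ],
        "t_end_day": 364.0,
        "h_day": 0.01,
    },
    "link": {
        "roseburia": {"slope": -0.5750e-3, "intercept": 2.4967e-2},
        "permeability": {"slope": 0.0370e-6, "intercept": 0.9885e-6},
    },
    "analysis": {"tails": "two"},
    "synthetic": {"n_patients": 11, "seed": 0, "target_score_rhi_correlation": 0.75},
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the built-in defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    return _deep_merge(DEFAULT_CONFIG, user)


def model_from_config(config: Mapping) -> tuple[PKParameters, PDParameters, list[DoseEvent], float, float]:
    """Build the simulation inputs from the ``model`` config section."""
    section = config["model"]
    pk = PKParameters(**section["pk"])
    pd_params = PDParameters(**section["pd"])
    schedule = []
    for entry in section["schedule"]:
        time = entry["week"] * DAYS_PER_WEEK if "week" in entry else entry["day"]
        schedule.append(
            DoseEvent(
                time=float(time),
                dose_mg=entry.get("dose_mg"),
                c1_increment=entry.get("c1_increment"),
            )
        )
    return pk, pd_params, schedule, float(section["t_end_day"]), float(section["h_day"])


def write_trajectory(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory frame (optionally with link columns) as CSV."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        times=df["time_day"].to_numpy(),
        c1=df["C1_mg_per_L"].to_numpy(),
        c2=df["C2_mg_per_L"].to_numpy(),
        m=df["M_mg_per_L"].to_numpy(),
    )


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Long-format view: patient_id, disease, therapy, phase, endpoint, value."""
    rows = []
    for rec in records:
        for endpoint in ENDPOINTS:
            data = rec.endpoint(endpoint)
            if not data:
                continue
            for phase in PHASES:
                if phase in data:
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "disease": rec.disease,
                            "therapy": rec.therapy,
                            "phase": phase,
                            "endpoint": endpoint,
                            "value": data[phase],
                        }
                    )
    return pd.DataFrame(rows, columns=["patient_id", "disease", "therapy", "phase", "endpoint", "value"])


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read the long format back into validated patient records."""
    df = pd.read_csv(path)
    required = {"patient_id", "disease", "therapy", "phase", "endpoint", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for pid, group in df.groupby("patient_id", sort=True):
        disease = group["disease"].iloc[0]
        therapy = group["therapy"].iloc[0]
        data: dict[str, dict] = {e: {} for e in ENDPOINTS}
        for row in group.itertuples():
            if row.endpoint not in data:
                raise ValueError(f"unknown endpoint {row.endpoint!r}")
            value = row.value
            if row.endpoint in ("activity", "rhi"):
                value = int(round(value))
            data[row.endpoint][row.phase] = value
        records.append(
            PatientRecord(
                patient_id=int(pid),
                disease=disease,
                therapy=therapy,
                activity_scores=data["activity"],
                rhi=data["rhi"],
                teer=data["teer"] or None,
                pm=data["pm"] or None,
                roseburia=data["roseburia"] or None,
            )
        )
    return records


def _clean(obj):
    """Make a report YAML-serializable (numpy scalars, inf, nan)."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            return "nan"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    return obj


def write_report(report: Mapping, path: str | Path) -> None:
    """Write a study report as YAML (full precision retained)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_clean(dict(report)), fh, sort_keys=False)
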