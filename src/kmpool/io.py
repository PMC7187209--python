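"""CSV/JSON interchange for curves, risk tables, IPD and cohorts.

Formats:
  curve CSV       time_months, survival
  risk-table CSV  time_months, n_at_risk
  IPD CSV         trial_id, arm, patient_id, time_months, event
  cohort CSV      patient_id, age_years, sex, pt_stage, nodes_lt10, site,
                  diff_poor, treated, time_months, event
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .reconstruct import DigitizedCurve, RiskTable, preprocess_curve

__all__ = [
    "read_curve",
    "write_curve",
    "read_risk_table",
    "write_risk_table",
    "read_ipd",
    "write_ipd",
    "read_cohort",
    "write_cohort",
    "write_report",
]

IPD_COLUMNS = ["trial_id", "arm", "patient_id", "time_months", "event"]
COHORT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "pt_stage",
    "nodes_lt10",
    "site",
    "diff_poor",
    "treated",
    "time_months",
    "event",
]


def read_curve(path, arm: str = "") -> DigitizedCurve:
    df = pd.read_csv(path)
    return preprocess_curve(df[["time_months", "survival"]].to_numpy(), arm=arm)


def write_curve(curve: DigitizedCurve, path) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.survival}).to_csv(
        path, index=False
    )


def read_risk_table(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(
        times=df["time_months"].to_numpy(dtype=float),
        n_at_risk=df["n_at_risk"].to_numpy(dtype=int),
    )


def write_risk_table(risk: RiskTable, path) -> None:
    pd.DataFrame({"time_months": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(
        path, index=False
    )


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(IPD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IPD file {path} lacks columns: {sorted(missing)}")
    return df[IPD_COLUMNS]


def write_ipd(ipd: pd.DataFrame, path) -> None:
    ipd[IPD_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} lacks columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    if hasattr(obj, "summary"):
        return _jsonable(obj.summary())
    return str(obj)


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
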