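"""Event-table dataset I/O and run configuration.

Datasets follow the pharmacometric event-table convention: one row per
dose (EVID=1, with AMT mg and DUR h) or observation (EVID=0, with DV
mg/L and MDV=0), plus per-subject covariate columns repeated on every
row.  DUR (infusion duration) is carried instead of an infusion rate
because duration is what the dosing protocol specifies.

Validation is exhaustive, not fail-fast: a malformed file is diagnosed
in one pass with row numbers for every violation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Observation, SubjectRecord
from .covariates import Covariates, classify_renal_function, egfr_schwartz
from .pk import DosingEvent

__all__ = [
    "AnalysisDataset",
    "DatasetValidationError",
    "ConfigError",
    "MANDATORY_COLUMNS",
    "COLUMN_ORDER",
    "cohort_to_dataframe",
    "read_dataset",
    "write_dataset",
    "load_config",
    "require_keys",
    "config_hash",
]

MANDATORY_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "WT")
COLUMN_ORDER = (
    "ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "KIND",
    "WT", "HT", "SCR", "AGE", "PRETERM", "SEX",
    "ALT", "AST", "BUN", "CYSC", "ALB", "TP", "COMED", "EGFR", "GROUP",
)


class DatasetValidationError(ValueError):
    """Carries the full list of violations found in one validation pass."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "dataset validation failed:\n  " + "\n  ".join(self.violations)
        )


class ConfigError(ValueError):
    pass


class AnalysisDataset:
    """A validated event-oriented dosing/observation table."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            violations = self.validate()
            if violations:
                raise DatasetValidationError(violations)

    def validate(self) -> list:
        df = self.df
        v: list[str] = []
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            v.append(f"missing mandatory column(s): {', '.join(missing)}")
            return v
        for row, rec in df.iterrows():
            where = f"row {row + 2}"  # 1-based with header line
            if pd.isna(rec["TIME"]) or rec["TIME"] < 0:
                v.append(f"{where}: negative or missing TIME ({rec['TIME']})")
            if rec["EVID"] not in (0, 1):
                v.append(f"{where}: EVID must be 0 (observation) or 1 (dose)")
            elif rec["EVID"] == 1:
                if pd.isna(rec["AMT"]) or rec["AMT"] <= 0:
                    v.append(f"{where}: dose row needs AMT > 0")
                if pd.isna(rec["DUR"]) or rec["DUR"] <= 0:
                    v.append(f"{where}: dose row needs DUR > 0")
            else:
                if pd.isna(rec["DV"]) or rec["MDV"] not in (0,):
                    v.append(f"{where}: observation row missing DV (or MDV != 0)")
        for sid, grp in df.groupby("ID", sort=False):
            times = grp["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(times) < 0):
                v.append(f"subject {sid}: TIME not nondecreasing")
            if not (grp["EVID"] == 1).any():
                v.append(f"subject {sid}: no dose rows")
            if not (grp["EVID"] == 0).any():
                v.append(f"subject {sid}: no observation rows")
        return v

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def to_subjects(self) -> list:
        """Materialise `SubjectRecord`s for the estimation engine."""
        out = []
        opt = lambda rec, col: (
            None if col not in rec or pd.isna(rec[col]) else float(rec[col])
        )
        for sid, grp in self.df.groupby("ID", sort=False):
            first = grp.iloc[0]
            cov = Covariates(
                wt=float(first["WT"]),
                ht=float(first.get("HT", 50.0) if "HT" in grp.columns else 50.0),
                scr=float(first.get("SCR", 20.0) if "SCR" in grp.columns else 20.0),
                age_months=float(first.get("AGE", 1.0) if "AGE" in grp.columns else 1.0),
                preterm=bool(first.get("PRETERM", 0)) if "PRETERM" in grp.columns else False,
                sex=str(first.get("SEX", "M")) if "SEX" in grp.columns else "M",
                alt=opt(first, "ALT"), ast=opt(first, "AST"), bun=opt(first, "BUN"),
                cysc=opt(first, "CYSC"), alb=opt(first, "ALB"), tp=opt(first, "TP"),
                comed=bool(first.get("COMED", 0)) if "COMED" in grp.columns else False,
            )
            doses = tuple(
                DosingEvent(float(r["TIME"]), float(r["AMT"]), float(r["DUR"]))
                for _, r in grp[grp["EVID"] == 1].iterrows()
            )
            obs = tuple(
                Observation(float(r["TIME"]), float(r["DV"]),
                            str(r["KIND"]) if "KIND" in grp.columns and not pd.isna(r["KIND"]) else "")
                for _, r in grp[grp["EVID"] == 0].iterrows()
            )
            egfr = egfr_schwartz(cov)
            out.append(SubjectRecord(
                id=str(sid), covariates=cov, egfr=egfr,
                group=classify_renal_function(egfr), doses=doses, observations=obs,
            ))
        return out


def cohort_to_dataframe(cohort: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Event table from a simulated cohort (deterministic row/column order)."""
    rows = []
    for s in cohort:
        covd = s.covariates.as_dict()
        base = {**covd, "ID": s.id, "EGFR": round(s.egfr, 6), "GROUP": s.group}
        for ev in s.doses:
            rows.append({**base, "TIME": ev.start_time, "EVID": 1,
                         "AMT": ev.amount, "DUR": ev.duration,
                         "DV": np.nan, "MDV": 1, "KIND": ""})
        for ob in s.observations:
            rows.append({**base, "TIME": ob.time, "EVID": 0, "AMT": np.nan,
                         "DUR": np.nan, "DV": ob.dv, "MDV": 0, "KIND": ob.kind})
    df = pd.DataFrame(rows)
    df = df.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False], kind="stable")
    cols = [c for c in COLUMN_ORDER if c in df.columns]
    return df[cols].reset_index(drop=True)


def write_dataset(cohort_or_dataset, path) -> None:
    """Write an event-table CSV; bit-identical across runs for equal input."""
    if isinstance(cohort_or_dataset, AnalysisDataset):
        df = cohort_or_dataset.df
    elif isinstance(cohort_or_dataset, pd.DataFrame):
        df = cohort_or_dataset
    else:
        df = cohort_to_dataframe(cohort_or_dataset)
    cols = [c for c in COLUMN_ORDER if c in df.columns] + [
        c for c in df.columns if c not in COLUMN_ORDER
    ]
    df[cols].to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_dataset(path) -> AnalysisDataset:
    """Read and validate an event-table CSV."""
    df = pd.read_csv(path, dtype={"ID": str}, keep_default_na=True)
    if "KIND" in df.columns:
        df["KIND"] = df["KIND"].fillna("")
    return AnalysisDataset(df)


# -- configuration -------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"config {path} is not a mapping")
    return dict(cfg)


def require_keys(cfg: Mapping, keys: Sequence[str], where: str = "config") -> None:
    """Schema check that names every missing key."""
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise ConfigError(f"{where} is missing required key(s): {', '.join(missing)}")


def config_hash(cfg: Mapping) -> str:
    """Stable hash of a configuration for the run manifest."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
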