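"""Relational EHR event tables: the common input container for the pipeline.

Five tables, CSV on disk, pandas in memory:

* ``demographics`` — patient_id, birth_year, sex, race, rf_positive, ccp_positive
* ``diagnoses``    — patient_id, date, icd9_code
* ``cdai``         — patient_id, date, cdai_score (0-72 composite disease-activity index)
* ``labs``         — patient_id, date, lab_name (ESR or CRP), value
* ``meds``         — patient_id, date, med_code, med_class

Dates are ISO-8601 strings on disk and ``datetime64[ns]`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

MED_CLASSES = ("csDMARD", "biologic", "tofacitinib", "corticosteroid")
DMARD_CLASSES = ("csDMARD", "biologic", "tofacitinib")
LAB_NAMES = ("ESR", "CRP")

_COLUMNS = {
    "demographics": ["patient_id", "birth_year", "sex", "race", "rf_positive", "ccp_positive"],
    "diagnoses": ["patient_id", "date", "icd9_code"],
    "cdai": ["patient_id", "date", "cdai_score"],
    "labs": ["patient_id", "date", "lab_name", "value"],
    "meds": ["patient_id", "date", "med_code", "med_class"],
}

_DATED = ("diagnoses", "cdai", "labs", "meds")


@dataclass
class EHRTables:
    demographics: pd.DataFrame
    diagnoses: pd.DataFrame
    cdai: pd.DataFrame
    labs: pd.DataFrame
    meds: pd.DataFrame

    def validate(self) -> "EHRTables":
        """Check referential integrity and value ranges; raise ``ValueError`` on violation."""
        for name, cols in _COLUMNS.items():
            df = getattr(self, name)
            if df is None:
                raise ValueError(f"missing table: {name}")
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"table {name!r} lacks columns {missing}")
        known = set(self.demographics["patient_id"])
        for name in _DATED:
            df = getattr(self, name)
            orphans = set(df["patient_id"]) - known
            if orphans:
                raise ValueError(f"table {name!r} has patient_ids absent from demographics: {sorted(orphans)[:5]}")
        if len(self.cdai) and not self.cdai["cdai_score"].between(0, 72).all():
            raise ValueError("cdai_score outside [0, 72]")
        if len(self.meds):
            bad = set(self.meds["med_class"]) - set(MED_CLASSES)
            if bad:
                raise ValueError(f"unknown med_class values: {sorted(bad)}")
        return self

    def is_empty(self) -> bool:
        return all(len(getattr(self, f.name)) == 0 for f in fields(self))

    def copy(self) -> "EHRTables":
        return EHRTables(**{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def write_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in _COLUMNS:
            df = getattr(self, name).copy()
            if "date" in df.columns and len(df):
                df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
            df.to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "EHRTables":
        src = Path(in_dir)
        parts = {}
        for name, cols in _COLUMNS.items():
            path = src / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing table file: {path}")
            df = pd.read_csv(path)
            if "date" in df.columns:
                df["date"] = pd.to_datetime(df["date"])
            parts[name] = df
        return cls(**parts).validate()

    @classmethod
    def empty(cls) -> "EHRTables":
        parts = {}
        for name, cols in _COLUMNS.items():
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            parts[name] = df
        return cls(**parts)
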