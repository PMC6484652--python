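"""Cohort construction: RA inclusion criteria, index-visit selection, outcome labels.

Inclusion requires, per patient: two qualifying ICD-9 diagnosis codes (714.0,
714.1, 714.2) at least 30 days apart, at least one DMARD prescription, at
least two CDAI scores, and at least one inflammation lab (ESR or CRP).  The
*index visit* is the chronologically last CDAI-scored visit; its binary
disease state (controlled, CDAI <= 10, vs uncontrolled) is the forecasting
target, and the penultimate CDAI visit supplies the prior outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .tables import EHRTables, DMARD_CLASSES

logger = logging.getLogger(__name__)

CATEGORIES = ("remission", "low", "moderate", "high")


@dataclass
class InclusionRules:
    qualifying_icd9: frozenset = frozenset({"714.0", "714.1", "714.2"})
    min_code_spacing_days: int = 30
    min_dmard_count: int = 1
    min_cdai_count: int = 2
    required_labs: frozenset = frozenset({"ESR", "CRP"})   # at least one record of any
    min_span_days: int | None = None   # optional extra care-span filter, default off

    def validate(self) -> "InclusionRules":
        if self.min_code_spacing_days < 0:
            raise ValueError("min_code_spacing_days must be >= 0")
        if self.min_dmard_count < 1 or self.min_cdai_count < 1:
            raise ValueError("min_dmard_count and min_cdai_count must be >= 1")
        return self


@dataclass
class CohortMember:
    patient_id: str
    index_date: pd.Timestamp
    index_cdai: float
    prior_date: pd.Timestamp
    prior_cdai: float
    outcome_binary: str            # "controlled" | "uncontrolled"
    outcome_category: str          # remission | low | moderate | high
    prior_outcome_binary: str


def bin_cdai(score: float) -> str:
    """Four-category CDAI disease activity: remission <=2.8 < low <=10 < moderate <=22 < high."""
    if not 0 <= score <= 72:
        raise ValueError(f"CDAI score {score} outside [0, 72]")
    if score <= 2.8:
        return "remission"
    if score <= 10:
        return "low"
    if score <= 22:
        return "moderate"
    return "high"


def label_binary(score: float) -> str:
    """Binary disease state: controlled iff CDAI <= 10."""
    if not 0 <= score <= 72:
        raise ValueError(f"CDAI score {score} outside [0, 72]")
    return "controlled" if score <= 10 else "uncontrolled"


def apply_inclusion(tables: EHRTables, rules: InclusionRules | None = None) -> list[str]:
    """Patient ids passing every inclusion criterion, sorted."""
    rules = (rules or InclusionRules()).validate()
    tables.validate()

    dx = tables.diagnoses
    qual_dx = dx[dx["icd9_code"].astype(str).isin(rules.qualifying_icd9)].copy()
    ok_codes: set[str] = set()
    if len(qual_dx):
        qual_dx["date"] = pd.to_datetime(qual_dx["date"])
        for pid, g in qual_dx.groupby("patient_id", sort=False):
            d = g["date"].sort_values()
            if len(d) >= 2 and (d.iloc[-1] - d.iloc[0]).days >= rules.min_code_spacing_days:
                ok_codes.add(pid)

    meds = tables.meds
    dmard_counts = meds[meds["med_class"].isin(DMARD_CLASSES)].groupby("patient_id").size()
    ok_dmard = set(dmard_counts[dmard_counts >= rules.min_dmard_count].index)

    cdai_counts = tables.cdai.groupby("patient_id").size()
    ok_cdai = set(cdai_counts[cdai_counts >= rules.min_cdai_count].index)

    labs = tables.labs
    ok_labs = set(labs.loc[labs["lab_name"].isin(rules.required_labs), "patient_id"])

    included = ok_codes & ok_dmard & ok_cdai & ok_labs

    if rules.min_span_days is not None and included:
        cd = tables.cdai[tables.cdai["patient_id"].isin(included)].copy()
        cd["date"] = pd.to_datetime(cd["date"])
        span = cd.groupby("patient_id")["date"].agg(lambda s: (s.max() - s.min()).days)
        included &= set(span[span >= rules.min_span_days].index)

    return sorted(included)


def build_cohort(tables: EHRTables, rules: InclusionRules | None = None) -> list[CohortMember]:
    """One :class:`CohortMember` per included patient, sorted by patient_id.

    Two CDAI records on the same date are resolved by keeping the last by
    table order (logged).
    """
    included = apply_inclusion(tables, rules)
    cd = tables.cdai[tables.cdai["patient_id"].isin(included)].copy()
    cd["date"] = pd.to_datetime(cd["date"])

    by_pid = dict(tuple(cd.groupby("patient_id", sort=False))) if len(cd) else {}
    members: list[CohortMember] = []
    for pid in included:
        g = by_pid[pid]
        if g["date"].duplicated().any():
            logger.warning("patient %s has CDAI records sharing a date; keeping last by table order", pid)
            g = g.drop_duplicates(subset="date", keep="last")
        g = g.sort_values("date", kind="stable")
        if len(g) < 2:
            raise RuntimeError(f"patient {pid} passed inclusion but has <2 distinct-date CDAI records")
        idx_row, prior_row = g.iloc[-1], g.iloc[-2]
        members.append(CohortMember(
            patient_id=pid,
            index_date=idx_row["date"],
            index_cdai=float(idx_row["cdai_score"]),
            prior_date=prior_row["date"],
            prior_cdai=float(prior_row["cdai_score"]),
            outcome_binary=label_binary(float(idx_row["cdai_score"])),
            outcome_category=bin_cdai(float(idx_row["cdai_score"])),
            prior_outcome_binary=label_binary(float(prior_row["cdai_score"])),
        ))
    return members


def cohort_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": m.patient_id,
        "index_date": m.index_date,
        "index_cdai": m.index_cdai,
        "prior_date": m.prior_date,
        "prior_cdai": m.prior_cdai,
        "outcome_binary": m.outcome_binary,
        "outcome_category": m.outcome_category,
        "prior_outcome_binary": m.prior_outcome_binary,
    } for m in members])


def frame_to_cohort(df: pd.DataFrame) -> list[CohortMember]:
    return [CohortMember(
        patient_id=r["patient_id"],
        index_date=pd.Timestamp(r["index_date"]),
        index_cdai=float(r["index_cdai"]),
        prior_date=pd.Timestamp(r["prior_date"]),
        prior_cdai=float(r["prior_cdai"]),
        outcome_binary=r["outcome_binary"],
        outcome_category=r["outcome_category"],
        prior_outcome_binary=r["prior_outcome_binary"],
    ) for _, r in df.iterrows()]
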