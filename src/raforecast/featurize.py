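"""Fixed-interval window featurization of each patient's pre-index history.

Time is divided into ``n_windows`` consecutive windows of ``window_days``
counting backward from the index date (window 1 oldest, window ``n`` most
recent).  Within each window only the most recent value of each continuous
variable (CDAI, ESR, CRP) is kept; windows with no value receive the missing
sentinel (zero).  Each medication contributes a per-window 0/1 indicator set
in the window of its chronologically *first* occurrence only.  Five static
variables (age at index, sex, race, RF, anti-CCP) complete the sample.  With
the defaults — 4 windows x (29 DMARDs + 8 corticosteroids + CDAI + ESR + CRP)
+ 5 statics — the flattened feature vector has 165 entries.

The index visit's own CDAI (the label) never enters the features; by default
all index-day events are excluded (the forecast must precede the visit).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortMember
from .synthetic import DMARD_CODES, STEROID_CODES, RACES
from .tables import EHRTables

logger = logging.getLogger(__name__)

DISCARDED = -1
CONTINUOUS_VARS = ("CDAI", "ESR", "CRP")
STATIC_VARS = ("age", "sex", "race", "rf_positive", "ccp_positive")
SEX_CODE = {"F": 1, "M": 0}
RACE_CODE = {r: i for i, r in enumerate(RACES)}


@dataclass
class WindowConfig:
    n_windows: int = 4
    window_days: int = 120
    lookback_cap_days: int | None = None     # default n_windows * window_days
    include_index_day: bool = False
    missing_sentinel: float = 0.0
    med_carry_forward: bool = False          # indicator persists after first-occurrence window

    def validate(self) -> "WindowConfig":
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.window_days <= 0:
            raise ValueError("window_days must be > 0")
        if self.cap <= 0:
            raise ValueError("lookback_cap_days must be > 0")
        return self

    @property
    def cap(self) -> int:
        return self.lookback_cap_days if self.lookback_cap_days is not None \
            else self.n_windows * self.window_days


@dataclass
class FeatureSchema:
    """Column layout of the flattened feature vector: time-varying block then statics."""

    med_codes: tuple[str, ...] = DMARD_CODES + STEROID_CODES
    n_windows: int = 4
    static_vars: tuple[str, ...] = STATIC_VARS

    @property
    def tv_vars(self) -> tuple[str, ...]:
        return self.med_codes + CONTINUOUS_VARS

    @property
    def n_tv(self) -> int:
        return len(self.tv_vars)

    @property
    def total_dim(self) -> int:
        return self.n_windows * self.n_tv + len(self.static_vars)

    @property
    def tv_columns(self) -> list[str]:
        # window-major: all variables of window 1, then window 2, ...
        return [f"{v}@w{w}" for w in range(1, self.n_windows + 1) for v in self.tv_vars]

    @property
    def columns(self) -> list[str]:
        return self.tv_columns + list(self.static_vars)

    def group_map(self) -> dict[str, list[int]]:
        """Variable name -> flattened column indices across all windows (statics: one index)."""
        cols = self.columns
        gm: dict[str, list[int]] = {}
        for v in self.tv_vars:
            gm[v] = [cols.index(f"{v}@w{w}") for w in range(1, self.n_windows + 1)]
        base = self.n_windows * self.n_tv
        for i, v in enumerate(self.static_vars):
            gm[v] = [base + i]
        return gm

    def to_json(self) -> str:
        return json.dumps({"med_codes": list(self.med_codes), "n_windows": self.n_windows,
                           "static_vars": list(self.static_vars)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(med_codes=tuple(d["med_codes"]), n_windows=int(d["n_windows"]),
                   static_vars=tuple(d["static_vars"]))


@dataclass
class FeatureSample:
    patient_id: str
    tv_matrix: np.ndarray        # (n_windows, n_tv)
    static_vec: np.ndarray       # (n_static,)
    label: str
    label_category: str

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.tv_matrix.ravel(), self.static_vec])


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def validate(self) -> "SplitSpec":
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be >= 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        return self


def assign_window(event_date: pd.Timestamp, index_date: pd.Timestamp,
                  cfg: WindowConfig) -> int:
    """Window index in 1..n_windows (1 oldest), or ``DISCARDED``.

    An event ``d`` days before the index maps to ``n - floor(d / window_days)``
    while ``d`` is inside the lookback cap; the index day itself is discarded
    unless ``include_index_day`` (leakage guard).  Events after the index are
    an error.
    """
    d = (pd.Timestamp(index_date) - pd.Timestamp(event_date)).days
    if d < 0:
        raise ValueError(f"event date {event_date} is after index date {index_date}")
    if d == 0 and not cfg.include_index_day:
        return DISCARDED
    if d >= cfg.cap:
        return DISCARDED
    w = cfg.n_windows - d // cfg.window_days
    return int(w)


def reduce_window(values: list[tuple[pd.Timestamp, float]]) -> float | None:
    """Most recent value in a window (ties: last by input order, logged); None if empty."""
    if not values:
        return None
    best_i, best_d = 0, pd.Timestamp(values[0][0])
    tie = False
    for i, (d, _) in enumerate(values[1:], start=1):
        d = pd.Timestamp(d)
        if d > best_d:
            best_i, best_d, tie = i, d, False
        elif d == best_d:
            best_i, tie = i, True
    if tie:
        logger.warning("tied dates within a window; keeping last by table order")
    return float(values[best_i][1])


def encode_medications(med_events: pd.DataFrame, index_date: pd.Timestamp,
                       cfg: WindowConfig, med_codes: tuple[str, ...]) -> np.ndarray:
    """(n_windows, n_codes) 0/1 indicators from each medication's first occurrence.

    Later occurrences of a code are ignored; if ``med_carry_forward`` the
    indicator stays 1 from the first-occurrence window through the last.
    """
    out = np.zeros((cfg.n_windows, len(med_codes)))
    if not len(med_events):
        return out
    ev = med_events.sort_values("date", kind="stable")
    first = ev.drop_duplicates(subset="med_code", keep="first")
    code_ix = {c: j for j, c in enumerate(med_codes)}
    for _, row in first.iterrows():
        j = code_ix.get(row["med_code"])
        if j is None:
            continue
        w = assign_window(row["date"], index_date, cfg)
        if w == DISCARDED:
            continue
        if cfg.med_carry_forward:
            out[w - 1:, j] = 1.0
        else:
            out[w - 1, j] = 1.0
    return out


def assemble(member: CohortMember, tables: EHRTables, cfg: WindowConfig | None = None,
             schema: FeatureSchema | None = None) -> FeatureSample:
    """Build one patient's windowed feature sample from their event history."""
    cfg = (cfg or WindowConfig()).validate()
    schema = schema or FeatureSchema(n_windows=cfg.n_windows)
    if schema.n_windows != cfg.n_windows:
        raise ValueError("schema n_windows does not match window config")
    pid, idx = member.patient_id, member.index_date

    tv = np.full((cfg.n_windows, schema.n_tv), cfg.missing_sentinel, dtype=float)

    # continuous variables: most recent value per window
    cd = tables.cdai[tables.cdai["patient_id"] == pid]
    series = {"CDAI": list(zip(pd.to_datetime(cd["date"]), cd["cdai_score"]))}
    lb = tables.labs[tables.labs["patient_id"] == pid]
    for lab in ("ESR", "CRP"):
        sub = lb[lb["lab_name"] == lab]
        series[lab] = list(zip(pd.to_datetime(sub["date"]), sub["value"]))
    col_of = {v: j for j, v in enumerate(schema.tv_vars)}
    for var, events in series.items():
        per_win: dict[int, list] = {}
        for d, val in events:
            if (idx - d).days < 0:
                continue   # post-index rows may exist in the table; they are not history
            w = assign_window(d, idx, cfg)
            if w != DISCARDED:
                per_win.setdefault(w, []).append((d, val))
        for w, vals in per_win.items():
            red = reduce_window(vals)
            if red is not None:
                tv[w - 1, col_of[var]] = red

    meds = tables.meds[(tables.meds["patient_id"] == pid)]
    meds = meds[pd.to_datetime(meds["date"]) <= idx]
    med_ind = encode_medications(meds, idx, cfg, schema.med_codes)
    tv[:, :len(schema.med_codes)] = med_ind

    demo = tables.demographics[tables.demographics["patient_id"] == pid]
    if not len(demo):
        raise ValueError(f"patient {pid} missing from demographics")
    row = demo.iloc[0]
    age = idx.year - int(row["birth_year"])
    static = np.array([
        float(age),
        float(SEX_CODE.get(row["sex"], 0)),
        float(RACE_CODE.get(row["race"], len(RACE_CODE))),
        float(row["rf_positive"]),
        float(row["ccp_positive"]),
    ])
    return FeatureSample(patient_id=pid, tv_matrix=tv, static_vec=static,
                         label=member.outcome_binary, label_category=member.outcome_category)


def build_matrix(members: list[CohortMember], tables: EHRTables,
                 cfg: WindowConfig | None = None,
                 schema: FeatureSchema | None = None) -> tuple[pd.DataFrame, FeatureSchema]:
    """Feature matrix for a cohort: one flattened row per member plus label columns."""
    cfg = (cfg or WindowConfig()).validate()
    schema = schema or FeatureSchema(n_windows=cfg.n_windows)
    # pre-partition the event tables by patient so assembly is linear overall
    groups = {}
    for name in ("cdai", "labs", "meds", "demographics"):
        df_t = getattr(tables, name).copy()
        if "date" in df_t.columns:
            df_t["date"] = pd.to_datetime(df_t["date"])
        groups[name] = dict(tuple(df_t.groupby("patient_id", sort=False))) if len(df_t) else {}

    def mini(pid: str) -> EHRTables:
        empty = {name: getattr(tables, name).iloc[0:0] for name in
                 ("demographics", "diagnoses", "cdai", "labs", "meds")}
        return EHRTables(
            demographics=groups["demographics"].get(pid, empty["demographics"]),
            diagnoses=empty["diagnoses"],
            cdai=groups["cdai"].get(pid, empty["cdai"]),
            labs=groups["labs"].get(pid, empty["labs"]),
            meds=groups["meds"].get(pid, empty["meds"]),
        )

    samples = [assemble(m, mini(m.patient_id), cfg, schema) for m in members]
    X = np.vstack([s.flatten() for s in samples]) if samples else \
        np.empty((0, schema.total_dim))
    df = pd.DataFrame(X, columns=schema.columns)
    df.insert(0, "patient_id", [s.patient_id for s in samples])
    df["label"] = [s.label for s in samples]
    df["label_category"] = [s.label_category for s in samples]
    return df, schema


def matrix_arrays(df: pd.DataFrame, schema: FeatureSchema) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature matrix frame; y is 1 for uncontrolled."""
    X = df[schema.columns].to_numpy(dtype=float)
    y = (df["label"] == "uncontrolled").to_numpy(dtype=int)
    return X, y


def split(members: list, spec: SplitSpec | None = None,
          labels: list[str] | None = None) -> tuple[list, list, list]:
    """Deterministic stratified train/validation/test partition by patient.

    Stratified on the binary outcome; overall sizes are the rounded fractions
    (test and validation rounded first, train takes the remainder), allocated
    across strata by largest remainder.
    """
    spec = (spec or SplitSpec()).validate()
    n = len(members)
    if n < 3:
        raise ValueError("need at least 3 members to split")
    if labels is None:
        labels = [getattr(m, "outcome_binary") for m in members]
    rng = np.random.default_rng(spec.seed)

    n_val = int(round(spec.fractions[1] * n))
    n_test = int(round(spec.fractions[2] * n))
    n_train = n - n_val - n_test

    strata: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        strata.setdefault(lab, []).append(i)
    for idxs in strata.values():
        rng.shuffle(idxs)

    take = {k: [0, 0, 0] for k in strata}
    for part, target in ((2, n_test), (1, n_val)):
        quotas = {k: target * len(v) / n for k, v in strata.items()}
        base = {k: int(np.floor(q)) for k, q in quotas.items()}
        short = target - sum(base.values())
        for k in sorted(strata, key=lambda k: quotas[k] - base[k], reverse=True)[:short]:
            base[k] += 1
        for k in strata:
            take[k][part] = base[k]

    parts: tuple[list, list, list] = ([], [], [])
    for k, idxs in strata.items():
        n_te, n_va = take[k][2], take[k][1]
        for i in idxs[:n_te]:
            parts[2].append(members[i])
        for i in idxs[n_te:n_te + n_va]:
            parts[1].append(members[i])
        for i in idxs[n_te + n_va:]:
            parts[0].append(members[i])
    assert len(parts[0]) == n_train and len(parts[1]) == n_val and len(parts[2]) == n_test
    return parts


def write_matrix(df: pd.DataFrame, schema: FeatureSchema, out_dir: str | Path,
                 name: str = "features") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    (out / f"{name}_schema.json").write_text(schema.to_json())
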