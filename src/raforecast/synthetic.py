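"""Synthetic EHR generator with persisted ground truth.

Emulates the longitudinal structure of a rheumatology clinic extract: each
patient has an autocorrelated latent disease severity followed across
irregularly spaced visits; CDAI is a calibrated monotone noisy map of that
severity; ESR/CRP are monotone noisy transforms of the same severity subject
to missingness; medication start events arise with a severity-increasing
hazard, and a biologic start lowers subsequent severity.

Two marginal targets are calibrated in closed form:

* ``controlled_target`` — the fraction of visits with CDAI <= 10 — via the
  intercept of the severity->CDAI map, solved on the realized severities;
* ``switch_target`` — the fraction of consecutive visit pairs whose binary
  outcome differs — via the consecutive-visit correlation of the Gaussian
  CDAI process.  For a stationary Gaussian pair with common threshold at the
  ``c`` quantile ``z`` and correlation ``rho``, the switch probability is
  ``4 * T(z, sqrt((1-rho)/(1+rho)))`` with Owen's T function, which is solved
  for ``rho``; the observation-noise share of the CDAI variance then follows
  from ``rho = ar_phi * signal_fraction``.

Because the generative model is linear-Gaussian (up to clipping of CDAI at
0/72 and the log transforms of the labs), the Bayes-optimal forecast of the
next visit's binary outcome is computable by Kalman filtering on the
observed history; :func:`bayes_optimal_scores` provides it as a ceiling
against which trained models can be judged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

from .tables import EHRTables

# Medication code books: 29 DMARDs (15 conventional synthetic, 13 biologic,
# 1 targeted synthetic) and 8 corticosteroids, the first being prednisone.
CSDMARD_CODES = tuple(f"DMARD_{i:02d}" for i in range(1, 16))
BIOLOGIC_CODES = tuple(f"DMARD_{i:02d}" for i in range(16, 29))
TOFACITINIB_CODES = ("DMARD_29",)
DMARD_CODES = CSDMARD_CODES + BIOLOGIC_CODES + TOFACITINIB_CODES
STEROID_CODES = ("prednisone",) + tuple(f"CS_{i:02d}" for i in range(2, 9))
CODE_CLASS = {
    **{c: "csDMARD" for c in CSDMARD_CODES},
    **{c: "biologic" for c in BIOLOGIC_CODES},
    **{c: "tofacitinib" for c in TOFACITINIB_CODES},
    **{c: "corticosteroid" for c in STEROID_CODES},
}

QUALIFYING_ICD9 = ("714.0", "714.1", "714.2")
RACES = ("white", "african_american", "hispanic", "asian", "other")

# Spread (SD) of the unclipped CDAI observation process, in CDAI points.
CDAI_SD = 8.0
# Lab observation noise on the standardized severity scale, and the
# log-scale transforms mapping that latent to positive lab values.
LAB_NOISE_SD = 0.8
ESR_SCALE, ESR_SLOPE = 28.0, 0.45   # mm/h, median ~28
CRP_SCALE, CRP_SLOPE = 5.0, 0.80    # mg/L, median ~5

_NONQUAL_MODES = ("one_code", "codes_close", "no_dmard", "few_cdai", "no_labs")


@dataclass
class HospitalProfile:
    """Generating parameters for one hospital's synthetic cohort."""

    name: str = "hospital"
    n_patients: int = 500
    visit_gap_median_days: float = 100.0
    visit_gap_dispersion: float = 0.45        # SD of log visit gap
    n_visits_median: int = 6
    age_mean_sd: tuple[float, float] = (57.0, 15.0)
    sex_female_prob: float = 0.825
    race_probs: dict[str, float] = field(default_factory=lambda: {
        "white": 0.512, "african_american": 0.057, "hispanic": 0.168,
        "asian": 0.175, "other": 0.088,
    })
    med_propensity: dict[str, float] = field(default_factory=lambda: {
        "csDMARD": 0.924, "biologic": 0.630, "tofacitinib": 0.050,
        "corticosteroid": 0.500,
    })
    controlled_target: float = 0.60
    switch_target: float = 0.25
    lab_missing_prob: dict[str, float] = field(default_factory=lambda: {"ESR": 0.30, "CRP": 0.30})
    ar_mu: float = 0.0
    ar_phi: float = 0.95
    ar_sigma: float = 0.31225    # innovation SD; stationary SD ~1 at phi=0.95
    treatment_effect: float = 0.15   # severity drop (stationary-SD units) while on a biologic
    nonqualifying_frac: float = 0.10
    seed: int = 0

    def validate(self) -> "HospitalProfile":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.visit_gap_median_days <= 0:
            raise ValueError("visit_gap_median_days must be > 0")
        if self.visit_gap_dispersion <= 0:
            raise ValueError("visit_gap_dispersion must be > 0")
        if not 0 <= self.sex_female_prob <= 1:
            raise ValueError("sex_female_prob must be in [0, 1]")
        for nm, p in [("controlled_target", self.controlled_target),
                      ("switch_target", self.switch_target),
                      ("nonqualifying_frac", self.nonqualifying_frac)]:
            if not 0 <= p <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValueError("race_probs must sum to 1")
        for k, v in self.med_propensity.items():
            if not 0 <= v <= 1:
                raise ValueError(f"med_propensity[{k!r}] must be in [0, 1]")
        for k, v in self.lab_missing_prob.items():
            if not 0 <= v <= 1:
                raise ValueError(f"lab_missing_prob[{k!r}] must be in [0, 1]")
        if not 0 <= self.ar_phi < 1:
            raise ValueError("ar_phi must be in [0, 1)")
        if self.ar_sigma < 0:
            raise ValueError("ar_sigma must be >= 0")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "HospitalProfile":
        d = dict(d)
        if "age_mean_sd" in d:
            d["age_mean_sd"] = tuple(d["age_mean_sd"])
        return cls(**d).validate()


def uh_profile(n_patients: int = 578, seed: int = 0, **overrides) -> HospitalProfile:
    """University-hospital-like cohort: frequent visits, broad treatment mix."""
    return HospitalProfile(name="UH", n_patients=n_patients, seed=seed, **overrides).validate()


def snh_profile(n_patients: int = 242, seed: int = 1, **overrides) -> HospitalProfile:
    """Safety-net-hospital-like cohort: sparser visits, narrower treatment mix."""
    defaults = dict(
        visit_gap_median_days=180.0,
        n_visits_median=4,
        age_mean_sd=(60.0, 15.0),
        sex_female_prob=0.806,
        race_probs={"white": 0.124, "african_american": 0.079, "hispanic": 0.368,
                    "asian": 0.289, "other": 0.140},
        med_propensity={"csDMARD": 0.789, "biologic": 0.289, "tofacitinib": 0.0,
                        "corticosteroid": 0.500},
        lab_missing_prob={"ESR": 0.40, "CRP": 0.40},
    )
    defaults.update(overrides)
    return HospitalProfile(name="SNH", n_patients=n_patients, seed=seed, **defaults).validate()


@dataclass
class GroundTruth:
    """Per-visit latent state and the realized calibration of a generated cohort."""

    visits: pd.DataFrame          # patient_id, visit_index, date, severity, active_biologic, cdai, esr, crp
    patients: pd.DataFrame        # patient_id, qualifying, nonqualifying_mode
    profile: HospitalProfile
    calibration: dict             # slope/intercept/noise of the severity->CDAI map etc.
    realized_controlled_fraction: float
    realized_switch_rate: float

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        v = self.visits.copy()
        if len(v):
            v["date"] = pd.to_datetime(v["date"]).dt.strftime("%Y-%m-%d")
        v.to_csv(out / "ground_truth_visits.csv", index=False)
        self.patients.to_csv(out / "ground_truth_patients.csv", index=False)
        meta = {
            "profile": dataclasses.asdict(self.profile),
            "calibration": self.calibration,
            "realized_controlled_fraction": self.realized_controlled_fraction,
            "realized_switch_rate": self.realized_switch_rate,
        }
        (out / "profile.json").write_text(json.dumps(meta, indent=2, default=list))


def consecutive_corr_for_switch(controlled: float, switch: float) -> float:
    """Correlation of consecutive Gaussian CDAI values that realizes a switch rate.

    Both visits are controlled with marginal probability ``controlled``; the
    switch probability of the thresholded pair is ``4*T(z, sqrt((1-rho)/(1+rho)))``.
    """
    if not 0 < controlled < 1:
        raise ValueError("controlled_target must be in (0, 1) for calibration")
    z = norm.ppf(controlled)

    def gap(rho: float) -> float:
        a = np.sqrt((1 - rho) / (1 + rho))
        return 4.0 * owens_t(z, a) - switch

    if gap(0.9999) > 0:
        raise ValueError("switch_target too small to realize with any correlation < 1")
    if gap(-0.9999) < 0:
        raise ValueError("switch_target too large to realize")
    return brentq(gap, -0.9999, 0.9999, xtol=1e-10)


def _solve_cdai_intercept(scaled_sev: np.ndarray, noise_sd: float, controlled: float) -> float:
    """Intercept b with mean_i Phi((10 - scaled_sev_i - b)/noise_sd) = controlled."""
    if noise_sd == 0:
        return 10.0 - float(np.quantile(scaled_sev, controlled))

    def gap(b: float) -> float:
        return float(np.mean(norm.cdf((10.0 - scaled_sev - b) / noise_sd))) - controlled

    lo = 10.0 - float(scaled_sev.max()) - 8 * noise_sd
    hi = 10.0 - float(scaled_sev.min()) + 8 * noise_sd
    return brentq(gap, lo, hi, xtol=1e-9)


def generate(profile: HospitalProfile, seed: int | None = None) -> tuple[EHRTables, GroundTruth]:
    """Generate the five EHR tables and their ground truth for one hospital.

    Deterministic given ``(profile, seed)``; ``seed`` defaults to ``profile.seed``.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n = profile.n_patients
    extract = pd.Timestamp("2017-07-01")

    if n == 0:
        return EHRTables.empty(), GroundTruth(
            visits=pd.DataFrame(columns=["patient_id", "visit_index", "date", "severity",
                                         "active_biologic", "cdai", "esr", "crp"]),
            patients=pd.DataFrame(columns=["patient_id", "qualifying", "nonqualifying_mode"]),
            profile=profile, calibration={}, realized_controlled_fraction=float("nan"),
            realized_switch_rate=float("nan"))

    phi, sig, mu = profile.ar_phi, profile.ar_sigma, profile.ar_mu
    tau = sig / np.sqrt(1 - phi ** 2) if sig > 0 else 0.0

    if sig > 0:
        rho = consecutive_corr_for_switch(profile.controlled_target, profile.switch_target)
        lam = rho / phi if phi > 0 else np.nan
        if not 0 < lam <= 1:
            raise ValueError(
                f"ar_phi={phi} cannot realize switch_target={profile.switch_target}: "
                f"required consecutive correlation {rho:.3f} exceeds ar_phi")
        g = CDAI_SD * np.sqrt(lam) / tau          # CDAI points per severity unit
        cdai_noise = CDAI_SD * np.sqrt(1 - lam)
    else:
        g, cdai_noise, lam, rho = 1.0, 0.0, 1.0, phi

    # --- patient-level draws -------------------------------------------------
    pids = [f"{profile.name}-{i:05d}" for i in range(n)]
    n_nq = int(round(profile.nonqualifying_frac * n))
    nq_idx = rng.choice(n, size=n_nq, replace=False) if n_nq else np.array([], dtype=int)
    nq_mode = {int(i): _NONQUAL_MODES[int(rng.integers(len(_NONQUAL_MODES)))] for i in nq_idx}

    demo_rows, dx_rows, cdai_rows, lab_rows, med_rows, visit_rows = [], [], [], [], [], []
    per_patient = []   # (pid, visit_dates, sev_effective, active_flags, mode)

    race_names = list(profile.race_probs)
    race_p = np.array([profile.race_probs[r] for r in race_names])
    miss = {"ESR": profile.lab_missing_prob.get("ESR", 0.0),
            "CRP": profile.lab_missing_prob.get("CRP", 0.0)}

    for i, pid in enumerate(pids):
        mode = nq_mode.get(i)
        n_visits = 2 + int(rng.poisson(max(profile.n_visits_median - 2, 0)))
        gaps = rng.lognormal(np.log(profile.visit_gap_median_days),
                             profile.visit_gap_dispersion, n_visits - 1)
        index_date = extract - pd.Timedelta(days=int(rng.integers(0, 91)))
        offsets = np.concatenate([[0.0], np.cumsum(gaps[::-1])])[::-1]  # oldest first
        dates = [index_date - pd.Timedelta(days=float(round(d))) for d in offsets]

        # latent severity AR(1), stationary start
        s = np.empty(n_visits)
        s[0] = mu + (rng.normal(0, tau) if tau > 0 else 0.0)
        for t in range(1, n_visits):
            s[t] = mu + phi * (s[t - 1] - mu) + (rng.normal(0, sig) if sig > 0 else 0.0)

        # medications: per class, ever-user Bernoulli, start visit with
        # severity-increasing weight, refills afterwards
        sev_std = (s - mu) / tau if tau > 0 else np.zeros(n_visits)
        class_codes = {"csDMARD": CSDMARD_CODES, "biologic": BIOLOGIC_CODES,
                       "tofacitinib": TOFACITINIB_CODES, "corticosteroid": STEROID_CODES}
        starts: list[tuple[int, str]] = []
        for cls_name, codes in class_codes.items():
            if rng.random() >= profile.med_propensity.get(cls_name, 0.0):
                continue
            w = np.exp(0.7 * sev_std)
            k = int(rng.choice(n_visits, p=w / w.sum()))
            n_codes = 1 + (rng.random() < 0.35)
            for code in rng.choice(codes, size=min(n_codes, len(codes)), replace=False):
                starts.append((k, str(code)))
        has_dmard = any(CODE_CLASS[c] != "corticosteroid" for _, c in starts)
        if not has_dmard and mode != "no_dmard":
            w = np.exp(0.7 * sev_std)
            k = int(rng.choice(n_visits, p=w / w.sum()))
            starts.append((k, str(rng.choice(CSDMARD_CODES))))
        if mode == "no_dmard":
            starts = [(k, c) for k, c in starts if CODE_CLASS[c] == "corticosteroid"]

        # biologic activity lowers severity from the visit after the start
        bio_starts = [k for k, c in starts if CODE_CLASS[c] in ("biologic", "tofacitinib")]
        active = np.zeros(n_visits, dtype=bool)
        if bio_starts:
            active[min(bio_starts) + 1:] = True
        sev = s - profile.treatment_effect * active

        for k, code in starts:
            med_rows.append((pid, dates[k], code, CODE_CLASS[code]))
            for t in range(k + 1, n_visits):
                if rng.random() < 0.4:
                    med_rows.append((pid, dates[t], code, CODE_CLASS[code]))

        # CDAI observations (intercept solved globally afterwards)
        cdai_part = g * sev + rng.normal(0, cdai_noise, n_visits) if cdai_noise > 0 else g * sev

        # labs
        esr = np.full(n_visits, np.nan)
        crp = np.full(n_visits, np.nan)
        sev_std_eff = (sev - mu) / tau if tau > 0 else np.zeros(n_visits)
        for t in range(n_visits):
            if rng.random() >= miss["ESR"]:
                esr[t] = ESR_SCALE * np.exp(ESR_SLOPE * (sev_std_eff[t] + rng.normal(0, LAB_NOISE_SD)))
            if rng.random() >= miss["CRP"]:
                crp[t] = CRP_SCALE * np.exp(CRP_SLOPE * (sev_std_eff[t] + rng.normal(0, LAB_NOISE_SD)))
        if mode == "no_labs":
            esr[:], crp[:] = np.nan, np.nan

        # demographics
        age = float(np.clip(rng.normal(*profile.age_mean_sd), 18, 95))
        sex = "F" if rng.random() < profile.sex_female_prob else "M"
        race = race_names[int(rng.choice(len(race_names), p=race_p))]
        sero_shift = 0.15 * np.tanh(float(sev_std.mean()))
        rf = int(rng.random() < np.clip(0.72 + sero_shift, 0, 1))
        ccp = int(rng.random() < np.clip(0.62 + sero_shift, 0, 1))
        demo_rows.append((pid, int(index_date.year - round(age)), sex, race, rf, ccp))

        # diagnoses
        d1 = dates[0]
        if mode == "one_code":
            dx_rows.append((pid, d1, str(rng.choice(QUALIFYING_ICD9))))
        elif mode == "codes_close":
            dx_rows.append((pid, d1, str(rng.choice(QUALIFYING_ICD9))))
            dx_rows.append((pid, d1 + pd.Timedelta(days=int(rng.integers(1, 30))),
                            str(rng.choice(QUALIFYING_ICD9))))
        else:
            d2 = d1 + pd.Timedelta(days=30 + int(round(rng.exponential(90))))
            dx_rows.append((pid, d1, str(rng.choice(QUALIFYING_ICD9))))
            dx_rows.append((pid, min(d2, index_date), str(rng.choice(QUALIFYING_ICD9))))

        per_patient.append((pid, dates, sev, active, cdai_part, esr, crp, mode))

    # --- global CDAI intercept calibration -----------------------------------
    # Solved on the realized index-visit severities of qualifying patients so
    # that the expected controlled fraction of the forecast labels equals the
    # target even under treatment shifts and finite-sample severity draws.
    qual_scaled = [g * sv[-1] for (_, _, sv, _, _, _, _, m) in per_patient if m is None]
    scaled_all = np.asarray(qual_scaled if qual_scaled
                            else [g * sv[-1] for (_, _, sv, _, _, _, _, _) in per_patient])
    if sig > 0:
        b = _solve_cdai_intercept(scaled_all, cdai_noise, profile.controlled_target)
    else:
        b = 10.0 - norm.ppf(min(max(profile.controlled_target, 1e-9), 1 - 1e-9)) * CDAI_SD - g * mu

    for pid, dates, sev, active, cdai_part, esr, crp, mode in per_patient:
        cdai = np.clip(np.round(cdai_part + b, 1), 0.0, 72.0)
        nv = len(dates)
        keep_cdai = [nv - 1] if mode == "few_cdai" else list(range(nv))
        for t in keep_cdai:
            cdai_rows.append((pid, dates[t], float(cdai[t])))
        for t in range(nv):
            if np.isfinite(esr[t]):
                lab_rows.append((pid, dates[t], "ESR", float(round(esr[t], 1))))
            if np.isfinite(crp[t]):
                lab_rows.append((pid, dates[t], "CRP", float(round(crp[t], 1))))
            visit_rows.append((pid, t, dates[t], float(sev[t]), bool(active[t]),
                               float(cdai[t]),
                               float(round(esr[t], 1)) if np.isfinite(esr[t]) else np.nan,
                               float(round(crp[t], 1)) if np.isfinite(crp[t]) else np.nan))

    tables = EHRTables(
        demographics=pd.DataFrame(demo_rows, columns=["patient_id", "birth_year", "sex", "race",
                                                      "rf_positive", "ccp_positive"]),
        diagnoses=pd.DataFrame(dx_rows, columns=["patient_id", "date", "icd9_code"]),
        cdai=pd.DataFrame(cdai_rows, columns=["patient_id", "date", "cdai_score"]),
        labs=pd.DataFrame(lab_rows, columns=["patient_id", "date", "lab_name", "value"]),
        meds=pd.DataFrame(med_rows, columns=["patient_id", "date", "med_code", "med_class"]),
    ).validate()

    visits = pd.DataFrame(visit_rows, columns=["patient_id", "visit_index", "date", "severity",
                                               "active_biologic", "cdai", "esr", "crp"])
    patients = pd.DataFrame({
        "patient_id": pids,
        "qualifying": [i not in nq_mode for i in range(n)],
        "nonqualifying_mode": [nq_mode.get(i, "") for i in range(n)],
    })

    qual_ids = set(patients.loc[patients["qualifying"], "patient_id"])
    qv = visits[visits["patient_id"].isin(qual_ids)]
    controlled = (qv["cdai"] <= 10).to_numpy()
    grp = qv.groupby("patient_id", sort=False)["cdai"].apply(lambda s: (s.to_numpy() <= 10))
    switches, pairs = 0, 0
    for arr in grp:
        if len(arr) > 1:
            switches += int((arr[1:] != arr[:-1]).sum())
            pairs += len(arr) - 1

    calibration = {
        "cdai_slope": float(g), "cdai_intercept": float(b), "cdai_noise_sd": float(cdai_noise),
        "signal_fraction": float(lam), "consecutive_corr": float(rho),
        "stationary_sd": float(tau),
        "esr": {"scale": ESR_SCALE, "slope": ESR_SLOPE, "noise_sd": LAB_NOISE_SD},
        "crp": {"scale": CRP_SCALE, "slope": CRP_SLOPE, "noise_sd": LAB_NOISE_SD},
    }
    truth = GroundTruth(
        visits=visits, patients=patients, profile=profile, calibration=calibration,
        realized_controlled_fraction=float(controlled.mean()) if len(controlled) else float("nan"),
        realized_switch_rate=float(switches / pairs) if pairs else float("nan"),
    )
    return tables, truth


def check_marginals(tables: EHRTables, truth: GroundTruth, targets: HospitalProfile,
                    tol_rate: float = 0.03, tol_gap_days: float = 15.0,
                    tol_med: float = 0.07) -> dict:
    """Compare realized cohort marginals with the profile's targets.

    Returns ``{quantity: {"value": ..., "target": ..., "tol": ..., "ok": bool}}``.
    """
    if tables.is_empty():
        raise ValueError("cannot check marginals of empty tables")
    qual_ids = set(truth.patients.loc[truth.patients["qualifying"], "patient_id"])
    cd = tables.cdai[tables.cdai["patient_id"].isin(qual_ids)].copy()
    cd["date"] = pd.to_datetime(cd["date"])

    report = {}

    def entry(name, value, target, tol):
        report[name] = {"value": float(value), "target": float(target), "tol": float(tol),
                        "ok": bool(abs(value - target) <= tol)}

    entry("controlled_fraction", truth.realized_controlled_fraction,
          targets.controlled_target, tol_rate)
    entry("switch_rate", truth.realized_switch_rate, targets.switch_target, tol_rate)

    gaps = []
    for _, gdf in cd.sort_values("date").groupby("patient_id", sort=False):
        d = gdf["date"].to_numpy()
        if len(d) > 1:
            gaps.extend(np.diff(d).astype("timedelta64[D]").astype(float))
    entry("median_visit_gap_days", float(np.median(gaps)) if gaps else float("nan"),
          targets.visit_gap_median_days, tol_gap_days)

    meds = tables.meds[tables.meds["patient_id"].isin(qual_ids)]
    n_q = max(len(qual_ids), 1)
    for cls_name, target in targets.med_propensity.items():
        frac = meds.loc[meds["med_class"] == cls_name, "patient_id"].nunique() / n_q
        entry(f"med_prevalence_{cls_name}", frac, target, tol_med)

    report["all_ok"] = all(v["ok"] for v in report.values() if isinstance(v, dict))
    return report


def bayes_optimal_scores(truth: GroundTruth) -> pd.DataFrame:
    """Bayes-optimal probability of an uncontrolled index visit, per qualifying patient.

    Kalman-filters the latent severity from each patient's observed pre-index
    history (CDAI, non-missing ESR/CRP, biologic activity — all functions of
    the generative model the generator itself used) and returns the exact
    one-step-ahead ``P(CDAI > 10)``.  CDAI values clipped at 0 or 72 are
    treated as exact observations, a slight approximation that only lowers
    the resulting AUROC.  Columns: patient_id, score, label (1 = uncontrolled).
    """
    cal, prof = truth.calibration, truth.profile
    if not cal:
        raise ValueError("ground truth has no calibration (empty cohort?)")
    phi, mu = prof.ar_phi, prof.ar_mu
    tau = cal["stationary_sd"]
    g, b, sd_c = cal["cdai_slope"], cal["cdai_intercept"], cal["cdai_noise_sd"]
    te = prof.treatment_effect
    qual = set(truth.patients.loc[truth.patients["qualifying"], "patient_id"])

    rows = []
    for pid, v in truth.visits.groupby("patient_id", sort=True):
        if pid not in qual or len(v) < 2:
            continue
        v = v.sort_values("visit_index")
        cdai = v["cdai"].to_numpy()
        esr = v["esr"].to_numpy()
        crp = v["crp"].to_numpy()
        act = v["active_biologic"].to_numpy().astype(float)
        T = len(v)
        m, P = mu, tau ** 2      # prior on the *base* (pre-treatment) severity
        for t in range(T - 1):
            obs = []
            if sd_c > 0:
                obs.append(((cdai[t] - b) / g + te * act[t], (sd_c / g) ** 2))
            for val, pars in ((esr[t], cal["esr"]), (crp[t], cal["crp"])):
                if np.isfinite(val) and val > 0 and tau > 0:
                    u = np.log(val / pars["scale"]) / pars["slope"]
                    obs.append((mu + tau * u + te * act[t], (tau * pars["noise_sd"]) ** 2))
            for y, r_var in obs:
                k_gain = P / (P + r_var)
                m = m + k_gain * (y - m)
                P = (1 - k_gain) * P
            m = mu + phi * (m - mu)
            P = phi ** 2 * P + (prof.ar_sigma ** 2)
        sev_next_mean = m - te * act[T - 1]
        pred_sd = np.sqrt(g ** 2 * P + sd_c ** 2)
        score = 1.0 - norm.cdf((10.0 - b - g * sev_next_mean) / pred_sd) if pred_sd > 0 \
            else float(g * sev_next_mean + b > 10.0)
        rows.append((pid, float(score), int(cdai[T - 1] > 10)))
    return pd.DataFrame(rows, columns=["patient_id", "score", "label"])
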