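"""End-to-end experiment driver: generate -> cohort -> featurize -> train -> evaluate -> transfer.

A single :class:`ExperimentConfig` (constructible from YAML/JSON) fans one
global seed out to every stage through named substreams, so a run is
reproducible bit-for-bit.  The transfer arm mirrors the three cross-hospital
strategies: train natively on the small target cohort, apply the
source-trained model directly to the target test set, and fine-tune the
source model on the target training set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import InclusionRules, build_cohort, cohort_to_frame
from .evaluate import (auroc, confident_wrong, confusion_plot, delong_ci, learning_curve,
                       permutation_importance, pis_frame, subgroup_performance)
from .featurize import FeatureSchema, SplitSpec, WindowConfig, build_matrix, matrix_arrays, split
from .models import (ChangePosteriorClassifier, DenseForecaster, Hyperparams,
                     OutcomePosteriorClassifier, RecurrentForecaster, fine_tune)
from .synthetic import HospitalProfile, check_marginals, generate

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (named substream), below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class ExperimentConfig:
    source_profile: HospitalProfile = field(default_factory=HospitalProfile)
    target_profile: HospitalProfile | None = None
    rules: InclusionRules = field(default_factory=InclusionRules)
    window: WindowConfig = field(default_factory=WindowConfig)
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    split_spec: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 0
    out_dir: str = "experiment_out"
    pis_repeats: int = 0                   # 0 disables the permutation-importance table
    pis_groups: list[str] | None = None
    learning_curve_sizes: list[int] | None = None
    learning_curve_repeats: int = 2
    finetune_epochs: tuple[int, int] = (30, 30)
    tsne: bool = False
    write_artifacts: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "source_profile" in d and isinstance(d["source_profile"], dict):
            d["source_profile"] = HospitalProfile.from_dict(d["source_profile"])
        if d.get("target_profile") and isinstance(d["target_profile"], dict):
            d["target_profile"] = HospitalProfile.from_dict(d["target_profile"])
        if "rules" in d and isinstance(d["rules"], dict):
            r = dict(d["rules"])
            if "qualifying_icd9" in r:
                r["qualifying_icd9"] = frozenset(r["qualifying_icd9"])
            if "required_labs" in r:
                r["required_labs"] = frozenset(r["required_labs"])
            d["rules"] = InclusionRules(**r)
        if "window" in d and isinstance(d["window"], dict):
            d["window"] = WindowConfig(**d["window"])
        if "hyperparams" in d and isinstance(d["hyperparams"], dict):
            h = dict(d["hyperparams"])
            for k in ("gru_units", "dense_units"):
                if k in h:
                    h[k] = tuple(h[k])
            d["hyperparams"] = Hyperparams(**h)
        if "split_spec" in d and isinstance(d["split_spec"], dict):
            s = dict(d["split_spec"])
            if "fractions" in s:
                s["fractions"] = tuple(s["fractions"])
            d["split_spec"] = SplitSpec(**s)
        if "finetune_epochs" in d:
            d["finetune_epochs"] = tuple(d["finetune_epochs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    arms: dict                  # arm name -> AurocResult dict
    confident_wrong: dict
    subgroups: list[dict]
    pis: list[dict]
    learning_curve: list[dict]
    marginals: dict
    sizes: dict
    manifest: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _prepare_site(profile: HospitalProfile, rules: InclusionRules, window: WindowConfig,
                  split_spec: SplitSpec, schema: FeatureSchema, seed: int, site: str):
    """generate -> cohort -> featurize -> split for one hospital."""
    tables, truth = generate(profile, seed=stage_seed(seed, f"{site}:generate"))
    logger.info("[%s] generated %d patients, %d CDAI rows", site,
                len(tables.demographics), len(tables.cdai))
    members = build_cohort(tables, rules)
    logger.info("[%s] cohort after inclusion: %d of %d patients", site,
                len(members), len(tables.demographics))
    df, schema = build_matrix(members, tables, window, schema)
    parts = split(members, SplitSpec(split_spec.fractions, stage_seed(seed, f"{site}:split")))
    ids = {name: {m.patient_id for m in part}
           for name, part in zip(("train", "val", "test"), parts)}
    frames = {name: df[df["patient_id"].isin(pid_set)].reset_index(drop=True)
              for name, pid_set in ids.items()}
    by_id = {m.patient_id: m for m in members}
    return {"tables": tables, "truth": truth, "members": members, "df": df,
            "frames": frames, "by_id": by_id, "schema": schema}


def _prior_vec(frame: pd.DataFrame, by_id: dict) -> np.ndarray:
    return np.array([int(by_id[p].prior_outcome_binary == "uncontrolled")
                     for p in frame["patient_id"]], dtype=float)[:, None]


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute all stages and write the report; see module docstring."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = FeatureSchema(n_windows=cfg.window.n_windows)
    hp = cfg.hyperparams.validate()
    seed = cfg.seed

    src = _prepare_site(cfg.source_profile, cfg.rules, cfg.window, cfg.split_spec,
                        schema, seed, "source")
    schema = src["schema"]
    Xtr, ytr = matrix_arrays(src["frames"]["train"], schema)
    Xva, yva = matrix_arrays(src["frames"]["val"], schema)
    Xte, yte = matrix_arrays(src["frames"]["test"], schema)

    def forecaster(seed_offset: int = 0, **over) -> RecurrentForecaster:
        return RecurrentForecaster(
            schema=schema, td_units=hp.td_units, gru_units=hp.gru_units,
            dropout=hp.dropout, l2_penalty=hp.l2_penalty, learning_rate=hp.learning_rate,
            batch_size=hp.batch_size, max_epochs=hp.max_epochs, patience=hp.patience,
            seed=stage_seed(seed, "train") + seed_offset, **over)

    logger.info("training recurrent forecaster on %d samples", len(ytr))
    recurrent = forecaster().fit(Xtr, ytr, validation_data=(Xva, yva))
    dense = DenseForecaster(
        dense_units=hp.dense_units, dropout=hp.dropout, l2_penalty=hp.l2_penalty,
        learning_rate=hp.learning_rate, batch_size=hp.batch_size,
        max_epochs=hp.max_epochs, patience=hp.patience,
        seed=stage_seed(seed, "train_dense")).fit(Xtr, ytr, validation_data=(Xva, yva))

    out_post = OutcomePosteriorClassifier(seed=stage_seed(seed, "outcome_posterior")).fit(Xtr, ytr)
    prior_tr = _prior_vec(src["frames"]["train"], src["by_id"])
    chg_post = ChangePosteriorClassifier(seed=stage_seed(seed, "change_posterior")).fit(prior_tr, ytr)
    prior_te = _prior_vec(src["frames"]["test"], src["by_id"])

    arms: dict[str, dict] = {}
    probs_rec = recurrent.predict_proba(Xte)[:, 1]
    arms["recurrent"] = delong_ci(probs_rec, yte).to_dict()
    arms["dense_surrogate"] = delong_ci(dense.predict_proba(Xte)[:, 1], yte).to_dict()
    arms["outcome_posterior"] = delong_ci(out_post.decision_function(Xte), yte).to_dict()
    arms["change_posterior"] = delong_ci(chg_post.decision_function(prior_te), yte).to_dict()

    cdai_te = src["frames"]["test"]["patient_id"].map(
        lambda p: src["by_id"][p].index_cdai).to_numpy()
    cw = confident_wrong(probs_rec, yte, cdai_values=cdai_te)
    subgroups = subgroup_performance(
        probs_rec, yte, src["frames"]["test"]["label_category"].to_numpy()
    ).to_dict("records")

    pis_entries = []
    if cfg.pis_repeats >= 2:
        pis_entries = permutation_importance(
            lambda X: recurrent.predict_proba(X)[:, 1], Xte, yte, schema.group_map(),
            n_windows=schema.n_windows, n_tv=schema.n_tv, n_repeats=cfg.pis_repeats,
            seed=stage_seed(seed, "pis"), groups=cfg.pis_groups, per_window=False)

    curve = []
    if cfg.learning_curve_sizes:
        pts = learning_curve(lambda s: forecaster(seed_offset=s % 1000),
                             Xtr, ytr, Xte, yte, sizes=cfg.learning_curve_sizes,
                             repeats=cfg.learning_curve_repeats,
                             seed=stage_seed(seed, "learning_curve"))
        curve = [dataclasses.asdict(p) for p in pts]

    if cfg.tsne and len(Xte) >= 5:
        coords = confusion_plot(recurrent.embed(Xte), yte,
                                seed=stage_seed(seed, "tsne"),
                                out_path=out / "confusion_plot.png")
        pd.DataFrame({"patient_id": src["frames"]["test"]["patient_id"],
                      "x": coords[:, 0], "y": coords[:, 1], "label": yte}
                     ).to_csv(out / "confusion_plot.csv", index=False)

    # ---- transfer experiment -------------------------------------------
    if cfg.target_profile is not None:
        tgt = _prepare_site(cfg.target_profile, cfg.rules, cfg.window, cfg.split_spec,
                            schema, seed, "target")
        tXtr, tytr = matrix_arrays(tgt["frames"]["train"], schema)
        tXva, tyva = matrix_arrays(tgt["frames"]["val"], schema)
        tXte, tyte = matrix_arrays(tgt["frames"]["test"], schema)
        native = forecaster(seed_offset=17).fit(tXtr, tytr, validation_data=(tXva, tyva))
        arms["target_native"] = delong_ci(native.predict_proba(tXte)[:, 1], tyte).to_dict()
        arms["target_direct_transfer"] = delong_ci(
            recurrent.predict_proba(tXte)[:, 1], tyte).to_dict()
        tuned = fine_tune(recurrent, tXtr, tytr, tXva, tyva,
                          head_epochs=cfg.finetune_epochs[0],
                          full_epochs=cfg.finetune_epochs[1],
                          seed=stage_seed(seed, "finetune"))
        arms["target_fine_tuned"] = delong_ci(tuned.predict_proba(tXte)[:, 1], tyte).to_dict()
        t_out = OutcomePosteriorClassifier(
            seed=stage_seed(seed, "t_outcome_posterior")).fit(tXtr, tytr)
        t_prior_tr = _prior_vec(tgt["frames"]["train"], tgt["by_id"])
        t_prior_te = _prior_vec(tgt["frames"]["test"], tgt["by_id"])
        t_chg = ChangePosteriorClassifier(
            seed=stage_seed(seed, "t_change_posterior")).fit(t_prior_tr, tytr)
        arms["target_outcome_posterior"] = delong_ci(t_out.decision_function(tXte), tyte).to_dict()
        arms["target_change_posterior"] = delong_ci(t_chg.decision_function(t_prior_te), tyte).to_dict()

    marginals = check_marginals(src["tables"], src["truth"], cfg.source_profile)
    sizes = {"n_source_patients": len(src["tables"].demographics),
             "n_source_cohort": len(src["members"]),
             "n_train": len(ytr), "n_val": len(yva), "n_test": len(yte),
             "n_features": schema.total_dim}
    if cfg.target_profile is not None:
        sizes.update({"n_target_cohort": len(tgt["members"]),
                      "n_target_train": len(tytr), "n_target_test": len(tyte)})

    from . import __version__ as pkg_version
    manifest = {
        "package_version": pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": cfg.config_hash(),
        "global_seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in
                        ("source:generate", "source:split", "train", "train_dense",
                         "outcome_posterior", "change_posterior", "pis",
                         "learning_curve", "tsne", "finetune")},
    }
    report = ExperimentReport(arms=arms, confident_wrong=cw, subgroups=subgroups,
                              pis=[e.__dict__ for e in pis_entries],
                              learning_curve=curve, marginals=marginals,
                              sizes=sizes, manifest=manifest)

    if cfg.write_artifacts:
        src["tables"].write_csv(out / "source_tables")
        src["truth"].write(out / "source_tables")
        cohort_to_frame(src["members"]).to_csv(out / "source_cohort.csv", index=False)
        (out / "schema.json").write_text(schema.to_json())
        recurrent.save(out / "model_recurrent")
        if pis_entries:
            pis_frame(pis_entries).to_csv(out / "pis.csv", index=False)
        if curve:
            pd.DataFrame(curve).to_csv(out / "learning_curve.csv", index=False)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str))
    return report
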