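"""Shared fixtures: synthetic cohorts generated once per session."""

import numpy as np
import pytest

import raforecast as rf
from raforecast.featurize import matrix_arrays, split


def _site_bundle(profile, split_seed, split_fracs=(0.6, 0.2, 0.2)):
    tables, truth = rf.generate(profile)
    members = rf.build_cohort(tables)
    df, schema = rf.build_matrix(members, tables)
    parts = split(members, rf.SplitSpec(fractions=split_fracs, seed=split_seed))
    frames = []
    for part in parts:
        ids = {m.patient_id for m in part}
        frames.append(df[df["patient_id"].isin(ids)].reset_index(drop=True))
    arrays = [matrix_arrays(f, schema) for f in frames]
    return {
        "profile": profile, "tables": tables, "truth": truth, "members": members,
        "df": df, "schema": schema, "parts": parts, "frames": frames, "arrays": arrays,
        "by_id": {m.patient_id: m for m in members},
    }


@pytest.fixture(scope="session")
def small_site():
    """250-patient cohort for cohort/featurization tests."""
    return _site_bundle(rf.uh_profile(n_patients=250, seed=5), split_seed=3)


@pytest.fixture(scope="session")
def strong_site():
    """2000-patient strong-signal cohort used by the signal-recovery checks."""
    return _site_bundle(rf.uh_profile(n_patients=2000, seed=7), split_seed=11)


@pytest.fixture(scope="session")
def target_site():
    """Small second-hospital cohort sharing the outcome mechanism (transfer tests)."""
    return _site_bundle(rf.snh_profile(n_patients=400, seed=13),
                        split_seed=17, split_fracs=(0.35, 0.15, 0.50))


@pytest.fixture(scope="session")
def trained_recurrent(strong_site):
    """GRU forecaster trained once on the strong-signal cohort."""
    (Xtr, ytr), (Xva, yva), _ = strong_site["arrays"]
    est = rf.RecurrentForecaster(schema=strong_site["schema"],
                                 max_epochs=60, patience=10, seed=0)
    est.fit(Xtr, ytr, validation_data=(Xva, yva))
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
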