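"""Forecaster and baseline contracts: capacity, determinism, posterior behavior."""

import numpy as np
import pytest

import raforecast as rf
from raforecast.evaluate import auroc
from raforecast.featurize import FeatureSchema
from raforecast.models import (ChangePosteriorClassifier, DenseForecaster,
                               OutcomePosteriorClassifier, RecurrentForecaster,
                               fine_tune, fit_outcome_posterior, predict_outcome_posterior,
                               fit_change_posterior, predict_change_posterior)

TOY_SCHEMA = FeatureSchema(med_codes=("A", "B"), n_windows=4)   # 4*(2+3)+5 = 25 columns


def toy_data(n=40, seed=0, shuffle_labels=False):
    """Separable toy set: the label is carried by window-4 CDAI."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, TOY_SCHEMA.total_dim))
    cdai_w4 = TOY_SCHEMA.columns.index("CDAI@w4")
    y = (X[:, cdai_w4] > 0).astype(int)
    if shuffle_labels:
        y = rng.permutation(y)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    return X, y


def quick_recurrent(**over):
    kw = dict(schema=TOY_SCHEMA, td_units=8, gru_units=(8,), dropout=0.0,
              learning_rate=1e-2, max_epochs=40, patience=40, seed=1)
    kw.update(over)
    return RecurrentForecaster(**kw)


class TestForecasters:
    @pytest.mark.parametrize("make", [
        quick_recurrent,
        lambda: DenseForecaster(dense_units=(16,), dropout=0.0, learning_rate=1e-2,
                                max_epochs=40, patience=40, seed=1),
    ])
    def test_separable_toy_reaches_training_auroc_1(self, make):
        X, y = toy_data(n=20)
        est = make().fit(X, y)
        assert auroc(est.predict_proba(X)[:, 1], y) == 1.0

    def test_same_seed_identical_history(self):
        X, y = toy_data(n=30)
        Xv, yv = toy_data(n=20, seed=2)
        h = [quick_recurrent().fit(X, y, validation_data=(Xv, yv)).history_
             for _ in range(2)]
        assert h[0] == h[1]

    def test_single_class_labels_error(self):
        X, _ = toy_data(n=10)
        with pytest.raises(ValueError, match="single class"):
            quick_recurrent().fit(X, np.zeros(10, dtype=int))

    def test_schema_mismatch_error(self):
        X, y = toy_data(n=20)
        est = quick_recurrent().fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            est.predict_proba(X[:, :-1])

    def test_empty_and_duplicated_predictions(self):
        X, y = toy_data(n=20)
        est = quick_recurrent().fit(X, y)
        assert est.predict_proba(np.empty((0, TOY_SCHEMA.total_dim))).shape == (0, 2)
        dup = np.vstack([X[0], X[0]])
        p = est.predict_proba(dup)[:, 1]
        assert p[0] == p[1]
        assert np.all((p >= 0) & (p <= 1))

    def test_embedding_dim_and_duplicates(self):
        X, y = toy_data(n=20)
        est = quick_recurrent(gru_units=(8, 5)).fit(X, y)
        emb = est.embed(np.vstack([X[0], X[0], X[1]]))
        assert emb.shape == (3, 5)
        np.testing.assert_array_equal(emb[0], emb[1])
        with pytest.raises(ValueError, match="not fitted"):
            quick_recurrent().embed(X)

    def test_null_signal_auroc_near_half(self):
        X, y = toy_data(n=500, seed=3, shuffle_labels=True)
        Xt, yt = toy_data(n=500, seed=4)
        est = quick_recurrent(max_epochs=15).fit(X, y)
        assert 0.4 <= auroc(est.predict_proba(Xt)[:, 1], yt) <= 0.6

    def test_save_load_roundtrip(self, tmp_path):
        X, y = toy_data(n=20)
        est = quick_recurrent().fit(X, y)
        est.save(tmp_path / "m")
        loaded = RecurrentForecaster.load(tmp_path / "m")
        np.testing.assert_allclose(loaded.predict_proba(X), est.predict_proba(X))

    def test_sklearn_get_set_params(self):
        est = quick_recurrent()
        params = est.get_params()
        assert params["td_units"] == 8
        est.set_params(td_units=4)
        assert est.td_units == 4


class TestOutcomePosterior:
    def test_p_controlled_estimate(self):
        y = np.array([0] * 60 + [1] * 40)      # 60% controlled
        m = fit_outcome_posterior(y)
        assert m.p_controlled_ == pytest.approx(0.60)

    def test_all_controlled_when_p_is_one(self):
        m = OutcomePosteriorClassifier(seed=0).fit(None, np.zeros(10, dtype=int))
        assert predict_outcome_posterior(m, 50).sum() == 0

    def test_empty_training_errors(self):
        with pytest.raises(ValueError):
            fit_outcome_posterior(np.array([]))

    def test_auroc_is_half_at_large_n(self):
        n = 100_000
        m = fit_outcome_posterior(np.array([0] * 6 + [1] * 4))
        scores = predict_outcome_posterior(m, n)
        rng = np.random.default_rng(1)
        for labels in (rng.integers(0, 2, n), (np.arange(n) % 5 == 0).astype(int)):
            assert abs(auroc(scores, labels) - 0.5) <= 0.02

    def test_deterministic_given_seed(self):
        m = fit_outcome_posterior(np.array([0, 1, 0, 1]), seed=7)
        np.testing.assert_array_equal(predict_outcome_posterior(m, 100),
                                      predict_outcome_posterior(m, 100))


class TestChangePosterior:
    def test_p_switch_estimate_and_zero_switch(self):
        prior = np.array([0, 0, 1, 1, 0, 1, 0, 0, 1, 1])
        y = prior.copy(); y[:3] = 1 - y[:3]
        m = fit_change_posterior(prior, y)
        assert m.p_switch_ == pytest.approx(0.3)
        m0 = ChangePosteriorClassifier(seed=0).fit(prior.astype(float), prior)
        np.testing.assert_array_equal(predict_change_posterior(m0, prior), prior)

    def test_missing_prior_errors(self):
        m = fit_change_posterior(np.array([0.0, 1.0]), np.array([0, 1]))
        with pytest.raises(ValueError, match="prior"):
            predict_change_posterior(m, np.array([np.nan, 1.0]))

    def test_auroc_matches_transition_chain_closed_form(self):
        # Symmetric two-state chain with persistence q = 0.75, flip prob p = 0.25.
        n, q, p = 100_000, 0.75, 0.25
        rng = np.random.default_rng(5)
        prior = rng.integers(0, 2, n)
        y = np.where(rng.random(n) < q, prior, 1 - prior)
        m = ChangePosteriorClassifier(seed=3)
        m.p_switch_ = p
        m.classes_ = np.array([0, 1])
        scores = predict_change_posterior(m, prior.astype(float))
        # closed form from the chain: P(score=1|y) via prior-given-y and the flip
        p1 = q * (1 - p) + (1 - q) * p       # P(s=1 | y=1)
        p0 = (1 - q) * (1 - p) + q * p       # P(s=1 | y=0)
        expected = p1 * (1 - p0) + 0.5 * (p1 * p0 + (1 - p1) * (1 - p0))
        assert abs(auroc(scores, y) - expected) <= 0.02


class TestFineTune:
    def test_zero_epochs_is_identity(self):
        X, y = toy_data(n=30)
        est = quick_recurrent().fit(X, y)
        tuned = fine_tune(est, X, y, None, None, head_epochs=0, full_epochs=0)
        np.testing.assert_array_equal(tuned.predict_proba(X), est.predict_proba(X))

    def test_source_model_unmodified(self):
        X, y = toy_data(n=30)
        Xv, yv = toy_data(n=20, seed=2)
        est = quick_recurrent().fit(X, y)
        before = est.predict_proba(X).copy()
        fine_tune(est, X, y, Xv, yv, head_epochs=5, full_epochs=5)
        np.testing.assert_array_equal(est.predict_proba(X), before)

    def test_self_fine_tune_does_not_degrade(self):
        X, y = toy_data(n=60, seed=6)
        Xv, yv = toy_data(n=40, seed=7)
        est = quick_recurrent().fit(X, y, validation_data=(Xv, yv))
        base = auroc(est.predict_proba(Xv)[:, 1], yv)
        tuned = fine_tune(est, X, y, Xv, yv, head_epochs=10, full_epochs=10)
        assert auroc(tuned.predict_proba(Xv)[:, 1], yv) >= base - 0.02
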