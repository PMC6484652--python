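"""AUROC/DeLong statistics, permutation importance, sensitivity analyses."""

import numpy as np
import pytest

from raforecast.evaluate import (auroc, confident_wrong, confusion_plot, delong_ci,
                                 learning_curve, permutation_importance,
                                 subgroup_performance)


def brute_force_auroc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_pair_counting_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_half(self):
        assert auroc([0.3] * 10, [0, 1] * 5) == 0.5

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)     # rounding forces ties
            assert auroc(s, y) == brute_force_auroc(s, y)


class TestDelong:
    def test_perfect_separation_degenerate_ci(self):
        r = delong_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (r.auc, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)

    def test_needs_two_per_class(self):
        with pytest.raises(ValueError):
            delong_ci([0.1, 0.5, 0.9], [0, 1, 1])

    def test_ci_orders_and_contains_auc(self, rng):
        s = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        r = delong_ci(s, y)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_matches_stratified_bootstrap(self, rng):
        for _ in range(20):
            n = int(rng.integers(25, 60))
            y = np.concatenate([np.zeros(n), np.ones(n)]).astype(int)
            s = rng.normal(size=2 * n) + 0.8 * y
            r = delong_ci(s, y)
            boots = []
            for _ in range(2000):
                i0 = rng.integers(0, n, n)
                i1 = n + rng.integers(0, n, n)
                boots.append(auroc(np.concatenate([s[i0], s[i1]]),
                                   np.concatenate([y[i0], y[i1]])))
            lo, hi = np.percentile(boots, [2.5, 97.5])
            assert abs(r.ci_low - lo) <= 0.02 and abs(r.ci_high - hi) <= 0.02


class TestPermutationImportance:
    @staticmethod
    def _score_fn(X):
        return X[:, 0]          # model uses only column 0

    def test_label_variable_significant_constant_not(self, rng):
        n = 400
        X = np.zeros((n, 3))
        X[:, 0] = rng.normal(size=n)
        X[:, 1] = 7.0                         # constant column
        y = (X[:, 0] > 0).astype(int)
        gm = {"signal": [0], "constant": [1]}
        entries = {e.group: e for e in permutation_importance(
            self._score_fn, X, y, gm, n_repeats=30, seed=0, include_time=False)}
        assert entries["signal"].significant and entries["signal"].pis > 10
        assert not entries["constant"].significant
        assert entries["constant"].ci_low <= 0 <= entries["constant"].ci_high

    def test_permuting_everything_destroys_information(self, rng):
        n = 500
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] > 0).astype(int)
        entries = permutation_importance(self._score_fn, X, y, {"all": [0, 1]},
                                         n_repeats=50, seed=1, include_time=False,
                                         per_window=False)
        permuted_auc = auroc(self._score_fn(X), y) - entries[0].pis / 100
        assert abs(permuted_auc - 0.5) <= 0.05

    def test_unknown_group_errors(self):
        with pytest.raises(KeyError):
            permutation_importance(self._score_fn, np.zeros((10, 2)),
                                   [0, 1] * 5, {"a": [0]}, groups=["b"], n_repeats=2)


class TestSensitivity:
    def test_confident_wrong_examples(self):
        out = confident_wrong([0.9, 0.55, 0.1], [1, 0, 1])
        # 0.9/label 1 confident-correct; 0.55 not confident; 0.1/label 1 confident-wrong
        assert out["n_confident"] == 2 and out["n_confident_wrong"] == 1
        out2 = confident_wrong([0.3, 0.6, 0.79, 0.21], [0, 1, 0, 1])
        assert out2["n_confident_wrong"] == 0

    def test_confident_wrong_reports_cdai(self):
        out = confident_wrong([0.9, 0.1], [0, 1], cdai_values=[12.0, 11.0])
        assert out["confident_wrong_cdai"] == [12.0, 11.0]

    def test_subgroup_all_correct(self):
        df = subgroup_performance([0.1, 0.9, 0.2, 0.95], [0, 1, 0, 1],
                                  ["remission", "high", "low", "moderate"])
        assert (df["accuracy"] == 1.0).all() and len(df) == 4

    def test_subgroup_skips_empty_categories(self):
        df = subgroup_performance([0.1, 0.9], [0, 1], ["remission", "high"])
        assert set(df["category"]) == {"remission", "high"}

    def test_subgroup_null_near_base_rate(self, rng):
        n = 2000
        y = rng.integers(0, 2, n)
        p = rng.random(n)
        cats = rng.choice(["remission", "low", "moderate", "high"], n)
        df = subgroup_performance(p, y, cats)
        assert (abs(df["accuracy"] - 0.5) < 0.08).all()


class TestLearningCurve:
    class Linear:
        """Deterministic stub estimator scoring by one coefficient sign."""

        def __init__(self, seed):
            self.seed = seed

        def fit(self, X, y):
            self.w_ = np.linalg.lstsq(X, y * 2 - 1, rcond=None)[0]
            return self

        def predict_proba(self, X):
            s = X @ self.w_
            return np.column_stack([-s, s])

    def test_full_pool_single_repeat_equals_direct_run(self, rng):
        X = rng.normal(size=(50, 3)); y = (X[:, 0] > 0).astype(int)
        Xt = rng.normal(size=(40, 3)); yt = (Xt[:, 0] > 0).astype(int)
        pts = learning_curve(self.Linear, X, y, Xt, yt, sizes=[50], repeats=1, seed=9)
        direct = auroc(self.Linear(9).fit(X, y).predict_proba(Xt)[:, 1], yt)
        assert pts[0].mean_auc == pytest.approx(direct)

    def test_oversized_request_errors(self, rng):
        X = rng.normal(size=(10, 2)); y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError):
            learning_curve(self.Linear, X, y, X, y, sizes=[11])


class TestConfusionPlot:
    def test_deterministic_and_duplicates_close(self, rng, tmp_path):
        E = rng.normal(size=(60, 8))
        E[1] = E[0]                           # exact duplicate pair
        y = rng.integers(0, 2, 60)
        c1 = confusion_plot(E, y, seed=3, out_path=tmp_path / "p.png")
        c2 = confusion_plot(E, y, seed=3)
        np.testing.assert_allclose(c1, c2)
        assert (tmp_path / "p.png").exists()
        d = np.linalg.norm(c1[0] - c1[1])
        from scipy.spatial.distance import pdist
        assert d <= np.percentile(pdist(c1), 5)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            confusion_plot(np.zeros((3, 2)), [0, 1, 0])
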