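"""Forecasting models: recurrent and dense neural forecasters, posterior baselines.

All four are scikit-learn style estimators (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so they compose with sklearn model selection; the
module-level functions (``train_forecaster``, ``predict``, ``fine_tune``,
``fit_outcome_posterior``, ...) are thin wrappers kept for pipeline use.

Labels follow the sklearn convention ``y in {0, 1}`` with 1 = uncontrolled
disease activity at the index visit; predicted probabilities are
``P(uncontrolled)``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .featurize import FeatureSchema
from .nn import DenseNet, RecurrentNet, train_network


@dataclass
class Hyperparams:
    """Training configuration; defaults keep the network small and highly regularized."""

    td_units: int = 32
    gru_units: tuple[int, ...] = (32, 16)
    dense_units: tuple[int, ...] = (64, 32)   # used by the dense surrogate
    dropout: float = 0.5
    l2_penalty: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def validate(self) -> "Hyperparams":
        if self.td_units < 1 or any(u < 1 for u in self.gru_units) or self.batch_size < 1 \
                or self.max_epochs < 1:
            raise ValueError("all unit/batch/epoch counts must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.l2_penalty < 0 or self.learning_rate <= 0:
            raise ValueError("l2_penalty must be >= 0 and learning_rate > 0")
        return self


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (n_samples, n_features)")
    if y is not None:
        y = np.asarray(y).ravel().astype(int)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1 (1 = uncontrolled)")
    return X, y


class _NeuralForecasterBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the two neural forecasters."""

    def _make_net(self, n_features):
        raise NotImplementedError

    def _net_input(self, X):
        raise NotImplementedError

    def _validate_schema(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the fitted schema "
                f"({self.n_features_in_})")

    def fit(self, X, y, validation_data=None):
        X, y = _check_Xy(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.scaler_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scaler_scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.scaler_mean_) / self.scaler_scale_

        Xv = yv = None
        if validation_data is not None:
            Xv, yv = _check_Xy(*validation_data)
            self._validate_schema(Xv)
            Xv = (Xv - self.scaler_mean_) / self.scaler_scale_

        hp = self._hp()
        self.net_ = self._make_net(X.shape[1])
        self.history_ = train_network(
            self.net_, self._net_input(Xs), y,
            self._net_input(Xv) if Xv is not None else None, yv,
            learning_rate=hp.learning_rate, batch_size=hp.batch_size,
            max_epochs=hp.max_epochs, patience=hp.patience,
            l2_penalty=hp.l2_penalty, seed=hp.seed)
        return self

    def _scored_input(self, X):
        X, _ = _check_Xy(X)
        if len(X) == 0:
            return np.empty((0, self.n_features_in_))
        self._validate_schema(X)
        return (X - self.scaler_mean_) / self.scaler_scale_

    def decision_function(self, X):
        Xs = self._scored_input(X)
        if len(Xs) == 0:
            return np.empty(0)
        probs, _ = self.net_.forward(self._net_input(Xs), train=False)
        return probs

    def predict_proba(self, X):
        p1 = self.decision_function(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0.5).astype(int)

    def embed(self, X):
        """Per-sample vector from the final pre-output layer."""
        if not hasattr(self, "net_"):
            raise ValueError("model is not fitted")
        Xs = self._scored_input(X)
        if len(Xs) == 0:
            return np.empty((0, self.net_.embedding_dim))
        return self.net_.embed(self._net_input(Xs))

    # -- persistence -----------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "params.npz", **self.net_.params,
                 scaler_mean=self.scaler_mean_, scaler_scale=self.scaler_scale_)
        (out / "config.json").write_text(json.dumps({
            "class": type(self).__name__,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()
                       if not isinstance(v, FeatureSchema)},
            "n_features_in": int(self.n_features_in_),
        }, indent=2))
        if getattr(self, "schema", None) is not None:
            (out / "schema.json").write_text(self.schema.to_json())
        pd.DataFrame(self.history_).to_csv(out / "history.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path):
        src = Path(in_dir)
        cfg = json.loads((src / "config.json").read_text())
        params = dict(cfg["params"])
        for k in ("gru_units", "dense_units"):
            if k in params:
                params[k] = tuple(params[k])
        schema_path = src / "schema.json"
        if schema_path.exists() and "schema" in cls().get_params():
            params["schema"] = FeatureSchema.from_json(schema_path.read_text())
        est = cls(**params)
        est.n_features_in_ = cfg["n_features_in"]
        est.classes_ = np.array([0, 1])
        data = np.load(src / "params.npz")
        est.scaler_mean_ = data["scaler_mean"]
        est.scaler_scale_ = data["scaler_scale"]
        est.net_ = est._make_net(est.n_features_in_)
        est.net_.params = {k: data[k] for k in est.net_.params}
        hist = src / "history.csv"
        est.history_ = pd.read_csv(hist).to_dict("records") if hist.exists() else []
        return est


class RecurrentForecaster(_NeuralForecasterBase):
    """GRU forecaster over the windowed tensor.

    ``X`` is the flattened (window-major time-varying block + statics) matrix
    produced by the featurizer; ``schema`` describes how to fold it back into
    (n_samples, n_windows, n_time_varying) with the five static variables
    broadcast onto every window before the shared per-window dense transform.
    """

    def __init__(self, schema: FeatureSchema | None = None, td_units: int = 32,
                 gru_units: tuple[int, ...] = (32, 16), dropout: float = 0.5,
                 l2_penalty: float = 1e-4, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 200, patience: int = 20,
                 seed: int = 0):
        self.schema = schema
        self.td_units = td_units
        self.gru_units = gru_units
        self.dropout = dropout
        self.l2_penalty = l2_penalty
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _hp(self) -> Hyperparams:
        return Hyperparams(td_units=self.td_units, gru_units=tuple(self.gru_units),
                           dropout=self.dropout, l2_penalty=self.l2_penalty,
                           learning_rate=self.learning_rate, batch_size=self.batch_size,
                           max_epochs=self.max_epochs, patience=self.patience,
                           seed=self.seed).validate()

    def _effective_schema(self) -> FeatureSchema:
        return self.schema if self.schema is not None else FeatureSchema()

    def _make_net(self, n_features):
        sc = self._effective_schema()
        if n_features != sc.total_dim:
            raise ValueError(f"X has {n_features} columns but the schema defines {sc.total_dim}")
        per_window = sc.n_tv + len(sc.static_vars)
        return RecurrentNet(per_window, self.td_units, tuple(self.gru_units),
                            self.dropout, self.seed)

    def _net_input(self, X):
        sc = self._effective_schema()
        n = len(X)
        tv = X[:, :sc.n_windows * sc.n_tv].reshape(n, sc.n_windows, sc.n_tv)
        static = X[:, sc.n_windows * sc.n_tv:]
        stat_rep = np.repeat(static[:, None, :], sc.n_windows, axis=1)
        return np.concatenate([tv, stat_rep], axis=2)


class DenseForecaster(_NeuralForecasterBase):
    """Fully dense surrogate on the flattened feature vector (no recurrence)."""

    def __init__(self, dense_units: tuple[int, ...] = (64, 32), dropout: float = 0.5,
                 l2_penalty: float = 1e-4, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 200, patience: int = 20,
                 seed: int = 0):
        self.dense_units = dense_units
        self.dropout = dropout
        self.l2_penalty = l2_penalty
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _hp(self) -> Hyperparams:
        return Hyperparams(dense_units=tuple(self.dense_units), dropout=self.dropout,
                           l2_penalty=self.l2_penalty, learning_rate=self.learning_rate,
                           batch_size=self.batch_size, max_epochs=self.max_epochs,
                           patience=self.patience, seed=self.seed).validate()

    def _make_net(self, n_features):
        return DenseNet(n_features, tuple(self.dense_units), self.dropout, self.seed)

    def _net_input(self, X):
        return X


class OutcomePosteriorClassifier(BaseEstimator, ClassifierMixin):
    """Baseline: predict 'controlled' with the training-cohort controlled fraction.

    Each prediction is an independent Bernoulli draw; the AUROC score of a
    sample is 1 if it is predicted uncontrolled, else 0.  By construction the
    predictions are independent of the truth, so the expected AUROC is 0.5.
    """

    def __init__(self, seed: int = 0, analytic: bool = False):
        self.seed = seed
        self.analytic = analytic   # if True, score every sample with P(uncontrolled)

    def fit(self, X, y):
        y = np.asarray(y).ravel().astype(int)
        if len(y) == 0:
            raise ValueError("empty training labels")
        self.p_controlled_ = float(1 - y.mean())
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        n = len(X)
        if self.analytic:
            return np.full(n, 1 - self.p_controlled_)
        rng = np.random.default_rng((self.seed, n))
        return (rng.random(n) >= self.p_controlled_).astype(float)

    def predict(self, X):
        return self.decision_function(X).astype(int) if not self.analytic \
            else (self.decision_function(X) > 0.5).astype(int)

    def predict_proba(self, X):
        s = self.decision_function(X)
        return np.column_stack([1 - s, s])


class ChangePosteriorClassifier(BaseEstimator, ClassifierMixin):
    """Baseline: carry each patient's prior outcome forward, flipping at the
    training cohort's visit-to-visit switch rate.

    ``X`` must contain the prior binary outcome (1 = uncontrolled) in its
    first column; ``fit`` estimates ``p_switch_`` from (prior, next) pairs.
    """

    def __init__(self, seed: int = 0, analytic: bool = False):
        self.seed = seed
        self.analytic = analytic

    @staticmethod
    def _priors(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        prior = X[:, 0]
        if np.isnan(prior).any():
            raise ValueError("prior outcome missing for some samples")
        return prior.astype(int)

    def fit(self, X, y):
        prior = self._priors(X)
        y = np.asarray(y).ravel().astype(int)
        if len(y) == 0:
            raise ValueError("empty training transitions")
        self.p_switch_ = float(np.mean(prior != y))
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        prior = self._priors(X)
        if self.analytic:
            return np.where(prior == 1, 1 - self.p_switch_, self.p_switch_)
        rng = np.random.default_rng((self.seed, len(prior)))
        flip = rng.random(len(prior)) < self.p_switch_
        return np.where(flip, 1 - prior, prior).astype(float)

    def predict(self, X):
        s = self.decision_function(X)
        return s.astype(int) if not self.analytic else (s > 0.5).astype(int)

    def predict_proba(self, X):
        s = self.decision_function(X)
        return np.column_stack([1 - s, s])


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_forecaster(X_train, y_train, X_val, y_val, hp: Hyperparams | None = None,
                     schema: FeatureSchema | None = None) -> RecurrentForecaster:
    hp = (hp or Hyperparams()).validate()
    est = RecurrentForecaster(schema=schema, td_units=hp.td_units,
                              gru_units=hp.gru_units, dropout=hp.dropout,
                              l2_penalty=hp.l2_penalty, learning_rate=hp.learning_rate,
                              batch_size=hp.batch_size, max_epochs=hp.max_epochs,
                              patience=hp.patience, seed=hp.seed)
    return est.fit(X_train, y_train, validation_data=(X_val, y_val))


def train_dense_surrogate(X_train, y_train, X_val, y_val,
                          hp: Hyperparams | None = None) -> DenseForecaster:
    hp = (hp or Hyperparams()).validate()
    est = DenseForecaster(dense_units=hp.dense_units, dropout=hp.dropout,
                          l2_penalty=hp.l2_penalty, learning_rate=hp.learning_rate,
                          batch_size=hp.batch_size, max_epochs=hp.max_epochs,
                          patience=hp.patience, seed=hp.seed)
    return est.fit(X_train, y_train, validation_data=(X_val, y_val))


def predict(model, X) -> np.ndarray:
    """Probability of uncontrolled disease at the next visit, per sample."""
    return model.predict_proba(X)[:, 1]


def extract_embedding(model, X) -> np.ndarray:
    return model.embed(X)


def fine_tune(model: _NeuralForecasterBase, X_train, y_train, X_val, y_val,
              head_epochs: int = 50, full_epochs: int = 50,
              lr_factor: float = 0.1, seed: int | None = None) -> _NeuralForecasterBase:
    """Two-phase transfer fine-tuning; returns a new model, source unmodified.

    Phase 1 retrains only the output layer at ``learning_rate * lr_factor``;
    phase 2 unfreezes everything at the same reduced rate.  Zero epochs in
    both phases is the identity.
    """
    tuned = copy.deepcopy(model)
    if head_epochs == 0 and full_epochs == 0:
        return tuned
    X_train, y_train = _check_Xy(X_train, y_train)
    tuned._validate_schema(X_train)
    hp = tuned._hp()
    seed = hp.seed if seed is None else seed
    Xs = (X_train - tuned.scaler_mean_) / tuned.scaler_scale_
    Xv = yv = None
    if X_val is not None:
        X_val, yv = _check_Xy(X_val, y_val)
        Xv = tuned._net_input((X_val - tuned.scaler_mean_) / tuned.scaler_scale_)
    lr = hp.learning_rate * lr_factor
    common = dict(learning_rate=lr, batch_size=hp.batch_size, patience=hp.patience,
                  l2_penalty=hp.l2_penalty)
    hist = []
    if head_epochs > 0:
        hist += train_network(tuned.net_, tuned._net_input(Xs), y_train, Xv, yv,
                              max_epochs=head_epochs, seed=seed,
                              trainable={"W_out", "b_out"}, **common)
    if full_epochs > 0:
        hist += train_network(tuned.net_, tuned._net_input(Xs), y_train, Xv, yv,
                              max_epochs=full_epochs, seed=seed + 1, **common)
    tuned.history_ = list(getattr(tuned, "history_", [])) + hist
    return tuned


def fit_outcome_posterior(y_train, seed: int = 0) -> OutcomePosteriorClassifier:
    return OutcomePosteriorClassifier(seed=seed).fit(np.empty((len(y_train), 0)), y_train)


def predict_outcome_posterior(model: OutcomePosteriorClassifier, n_samples: int) -> np.ndarray:
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return model.decision_function(np.empty((n_samples, 0)))


def fit_change_posterior(prior_outcomes, outcomes, seed: int = 0) -> ChangePosteriorClassifier:
    return ChangePosteriorClassifier(seed=seed).fit(np.asarray(prior_outcomes, dtype=float),
                                                    outcomes)


def predict_change_posterior(model: ChangePosteriorClassifier, prior_outcomes) -> np.ndarray:
    return model.decision_function(np.asarray(prior_outcomes, dtype=float))


def random_search(estimator_factory, param_space: dict, X_train, y_train, X_val, y_val,
                  n_iter: int = 10, seed: int = 0) -> tuple[dict, float]:
    """Small random-search hook over a declared hyperparameter space.

    ``param_space`` maps parameter name -> list of candidate values; returns
    the best (params, validation AUROC) by the package's AUROC.
    """
    from .evaluate import auroc
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for _ in range(n_iter):
        draw = {k: v[int(rng.integers(len(v)))] for k, v in param_space.items()}
        est = estimator_factory(**draw)
        est.fit(X_train, y_train, validation_data=(X_val, y_val))
        score = auroc(est.predict_proba(X_val)[:, 1], y_val)
        if score > best_score:
            best, best_score = draw, float(score)
    return best, best_score
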