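"""Evaluation and model-explanation statistics.

AUROC is computed as the Mann-Whitney statistic (concordant pairs plus half
ties over all positive-negative pairs); its confidence interval uses the
DeLong placement-value variance estimator.  Permutation importance scores
(PIS) are reported in percentage points of AUROC lost when a variable
group's columns are permuted across test samples; a group is significant
when the percentile interval of its permuted AUROCs excludes the baseline
AUROC.  "Combined" permutes all of a group's windows jointly; the "time"
entry permutes the window order within each sample, destroying sequence
information while preserving content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class AurocResult:
    auc: float
    ci_low: float
    ci_high: float
    alpha: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "alpha": self.alpha, "n_pos": self.n_pos, "n_neg": self.n_neg}


@dataclass
class PISEntry:
    group: str
    window: str              # "1".."n", "combined", or "static"
    pis: float               # percentage points of AUROC
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class LearningCurvePoint:
    n_train: int
    mean_auc: float
    sd_auc: float
    aucs: tuple


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).ravel().astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: (concordant pairs + half ties) / (n_pos * n_neg)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if len(s) != len(y):
        raise ValueError("scores and labels length mismatch")
    r = rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos, neg = scores[y == 1], scores[y == 0]
    # V10_i: fraction of negatives below positive i (ties count half); V01_j symmetric
    v10 = np.array([np.mean((neg < p) + 0.5 * (neg == p)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    return v10, v01


def delong_ci(scores, labels, alpha: float = 0.05) -> AurocResult:
    """AUROC with a DeLong Wald confidence interval, truncated to [0, 1]."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("DeLong variance needs at least 2 samples of each class")
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
    half = norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return AurocResult(auc=auc, ci_low=float(max(auc - half, 0.0)),
                       ci_high=float(min(auc + half, 1.0)),
                       alpha=alpha, n_pos=n_pos, n_neg=n_neg)


def permutation_importance(score_fn, X: np.ndarray, y, group_map: dict[str, list[int]],
                           n_windows: int | None = None, n_tv: int | None = None,
                           n_repeats: int = 100, seed: int = 0,
                           groups: list[str] | None = None,
                           per_window: bool = True, include_time: bool = True,
                           alpha: float = 0.05) -> list[PISEntry]:
    """Grouped permutation importance on a test matrix.

    ``score_fn(X) -> P(uncontrolled)`` is the trained model's scorer;
    ``group_map`` maps variable name -> flattened column indices across
    windows (static variables have a single index).  Produces one entry per
    (group, window), a jointly permuted "combined" entry per multi-window
    group, and — when ``n_windows``/``n_tv`` describe the window-major
    time-varying block — a "time" entry permuting window order within
    samples.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    base = auroc(score_fn(X), y)
    q_lo, q_hi = 100 * alpha / 2, 100 * (1 - alpha / 2)

    wanted = list(group_map) if groups is None else list(groups)
    unknown = [g for g in wanted if g not in group_map]
    if unknown:
        raise KeyError(f"unknown variable groups: {unknown}")

    def perm_entry(group: str, window: str, cols: list[int]) -> PISEntry:
        aucs = np.empty(n_repeats)
        for rep in range(n_repeats):
            perm = rng.permutation(len(X))
            Xp = X.copy()
            Xp[:, cols] = X[perm][:, cols]
            aucs[rep] = auroc(score_fn(Xp), y)
        drops = 100.0 * (base - aucs)
        lo, hi = np.percentile(drops, [q_lo, q_hi])
        # significant iff the permuted-AUROC interval excludes the baseline
        return PISEntry(group=group, window=window, pis=float(drops.mean()),
                        ci_low=float(lo), ci_high=float(hi),
                        significant=bool(lo > 0 or hi < 0))

    entries: list[PISEntry] = []
    for g in wanted:
        cols = group_map[g]
        if len(cols) == 1:
            entries.append(perm_entry(g, "static", cols))
            continue
        if per_window:
            for wi, c in enumerate(cols, start=1):
                entries.append(perm_entry(g, str(wi), [c]))
        entries.append(perm_entry(g, "combined", cols))

    if include_time and n_windows and n_tv:
        aucs = np.empty(n_repeats)
        tv_dim = n_windows * n_tv
        for rep in range(n_repeats):
            Xp = X.copy()
            tv = Xp[:, :tv_dim].reshape(len(X), n_windows, n_tv)
            for i in range(len(X)):
                tv[i] = tv[i][rng.permutation(n_windows)]
            Xp[:, :tv_dim] = tv.reshape(len(X), tv_dim)
            aucs[rep] = auroc(score_fn(Xp), y)
        drops = 100.0 * (base - aucs)
        lo, hi = np.percentile(drops, [q_lo, q_hi])
        entries.append(PISEntry(group="time", window="combined", pis=float(drops.mean()),
                                ci_low=float(lo), ci_high=float(hi),
                                significant=bool(lo > 0 or hi < 0)))
    return entries


def pis_frame(entries: list[PISEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def confident_wrong(probabilities, labels, low: float = 0.2, high: float = 0.8,
                    cdai_values=None) -> dict:
    """Samples the model is confident about (p < low or p > high) yet misclassifies.

    Correctness is judged at the 0.5 threshold.  When the index-visit CDAI
    values are supplied, those of the confident-wrong samples are returned.
    """
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    confident = (p > high) | (p < low)
    wrong = (p > 0.5).astype(int) != y
    cw = confident & wrong
    out = {
        "n": int(len(p)),
        "n_confident": int(confident.sum()),
        "n_confident_wrong": int(cw.sum()),
        "rate_confident_wrong": float(cw.mean()) if len(p) else 0.0,
    }
    if cdai_values is not None:
        out["confident_wrong_cdai"] = list(np.asarray(cdai_values, dtype=float)[cw])
    return out


def subgroup_performance(probabilities, labels, categories) -> pd.DataFrame:
    """Thresholded accuracy and mean probability per future-CDAI category."""
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    cats = np.asarray(categories)
    pred = (p > 0.5).astype(int)
    rows = []
    for cat in ("remission", "low", "moderate", "high"):
        m = cats == cat
        if not m.any():
            continue
        rows.append({"category": cat, "n": int(m.sum()),
                     "accuracy": float((pred[m] == y[m]).mean()),
                     "mean_probability": float(p[m].mean())})
    return pd.DataFrame(rows)


def learning_curve(model_factory, X_pool, y_pool, X_test, y_test,
                   sizes: list[int], repeats: int = 3, seed: int = 0) -> list[LearningCurvePoint]:
    """Test AUROC against training-set size.

    For each size, subsamples the pool without replacement ``repeats`` times
    (different subsample seeds), trains a fresh model from ``model_factory(seed)``
    with otherwise fixed hyperparameters, and scores the fixed test set.
    """
    X_pool = np.asarray(X_pool, dtype=float)
    y_pool = np.asarray(y_pool).ravel().astype(int)
    n = len(y_pool)
    points = []
    for size in sizes:
        if size > n:
            raise ValueError(f"size {size} exceeds pool size {n}")
        aucs = []
        for rep in range(repeats):
            rng = np.random.default_rng((seed, size, rep))
            if size == n:
                idx = np.arange(n)     # full pool: identical to a direct run
            else:
                while True:
                    idx = rng.choice(n, size=size, replace=False)
                    if len(np.unique(y_pool[idx])) == 2:
                        break
            est = model_factory(seed + rep)
            est.fit(X_pool[idx], y_pool[idx])
            aucs.append(auroc(est.predict_proba(X_test)[:, 1], y_test))
        points.append(LearningCurvePoint(n_train=int(size), mean_auc=float(np.mean(aucs)),
                                         sd_auc=float(np.std(aucs)), aucs=tuple(aucs)))
    return points


def confusion_plot(embeddings, labels, seed: int = 0, out_path=None,
                   perplexity: float | None = None):
    """2-D t-SNE of the learned patient representations, colored by true outcome.

    Returns the (n, 2) coordinates; writes a figure when ``out_path`` is given.
    """
    from sklearn.manifold import TSNE

    E = np.asarray(embeddings, dtype=float)
    if len(E) < 5:
        raise ValueError("need at least 5 points for a 2-D embedding")
    y = np.asarray(labels).ravel()
    perp = perplexity if perplexity is not None else min(30.0, max(2.0, (len(E) - 1) / 3 - 1))
    coords = TSNE(n_components=2, random_state=seed, perplexity=perp,
                  init="pca", max_iter=500).fit_transform(E)
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        for val, color in ((0, "tab:blue"), (1, "tab:red")):
            m = y == val
            ax.scatter(coords[m, 0], coords[m, 1], s=12, c=color, alpha=0.7,
                       label="controlled" if val == 0 else "uncontrolled")
        ax.set_xlabel("t-SNE 1"); ax.set_ylabel("t-SNE 2")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return coords
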