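"""Minimal numpy neural-network core for the forecasters.

Implements exactly the two architectures the package needs — a recurrent
network (time-distributed dense transform shared across windows, stacked
gated recurrent unit layers, sigmoid head) and a plain feed-forward network —
with manual backpropagation(-through-time), inverted dropout, L2 weight
decay and Adam.  Everything is float64 and driven by explicit
``numpy.random.Generator`` objects, so training is bit-reproducible given a
seed and fixed BLAS threading.

GRU update (per window t, layer input ``x_t``, state ``h``)::

    z = sigmoid(x_t Wz + h Uz + bz)          # update gate
    r = sigmoid(x_t Wr + h Ur + br)          # reset gate
    hh = tanh(x_t Wh + (r * h) Uh + bh)      # candidate
    h  = (1 - z) * h + z * hh
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class RecurrentNet:
    """Time-distributed dense -> stacked GRUs -> dense sigmoid, on (B, T, D) input."""

    def __init__(self, input_dim: int, td_units: int, gru_units: tuple[int, ...],
                 dropout: float, seed: int):
        rng = np.random.default_rng(seed)
        self.dropout = float(dropout)
        self.gru_units = tuple(gru_units)
        p: dict[str, np.ndarray] = {
            "W_td": _glorot(rng, input_dim, td_units), "b_td": np.zeros(td_units)}
        d = td_units
        for li, h in enumerate(self.gru_units):
            for gate in ("z", "r", "h"):
                p[f"W{gate}{li}"] = _glorot(rng, d, h)
                p[f"U{gate}{li}"] = _orthogonal(rng, h)
                p[f"b{gate}{li}"] = np.zeros(h)
            d = h
        p["W_out"] = _glorot(rng, d, 1)
        p["b_out"] = np.zeros(1)
        self.params = p
        self.embedding_dim = d

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
        """Return (probabilities (B,), cache for backward)."""
        B, T, _ = x.shape
        cache: dict = {"x": x, "masks": {}}

        def drop(a: np.ndarray, key: str) -> np.ndarray:
            if not train or self.dropout <= 0:
                return a
            mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
            cache["masks"][key] = mask
            return a * mask

        a_td = x @ self.params["W_td"] + self.params["b_td"]
        h_td = np.maximum(a_td, 0.0)
        cache["a_td"] = a_td
        inp = drop(h_td, "td")

        cache["layers"] = []
        for li, H in enumerate(self.gru_units):
            Wz, Uz, bz = self.params[f"Wz{li}"], self.params[f"Uz{li}"], self.params[f"bz{li}"]
            Wr, Ur, br = self.params[f"Wr{li}"], self.params[f"Ur{li}"], self.params[f"br{li}"]
            Wh, Uh, bh = self.params[f"Wh{li}"], self.params[f"Uh{li}"], self.params[f"bh{li}"]
            h = np.zeros((B, H))
            zs, rs, hhs, hs = [], [], [], []
            for t in range(T):
                xt = inp[:, t, :]
                z = _sigmoid(xt @ Wz + h @ Uz + bz)
                r = _sigmoid(xt @ Wr + h @ Ur + br)
                hh = np.tanh(xt @ Wh + (r * h) @ Uh + bh)
                h_new = (1.0 - z) * h + z * hh
                zs.append(z); rs.append(r); hhs.append(hh); hs.append(h_new)
                h = h_new
            seq = np.stack(hs, axis=1)
            cache["layers"].append({"inp": inp, "z": zs, "r": rs, "hh": hhs, "h": hs})
            inp = drop(seq, f"gru{li}") if li < len(self.gru_units) - 1 else seq

        h_last = cache["layers"][-1]["h"][-1]
        h_fin = drop(h_last, "head") if train else h_last
        cache["h_fin"] = h_fin
        logits = (h_fin @ self.params["W_out"] + self.params["b_out"]).ravel()
        probs = _sigmoid(logits)
        cache["probs"] = probs
        return probs, cache

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Final pre-output representation (last GRU hidden state)."""
        _, cache = self.forward(x, train=False)
        return cache["layers"][-1]["h"][-1].copy()

    # -- backward --------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the summed loss wrt every parameter; ``dlogits`` is dL/dlogit."""
        g = {k: np.zeros_like(v) for k, v in self.params.items()}
        masks = cache["masks"]
        h_fin = cache["h_fin"]
        dl = dlogits[:, None]
        g["W_out"] = h_fin.T @ dl
        g["b_out"] = dl.sum(axis=0)
        dh_last = dl @ self.params["W_out"].T
        if "head" in masks:
            dh_last = dh_last * masks["head"]

        B, T, _ = cache["x"].shape
        # gradient wrt each layer's output sequence; start with only the last step set
        n_layers = len(self.gru_units)
        dseq = np.zeros((B, T, self.gru_units[-1]))
        dseq[:, T - 1, :] = dh_last

        for li in range(n_layers - 1, -1, -1):
            lc = cache["layers"][li]
            inp = lc["inp"]
            H = self.gru_units[li]
            Wz, Uz = self.params[f"Wz{li}"], self.params[f"Uz{li}"]
            Wr, Ur = self.params[f"Wr{li}"], self.params[f"Ur{li}"]
            Wh, Uh = self.params[f"Wh{li}"], self.params[f"Uh{li}"]
            dinp = np.zeros_like(inp)
            dh = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                dh = dh + dseq[:, t, :]
                z, r, hh = lc["z"][t], lc["r"][t], lc["hh"][t]
                h_prev = lc["h"][t - 1] if t > 0 else np.zeros((B, H))
                dz = dh * (hh - h_prev)
                dhh = dh * z
                dh_prev = dh * (1.0 - z)
                dahh = dhh * (1.0 - hh ** 2)
                g[f"Wh{li}"] += inp[:, t, :].T @ dahh
                g[f"Uh{li}"] += (r * h_prev).T @ dahh
                g[f"bh{li}"] += dahh.sum(axis=0)
                drh = dahh @ Uh.T
                dr = drh * h_prev
                dh_prev = dh_prev + drh * r
                daz = dz * z * (1.0 - z)
                dar = dr * r * (1.0 - r)
                g[f"Wz{li}"] += inp[:, t, :].T @ daz
                g[f"Uz{li}"] += h_prev.T @ daz
                g[f"bz{li}"] += daz.sum(axis=0)
                g[f"Wr{li}"] += inp[:, t, :].T @ dar
                g[f"Ur{li}"] += h_prev.T @ dar
                g[f"br{li}"] += dar.sum(axis=0)
                dinp[:, t, :] = daz @ Wz.T + dar @ Wr.T + dahh @ Wh.T
                dh_prev = dh_prev + daz @ Uz.T + dar @ Ur.T
                dh = dh_prev
            if li > 0:
                key = f"gru{li - 1}"
                if key in masks:
                    dinp = dinp * masks[key]
                dseq = dinp
            else:
                if "td" in masks:
                    dinp = dinp * masks["td"]
                dinp = dinp * (cache["a_td"] > 0)
                x = cache["x"]
                g["W_td"] = np.einsum("btd,bth->dh", x, dinp)
                g["b_td"] = dinp.sum(axis=(0, 1))
        return g


class DenseNet:
    """Plain feed-forward network with relu hidden layers and a sigmoid head."""

    def __init__(self, input_dim: int, hidden_units: tuple[int, ...],
                 dropout: float, seed: int):
        rng = np.random.default_rng(seed)
        self.dropout = float(dropout)
        self.hidden_units = tuple(hidden_units)
        p: dict[str, np.ndarray] = {}
        d = input_dim
        for li, h in enumerate(self.hidden_units):
            p[f"W{li}"] = _glorot(rng, d, h)
            p[f"b{li}"] = np.zeros(h)
            d = h
        p["W_out"] = _glorot(rng, d, 1)
        p["b_out"] = np.zeros(1)
        self.params = p
        self.embedding_dim = d

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
        cache: dict = {"x": x, "masks": {}, "acts": []}
        a = x
        for li in range(len(self.hidden_units)):
            pre = a @ self.params[f"W{li}"] + self.params[f"b{li}"]
            h = np.maximum(pre, 0.0)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                cache["masks"][li] = mask
                h = h * mask
            cache["acts"].append((a, pre, h))
            a = h
        cache["h_fin"] = a
        logits = (a @ self.params["W_out"] + self.params["b_out"]).ravel()
        cache["probs"] = _sigmoid(logits)
        return cache["probs"], cache

    def embed(self, x: np.ndarray) -> np.ndarray:
        _, cache = self.forward(x, train=False)
        if self.hidden_units:
            return cache["acts"][-1][2].copy()
        return cache["x"].copy()

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        g = {k: np.zeros_like(v) for k, v in self.params.items()}
        dl = dlogits[:, None]
        g["W_out"] = cache["h_fin"].T @ dl
        g["b_out"] = dl.sum(axis=0)
        da = dl @ self.params["W_out"].T
        for li in range(len(self.hidden_units) - 1, -1, -1):
            a_in, pre, _ = cache["acts"][li]
            if li in cache["masks"]:
                da = da * cache["masks"][li]
            dpre = da * (pre > 0)
            g[f"W{li}"] = a_in.T @ dpre
            g[f"b{li}"] = dpre.sum(axis=0)
            da = dpre @ self.params[f"W{li}"].T
        return g


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             trainable: set[str] | None = None) -> None:
        self.t += 1
        for k in params:
            if trainable is not None and k not in trainable:
                continue
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_grad(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and dL/dlogit (already divided by batch size)."""
    eps = 1e-12
    loss = -float(np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    return loss, (probs - y) / len(y)


def train_network(net, X: np.ndarray, y: np.ndarray,
                  X_val: np.ndarray | None, y_val: np.ndarray | None,
                  learning_rate: float, batch_size: int, max_epochs: int,
                  patience: int, l2_penalty: float, seed: int,
                  trainable: set[str] | None = None,
                  score_fn=None) -> list[dict]:
    """Minibatch-shuffled Adam training with early stopping on validation AUROC.

    Mutates ``net.params`` in place, restoring the best-validation weights at
    the end; returns the per-epoch history.  ``score_fn(scores, labels)``
    defaults to the package's AUROC.
    """
    from .evaluate import auroc as _auroc
    score_fn = score_fn or _auroc

    rng = np.random.default_rng(seed)
    opt = Adam(net.params, learning_rate)
    n = len(y)
    history: list[dict] = []
    best_metric, best_params, since_best = -np.inf, None, 0
    use_val = X_val is not None and y_val is not None and len(set(y_val)) == 2

    weight_keys = [k for k in net.params if k.startswith(("W", "U"))]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            bi = order[start:start + batch_size]
            probs, cache = net.forward(X[bi], train=True, rng=rng)
            loss, dlogits = bce_grad(probs, y[bi])
            grads = net.backward(cache, dlogits)
            if l2_penalty > 0:
                for k in weight_keys:
                    grads[k] += l2_penalty * net.params[k]
                    loss += 0.5 * l2_penalty * float(np.sum(net.params[k] ** 2)) / max(n, 1)
            opt.step(net.params, grads, trainable)
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if use_val:
            val_probs, _ = net.forward(X_val, train=False)
            row["val_auroc"] = float(score_fn(val_probs, y_val))
            if row["val_auroc"] > best_metric + 1e-9:
                best_metric = row["val_auroc"]
                best_params = {k: v.copy() for k, v in net.params.items()}
                since_best = 0
            else:
                since_best += 1
        history.append(row)
        if use_val and since_best > patience:
            break
    if best_params is not None:
        net.params.update(best_params)
    return history
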