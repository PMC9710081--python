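"""Minimal numpy neural networks: MLP, simple RNN and LSTM (forget-gate).

All three are many-to-one classifiers ending in a 2-unit dense softmax
layer, trained with categorical cross-entropy and the ADAM optimizer
(alpha=1e-3, beta1=0.9, beta2=0.999, eps=1e-7).  Parameters live in plain
dicts of float64 arrays; every model exposes

* ``init_params(rng)`` — fan-in-scaled symmetric uniform initialisation,
* ``forward(params, X)`` — class probabilities,
* ``loss_and_grads(params, X, Y, ...)`` — loss plus analytic gradients,

and the analytic gradients are verified against central finite differences
in the test suite.

Recurrent conventions: hidden (and cell) state start at zero; the simple
RNN hidden update is ``h_t = sigma(Whx x_t + Whh h_{t-1} + bh)`` and the
LSTM uses tanh for the input node and state squashing with sigmoid gates,
``s_t = g*i + s_{t-1}*f`` and ``h_t = tanh(s_t)*o``.  The output is read
only at the final time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# --- activations -----------------------------------------------------------

def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


_ACT = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a ** 2),
    "sigmoid": (sigmoid, lambda z, a: a * (1.0 - a)),
}


def _uniform(rng, shape, fan_in):
    limit = 1.0 / np.sqrt(max(1, fan_in))
    return rng.uniform(-limit, limit, size=shape)


def cross_entropy(probs: np.ndarray, Y: np.ndarray) -> float:
    """Mean categorical cross-entropy; Y is one-hot (n, 2)."""
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(Y * np.log(p)).sum(axis=1).mean())


def onehot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return Y


# ---------------------------------------------------------------------------
# MLP (3 dense layers, dropout after each hidden layer)
# ---------------------------------------------------------------------------

class MLPNet:
    def __init__(self, n_features: int, hidden: tuple = (64, 64),
                 activation: str = "relu",
                 dropout: tuple = (0.2152, 0.1758)):
        self.n_features = n_features
        self.hidden = tuple(hidden)
        self.activation = activation
        self.dropout = tuple(dropout)
        self.l2_keys: tuple = ()

    def init_params(self, rng) -> dict:
        f, (h1, h2) = self.n_features, self.hidden
        return {
            "W1": _uniform(rng, (h1, f), f), "b1": np.zeros(h1),
            "W2": _uniform(rng, (h2, h1), h1), "b2": np.zeros(h2),
            "W3": _uniform(rng, (2, h2), h2), "b3": np.zeros(2),
        }

    def forward(self, params, X, dropout_rng=None):
        act, _ = _ACT[self.activation]
        Z1 = X @ params["W1"].T + params["b1"]
        H1 = act(Z1)
        H1 = _dropout(H1, self.dropout[0], dropout_rng)
        Z2 = H1 @ params["W2"].T + params["b2"]
        H2 = act(Z2)
        H2 = _dropout(H2, self.dropout[1], dropout_rng)
        return softmax(H2 @ params["W3"].T + params["b3"])

    def loss_and_grads(self, params, X, Y, l2: float = 0.0, dropout_rng=None):
        act, dact = _ACT[self.activation]
        n = X.shape[0]
        Z1 = X @ params["W1"].T + params["b1"]
        H1 = act(Z1)
        H1d, m1 = _dropout_mask(H1, self.dropout[0], dropout_rng)
        Z2 = H1d @ params["W2"].T + params["b2"]
        H2 = act(Z2)
        H2d, m2 = _dropout_mask(H2, self.dropout[1], dropout_rng)
        P = softmax(H2d @ params["W3"].T + params["b3"])
        loss = cross_entropy(P, Y)

        dZ3 = (P - Y) / n
        g = {"W3": dZ3.T @ H2d, "b3": dZ3.sum(axis=0)}
        dH2 = (dZ3 @ params["W3"]) * m2
        dZ2 = dH2 * dact(Z2, H2)
        g["W2"] = dZ2.T @ H1d
        g["b2"] = dZ2.sum(axis=0)
        dH1 = (dZ2 @ params["W2"]) * m1
        dZ1 = dH1 * dact(Z1, H1)
        g["W1"] = dZ1.T @ X
        g["b1"] = dZ1.sum(axis=0)
        return loss, g


def _dropout(H, rate, rng):
    if rng is None or rate <= 0:
        return H
    mask = (rng.random(H.shape) >= rate) / (1.0 - rate)
    return H * mask


def _dropout_mask(H, rate, rng):
    if rng is None or rate <= 0:
        return H, 1.0
    mask = (rng.random(H.shape) >= rate) / (1.0 - rate)
    return H * mask, mask


# ---------------------------------------------------------------------------
# Simple RNN
# ---------------------------------------------------------------------------

class SimpleRNNNet:
    def __init__(self, n_features: int, hidden: int = 8,
                 activation: str = "sigmoid"):
        self.n_features = n_features
        self.hidden = hidden
        self.activation = activation
        # a single L2 strength penalises the recurrent layer's weights
        self.l2_keys = ("Whx", "Whh")

    def init_params(self, rng) -> dict:
        f, h = self.n_features, self.hidden
        return {
            "Whx": _uniform(rng, (h, f), f),
            "Whh": _uniform(rng, (h, h), h),
            "bh": np.zeros(h),
            "Wyh": _uniform(rng, (2, h), h),
            "by": np.zeros(2),
        }

    def _scan(self, params, X):
        act, _ = _ACT[self.activation]
        n, T, _ = X.shape
        h = np.zeros((n, self.hidden))
        As, Hs = [], [h]
        for t in range(T):
            A = X[:, t, :] @ params["Whx"].T + h @ params["Whh"].T + params["bh"]
            h = act(A)
            As.append(A)
            Hs.append(h)
        return As, Hs

    def forward(self, params, X, dropout_rng=None):
        _, Hs = self._scan(params, X)
        return softmax(Hs[-1] @ params["Wyh"].T + params["by"])

    def loss_and_grads(self, params, X, Y, l2: float = 0.0, dropout_rng=None):
        act, dact = _ACT[self.activation]
        n, T, _ = X.shape
        As, Hs = self._scan(params, X)
        P = softmax(Hs[-1] @ params["Wyh"].T + params["by"])
        loss = cross_entropy(P, Y) + l2 * sum(
            float((params[k] ** 2).sum()) for k in self.l2_keys)

        dZ = (P - Y) / n
        g = {k: np.zeros_like(v) for k, v in params.items()}
        g["Wyh"] = dZ.T @ Hs[-1]
        g["by"] = dZ.sum(axis=0)
        dh = dZ @ params["Wyh"]
        for t in range(T - 1, -1, -1):
            dA = dh * dact(As[t], Hs[t + 1])
            g["Whx"] += dA.T @ X[:, t, :]
            g["Whh"] += dA.T @ Hs[t]
            g["bh"] += dA.sum(axis=0)
            dh = dA @ params["Whh"]
        for k in self.l2_keys:
            g[k] += 2.0 * l2 * params[k]
        return loss, g


# ---------------------------------------------------------------------------
# LSTM with forget gate
# ---------------------------------------------------------------------------

class LSTMNet:
    GATES = ("g", "i", "f", "o")

    def __init__(self, n_features: int, hidden: int = 4):
        self.n_features = n_features
        self.hidden = hidden
        self.l2_keys = tuple(f"W{u}{v}" for u in self.GATES for v in ("x", "h"))

    def init_params(self, rng) -> dict:
        f, h = self.n_features, self.hidden
        params = {}
        for u in self.GATES:
            params[f"W{u}x"] = _uniform(rng, (h, f), f)
            params[f"W{u}h"] = _uniform(rng, (h, h), h)
            params[f"b{u}"] = np.zeros(h)
        params["Wyh"] = _uniform(rng, (2, h), h)
        params["by"] = np.zeros(2)
        return params

    def _scan(self, params, X):
        n, T, _ = X.shape
        h = np.zeros((n, self.hidden))
        s = np.zeros((n, self.hidden))
        cache = []
        for t in range(T):
            x = X[:, t, :]
            pre = {u: x @ params[f"W{u}x"].T + h @ params[f"W{u}h"].T
                   + params[f"b{u}"] for u in self.GATES}
            gt = np.tanh(pre["g"])
            it = sigmoid(pre["i"])
            ft = sigmoid(pre["f"])
            ot = sigmoid(pre["o"])
            s_new = gt * it + s * ft
            tanh_s = np.tanh(s_new)
            h_new = tanh_s * ot
            cache.append(dict(x=x, h_prev=h, s_prev=s, g=gt, i=it, f=ft,
                              o=ot, s=s_new, tanh_s=tanh_s))
            h, s = h_new, s_new
        return cache, h

    def forward(self, params, X, dropout_rng=None):
        _, h = self._scan(params, X)
        return softmax(h @ params["Wyh"].T + params["by"])

    def loss_and_grads(self, params, X, Y, l2: float = 0.0, dropout_rng=None):
        n, T, _ = X.shape
        cache, hT = self._scan(params, X)
        P = softmax(hT @ params["Wyh"].T + params["by"])
        loss = cross_entropy(P, Y) + l2 * sum(
            float((params[k] ** 2).sum()) for k in self.l2_keys)

        dZ = (P - Y) / n
        g = {k: np.zeros_like(v) for k, v in params.items()}
        g["Wyh"] = dZ.T @ hT
        g["by"] = dZ.sum(axis=0)
        dh = dZ @ params["Wyh"]
        ds = np.zeros_like(dh)
        for t in range(T - 1, -1, -1):
            c = cache[t]
            do = dh * c["tanh_s"]
            ds = ds + dh * c["o"] * (1.0 - c["tanh_s"] ** 2)
            dg = ds * c["i"]
            di = ds * c["g"]
            df = ds * c["s_prev"]
            pre_grads = {
                "g": dg * (1.0 - c["g"] ** 2),
                "i": di * c["i"] * (1.0 - c["i"]),
                "f": df * c["f"] * (1.0 - c["f"]),
                "o": do * c["o"] * (1.0 - c["o"]),
            }
            dh = np.zeros_like(dh)
            for u in self.GATES:
                dA = pre_grads[u]
                g[f"W{u}x"] += dA.T @ c["x"]
                g[f"W{u}h"] += dA.T @ c["h_prev"]
                g[f"b{u}"] += dA.sum(axis=0)
                dh += dA @ params[f"W{u}h"]
            ds = ds * c["f"]
        for k in self.l2_keys:
            g[k] += 2.0 * l2 * params[k]
        return loss, g


# ---------------------------------------------------------------------------
# ADAM and the training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimisation settings; ADAM defaults are the standard published ones."""

    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    l2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")


class Adam:
    def __init__(self, params: dict, cfg: TrainingConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for k in params:
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * grads[k]
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * grads[k] ** 2
            params[k] -= c.learning_rate * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + c.eps)


def fit_network(net, X: np.ndarray, y: np.ndarray, cfg: TrainingConfig,
                X_val: Optional[np.ndarray] = None,
                y_val: Optional[np.ndarray] = None,
                use_dropout: bool = True) -> tuple[dict, dict]:
    """Mini-batch ADAM training; returns (params, history).

    Deterministic given ``cfg.seed``: initialisation, epoch shuffles and
    dropout masks all derive from one seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    params = net.init_params(rng)
    opt = Adam(params, cfg)
    Y = onehot(y)
    n = X.shape[0]
    history = {"loss": [], "val_loss": []}
    has_dropout = use_dropout and getattr(net, "dropout", None) is not None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = net.loss_and_grads(
                params, X[idx], Y[idx], l2=cfg.l2,
                dropout_rng=rng if has_dropout else None)
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss {loss} at epoch {epoch}")
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        history["loss"].append(epoch_loss / n)
        if X_val is not None:
            pv = net.forward(params, X_val)
            history["val_loss"].append(cross_entropy(pv, onehot(y_val)))
    return params, history


# --- functional forward wrappers (single instance or batch) ----------------

def mlp_forward(net: MLPNet, params: dict, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = net.forward(params, x)
    return out[0] if out.shape[0] == 1 else out


def simple_rnn_forward(net: SimpleRNNNet, params: dict,
                       sequence: np.ndarray) -> np.ndarray:
    X = np.asarray(sequence, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] < 1:
        raise ValueError("sequence must have length >= 1")
    out = net.forward(params, X)
    return out[0] if out.shape[0] == 1 else out


def lstm_forward(net: LSTMNet, params: dict,
                 sequence: np.ndarray) -> np.ndarray:
    X = np.asarray(sequence, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] < 1:
        raise ValueError("sequence must have length >= 1")
    out = net.forward(params, X)
    return out[0] if out.shape[0] == 1 else out
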