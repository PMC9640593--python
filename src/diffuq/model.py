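"""Recurrent network, output heads and aleatoric-uncertainty losses.

The architecture is a stack of LSTM layers (default sizes 128, 128, 64)
consuming the normalised increment series; the final hidden state feeds the
output head. The regression head emits a predictive mean and a log-variance
(clamped to [-10, 10] before exponentiation, so the reported standard
deviation is always positive); the classification head passes through a
fully connected ReLU layer of size 20 and emits logits over the five
diffusion models, turned into probabilities by a softmax.

Everything — forward pass, backpropagation through time, parameter
(un)flattening — is implemented on plain numpy arrays so the weight vector
can be manipulated directly by the SWAG posterior machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .simulators import MODELS

LOGVAR_CLAMP = 10.0
PROB_FLOOR = 1e-12

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture descriptor; hashable so caches can key on it."""

    head: str                                   # 'regression' | 'classification'
    lstm_sizes: tuple[int, ...] = (128, 128, 64)
    hidden_fc: int = 20                         # classification only
    input_dim: int = 1

    def __post_init__(self) -> None:
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")
        if not self.lstm_sizes or any(s < 1 for s in self.lstm_sizes):
            raise ValueError("lstm_sizes must be positive")
        object.__setattr__(self, "lstm_sizes", tuple(int(s) for s in self.lstm_sizes))

    @property
    def output_dim(self) -> int:
        return 2 if self.head == "regression" else len(MODELS)


@dataclass
class RegressionPrediction:
    mu: np.ndarray
    sigma: np.ndarray   # predictive standard deviation, > 0

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


@dataclass
class ClassificationPrediction:
    probs: np.ndarray   # (n, 5) rows on the simplex, canonical model order

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[1] != len(MODELS):
            raise ValueError("probability vectors must have 5 entries")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


# ---------------------------------------------------------------- parameters

def param_shapes(spec: NetworkSpec) -> dict[str, tuple[int, ...]]:
    """Ordered name -> shape map; the flattening order of the weight vector."""
    shapes: dict[str, tuple[int, ...]] = {}
    n_in = spec.input_dim
    for l, nh in enumerate(spec.lstm_sizes):
        shapes[f"lstm{l}_W"] = (n_in + nh, 4 * nh)
        shapes[f"lstm{l}_b"] = (4 * nh,)
        n_in = nh
    if spec.head == "classification":
        shapes["fc_W"] = (n_in, spec.hidden_fc)
        shapes["fc_b"] = (spec.hidden_fc,)
        n_in = spec.hidden_fc
    shapes["head_W"] = (n_in, spec.output_dim)
    shapes["head_b"] = (spec.output_dim,)
    return shapes


def n_params(spec: NetworkSpec) -> int:
    return sum(int(np.prod(s)) for s in param_shapes(spec).values())


def init_params(spec: NetworkSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, forget-gate bias 1."""
    params: dict[str, np.ndarray] = {}
    for name, shape in param_shapes(spec).items():
        if name.endswith("_b"):
            b = np.zeros(shape)
            if name.startswith("lstm"):
                nh = shape[0] // 4
                b[nh:2 * nh] = 1.0
            params[name] = b
        else:
            fan_in, fan_out = shape
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            params[name] = rng.uniform(-lim, lim, size=shape)
    return params


def flatten(params: dict[str, np.ndarray], spec: NetworkSpec) -> np.ndarray:
    return np.concatenate([params[k].ravel() for k in param_shapes(spec)])


def unflatten(theta: np.ndarray, spec: NetworkSpec) -> dict[str, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    if theta.size != n_params(spec):
        raise ValueError("weight vector size mismatch")
    out, i = {}, 0
    for name, shape in param_shapes(spec).items():
        k = int(np.prod(shape))
        out[name] = theta[i:i + k].reshape(shape).copy()
        i += k
    return out


# ------------------------------------------------------------------ forward

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _lstm_forward(W: np.ndarray, b: np.ndarray, X: np.ndarray):
    """One LSTM layer over a full (B, T, n_in) batch; returns H and caches."""
    B, T, n_in = X.shape
    nh = b.size // 4
    Wx, Wh = W[:n_in], W[n_in:]
    H = np.empty((B, T, nh))
    gates = np.empty((B, T, 4 * nh))
    C = np.empty((B, T, nh))
    h = np.zeros((B, nh))
    c = np.zeros((B, nh))
    for t in range(T):
        z = X[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :nh])
        f = _sigmoid(z[:, nh:2 * nh])
        g = np.tanh(z[:, 2 * nh:3 * nh])
        o = _sigmoid(z[:, 3 * nh:])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[:, t, :nh] = i
        gates[:, t, nh:2 * nh] = f
        gates[:, t, 2 * nh:3 * nh] = g
        gates[:, t, 3 * nh:] = o
        C[:, t] = c
        H[:, t] = h
    return H, (X, gates, C, H)


def _lstm_backward(W: np.ndarray, cache, dH: np.ndarray):
    """Backpropagation through time for one layer.

    dH holds the gradients flowing into each hidden output h_t. Returns the
    gradient with respect to the layer input and the parameter gradients.
    """
    X, gates, C, H = cache
    B, T, n_in = X.shape
    nh = C.shape[2]
    Wx, Wh = W[:n_in], W[n_in:]
    dW = np.zeros_like(W)
    db = np.zeros(4 * nh)
    dX = np.empty_like(X)
    dh_next = np.zeros((B, nh))
    dc_next = np.zeros((B, nh))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :nh]
        f = gates[:, t, nh:2 * nh]
        g = gates[:, t, 2 * nh:3 * nh]
        o = gates[:, t, 3 * nh:]
        c = C[:, t]
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, nh))
        h_prev = H[:, t - 1] if t > 0 else np.zeros((B, nh))
        tc = np.tanh(c)
        dh = dH[:, t] + dh_next
        dc = dc_next + dh * o * (1.0 - tc * tc)
        dz = np.empty((B, 4 * nh))
        dz[:, :nh] = dc * g * i * (1.0 - i)
        dz[:, nh:2 * nh] = dc * c_prev * f * (1.0 - f)
        dz[:, 2 * nh:3 * nh] = dc * i * (1.0 - g * g)
        dz[:, 3 * nh:] = dh * tc * o * (1.0 - o)
        dW[:n_in] += X[:, t].T @ dz
        dW[n_in:] += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dX, dW, db


def _forward_net(params: dict, spec: NetworkSpec, X: np.ndarray, need_cache: bool):
    """Run the stack; returns raw head output plus caches for backprop."""
    caches = []
    A = X
    for l in range(len(spec.lstm_sizes)):
        A, cache = _lstm_forward(params[f"lstm{l}_W"], params[f"lstm{l}_b"], A)
        caches.append(cache)
    h_last = A[:, -1]
    fc_pre = None
    if spec.head == "classification":
        fc_pre = h_last @ params["fc_W"] + params["fc_b"]
        h_head = np.maximum(fc_pre, 0.0)
    else:
        h_head = h_last
    out = h_head @ params["head_W"] + params["head_b"]
    if not need_cache:
        return out, None
    return out, (caches, h_last, fc_pre, h_head)


def _as_batch(incs: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    X = np.asarray(incs, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim == 2:
        X = X[:, :, None]
    if X.shape[1] < 1:
        raise ValueError("increment series must have length >= 1")
    if X.shape[2] != spec.input_dim:
        raise ValueError("input dimension mismatch")
    return X


def forward(params: dict, spec: NetworkSpec,
            incs: np.ndarray) -> RegressionPrediction | ClassificationPrediction:
    """Deterministic prediction for a batch (or single) increment series."""
    X = _as_batch(incs, spec)
    out, _ = _forward_net(params, spec, X, need_cache=False)
    if spec.head == "regression":
        logvar = np.clip(out[:, 1], -LOGVAR_CLAMP, LOGVAR_CLAMP)
        return RegressionPrediction(out[:, 0], np.exp(0.5 * logvar))
    return ClassificationPrediction(softmax(out))


# ------------------------------------------------------------------- losses

def softmax(logits: np.ndarray) -> np.ndarray:
    """Normalised exponential along the last axis, max-subtracted for stability."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gaussian_nll(mu, sigma, target, reduction: str = "mean") -> float:
    """Heteroscedastic Gaussian negative log-likelihood, constant dropped.

    Per sample: (log sigma^2 + (mu - target)^2 / sigma^2) / 2.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    target = np.atleast_1d(np.asarray(target, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    var = sigma ** 2
    per = 0.5 * (np.log(var) + (mu - target) ** 2 / var)
    return float(per.mean() if reduction == "mean" else per.sum())


def cross_entropy(probs, true_class, reduction: str = "mean") -> float:
    """-log p_true, probabilities clamped at 1e-12 before the log."""
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    idx = np.atleast_1d(np.asarray(true_class, dtype=int))
    p_true = np.clip(p[np.arange(len(idx)), idx], PROB_FLOOR, None)
    per = -np.log(p_true)
    return float(per.mean() if reduction == "mean" else per.sum())


def loss_and_grad(params: dict, spec: NetworkSpec, X: np.ndarray,
                  y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """Mean batch loss and its gradient with respect to every parameter.

    Regression targets are the true exponents (float); classification targets
    are integer class indices in canonical model order.
    """
    X = _as_batch(X, spec)
    B = X.shape[0]
    out, cache = _forward_net(params, spec, X, need_cache=True)
    caches, h_last, fc_pre, h_head = cache
    dout = np.empty_like(out)
    if spec.head == "regression":
        y = np.asarray(y, dtype=float)
        mu = out[:, 0]
        raw_lv = out[:, 1]
        logvar = np.clip(raw_lv, -LOGVAR_CLAMP, LOGVAR_CLAMP)
        inv_var = np.exp(-logvar)
        r = mu - y
        loss = float(np.mean(0.5 * (logvar + r * r * inv_var)))
        dout[:, 0] = r * inv_var / B
        dlv = 0.5 * (1.0 - r * r * inv_var) / B
        dlv[np.abs(raw_lv) > LOGVAR_CLAMP] = 0.0   # clamped: zero gradient
        dout[:, 1] = dlv
    else:
        y = np.asarray(y, dtype=int)
        p = softmax(out)
        loss = cross_entropy(p, y, reduction="mean")
        dout = p.copy()
        dout[np.arange(B), y] -= 1.0
        dout /= B

    grads: dict[str, np.ndarray] = {}
    grads["head_W"] = h_head.T @ dout
    grads["head_b"] = dout.sum(axis=0)
    dh = dout @ params["head_W"].T
    if spec.head == "classification":
        dh = dh * (fc_pre > 0)
        grads["fc_W"] = h_last.T @ dh
        grads["fc_b"] = dh.sum(axis=0)
        dh = dh @ params["fc_W"].T
    n_layers = len(spec.lstm_sizes)
    dH = np.zeros(caches[-1][3].shape)
    dH[:, -1] = dh
    for l in range(n_layers - 1, -1, -1):
        dX, dW, db = _lstm_backward(params[f"lstm{l}_W"], caches[l], dH)
        grads[f"lstm{l}_W"] = dW
        grads[f"lstm{l}_b"] = db
        dH = dX
    return loss, grads


# -------------------------------------------------------------- checkpoints

def save_checkpoint(path, spec: NetworkSpec, theta: np.ndarray, extra: dict | None = None) -> None:
    meta = {"version": CHECKPOINT_VERSION, "head": spec.head,
            "lstm_sizes": list(spec.lstm_sizes), "hidden_fc": spec.hidden_fc,
            "input_dim": spec.input_dim}
    arrays = {"theta": np.asarray(theta, dtype=float), "meta": np.bytes_(json.dumps(meta))}
    if extra:
        arrays.update(extra)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[NetworkSpec, np.ndarray, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        spec = NetworkSpec(head=meta["head"], lstm_sizes=tuple(meta["lstm_sizes"]),
                           hidden_fc=meta["hidden_fc"], input_dim=meta["input_dim"])
        theta = z["theta"].copy()
        extra = {k: z[k].copy() for k in z.files if k not in ("theta", "meta")}
    return spec, theta, extra
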