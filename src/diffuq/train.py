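"""Training protocol: Adam pretraining, SWAG collection, ensemble selection.

A run pretrains with Adam for ``epochs_total - epochs_swag`` epochs, then
switches to constant-rate plain SGD for ``epochs_swag`` epochs while folding
the iterates into a SWAG posterior every ``c`` steps (default: once per
epoch). ``build_multiswag`` repeats this for ``n_models`` independent seeds
and keeps the ``n_keep`` states whose SWA mean weights achieve the lowest
validation loss; predictions average ``samples_per_model`` Monte-Carlo weight
draws from each kept state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import (NetworkSpec, cross_entropy, flatten, forward, gaussian_nll,
                    init_params, loss_and_grad, unflatten)
from .preprocess import batch_pipeline
from .simulators import MODELS, LabeledDataset
from .swag import SwagConfig, SwagState, swag_collect, swag_init


@dataclass
class TrainConfig:
    lr_pretrain: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 128
    epochs_total: int = 75     # full training length in epochs
    epochs_swag: int = 12      # trailing epochs run as the SWAG phase
    swag: SwagConfig = field(default_factory=SwagConfig)
    n_models: int = 20         # SWAG models trained
    n_keep: int = 5            # best (by validation loss) kept for Multi-SWAG
    samples_per_model: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.epochs_swag < self.epochs_total):
            raise ValueError("need 0 < epochs_swag < epochs_total")
        if self.n_keep > self.n_models:
            raise ValueError("n_keep must not exceed n_models")
        self.swag.M = self.n_keep * self.samples_per_model


def dataset_to_arrays(ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Normalised increment matrix (n, T-1) and targets (alpha or class index)."""
    X = batch_pipeline(np.stack([t.positions for t in ds.trajectories]))
    if ds.task == "regression":
        y = np.array([t.alpha for t in ds.trajectories], dtype=float)
    else:
        y = np.array([MODELS.index(t.model) for t in ds.trajectories], dtype=int)
    return X, y


def evaluate_loss(theta: np.ndarray, spec: NetworkSpec, X: np.ndarray,
                  y: np.ndarray, batch_size: int = 512) -> float:
    """Mean task loss of a weight vector over a dataset."""
    params = unflatten(theta, spec)
    total, n = 0.0, len(X)
    for s in range(0, n, batch_size):
        xb, yb = X[s:s + batch_size], y[s:s + batch_size]
        pred = forward(params, spec, xb)
        if spec.head == "regression":
            total += gaussian_nll(pred.mu, pred.sigma, yb, reduction="sum")
        else:
            total += cross_entropy(pred.probs, yb, reduction="sum")
    return total / n


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(theta)
            self.v = np.zeros_like(theta)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _grad_flat(theta, spec, xb, yb, weight_decay):
    loss, grads = loss_and_grad(unflatten(theta, spec), spec, xb, yb)
    g = flatten(grads, spec)
    if weight_decay:
        g = g + weight_decay * theta
    return loss, g


def pretrain(spec: NetworkSpec, train: tuple[np.ndarray, np.ndarray],
             val: tuple[np.ndarray, np.ndarray] | None, cfg: TrainConfig,
             rng: np.random.Generator,
             log: list[dict] | None = None) -> np.ndarray:
    """Adam pretraining for epochs_total - epochs_swag epochs; returns weights."""
    X, y = train
    theta = flatten(init_params(spec, rng), spec)
    opt = _Adam(cfg.lr_pretrain)
    n = len(X)
    for epoch in range(cfg.epochs_total - cfg.epochs_swag):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            loss, g = _grad_flat(theta, spec, X[idx], y[idx], cfg.weight_decay)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            theta = opt.step(theta, g)
            losses.append(loss)
        rec = {"phase": "pretrain", "epoch": epoch,
               "train_loss": float(np.mean(losses))}
        if val is not None:
            rec["val_loss"] = evaluate_loss(theta, spec, *val)
        if log is not None:
            log.append(rec)
    return theta


def train_swag_phase(theta0: np.ndarray, spec: NetworkSpec,
                     train: tuple[np.ndarray, np.ndarray], cfg: TrainConfig,
                     rng: np.random.Generator,
                     log: list[dict] | None = None) -> SwagState:
    """Constant-rate SGD for epochs_swag epochs with moment collection.

    The collection frequency defaults to once per epoch (c = steps per
    epoch) when the SWAG config leaves c at 1 and T_swag at 0.
    """
    X, y = train
    n = len(X)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    swag_cfg = cfg.swag
    c = swag_cfg.c if swag_cfg.c is not None else steps_per_epoch
    theta = theta0.copy()
    state = swag_init(theta)
    cfg_eff = SwagConfig(eta=swag_cfg.eta, T_swag=cfg.epochs_swag * steps_per_epoch,
                         c=c, K_cols=swag_cfg.K_cols, M=swag_cfg.M)
    step = 0
    for epoch in range(cfg.epochs_swag):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            loss, g = _grad_flat(theta, spec, X[idx], y[idx], cfg.weight_decay)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite SWAG-phase loss at epoch {epoch}")
            theta = theta - cfg_eff.eta * g
            step += 1
            swag_collect(state, theta, step, cfg_eff)
            losses.append(loss)
        if log is not None:
            log.append({"phase": "swag", "epoch": epoch,
                        "train_loss": float(np.mean(losses)),
                        "n_collected": state.n_collected})
    if state.n_collected < 2:
        raise RuntimeError("SWAG phase produced fewer than 2 moment collections")
    return state


def build_multiswag(spec: NetworkSpec, train: tuple[np.ndarray, np.ndarray],
                    val: tuple[np.ndarray, np.ndarray], cfg: TrainConfig,
                    log: list[dict] | None = None
                    ) -> list[tuple[SwagState, NetworkSpec]]:
    """Train n_models independent SWAG models, keep the n_keep best.

    Ranking uses the validation loss of each model's SWA mean weights; the
    returned list is sorted by that loss, ascending.
    """
    root = np.random.SeedSequence(cfg.master_seed)
    scored = []
    for i, ss in enumerate(root.spawn(cfg.n_models)):
        rng = np.random.default_rng(ss)
        theta0 = pretrain(spec, train, val, cfg, rng, log)
        state = train_swag_phase(theta0, spec, train, cfg, rng, log)
        val_loss = evaluate_loss(state.theta_bar, spec, *val)
        scored.append((val_loss, i, state))
        if log is not None:
            log.append({"phase": "select", "member": i, "val_loss": val_loss})
    scored.sort(key=lambda t: (t[0], t[1]))
    return [(state, spec) for _, _, state in scored[:cfg.n_keep]]


def config_to_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)
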