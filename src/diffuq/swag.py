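"""Stochastic Weight Averaging Gaussian (SWAG) weight posterior.

SWAG interprets the iterates of constant-rate SGD around a pretrained
optimum as approximate samples from the Bayesian weight posterior. It keeps
the running first and second moments of the collected iterates plus a FIFO
deviation matrix of the last K centred iterates, defining the Gaussian

    theta ~ N(theta_bar, 1/2 Sigma_diag + D D^T / (2 (K - 1))),

where Sigma_diag = diag(theta2_bar - theta_bar^2). Deviation columns are
centred on the *running* mean at collection time. Multi-SWAG averages the
predictive distributions of an equal number of Monte-Carlo weight samples
drawn from several independently trained SWAG models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (ClassificationPrediction, NetworkSpec, RegressionPrediction,
                    forward, unflatten)

SIGMA_FLOOR = 1e-8  # floor on the mixture predictive std, keeps sigma > 0


@dataclass
class SwagConfig:
    eta: float = 1e-4        # SGD learning rate during the SWAG phase
    T_swag: int = 0          # number of SWAG training steps (0: derived by caller)
    c: int | None = None     # moment update frequency in steps (None: once per epoch)
    K_cols: int = 20         # max deviation-matrix columns
    M: int = 50              # Monte-Carlo samples in Bayesian model averaging

    def __post_init__(self) -> None:
        if self.K_cols < 2:
            raise ValueError("K_cols must be >= 2")
        if self.c is not None and self.c < 1:
            raise ValueError("c must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass
class SwagState:
    theta_bar: np.ndarray                 # running mean of collected iterates
    theta_sq_bar: np.ndarray              # running elementwise second moment
    dev_columns: list[np.ndarray] = field(default_factory=list)  # FIFO, <= K_cols
    n_collected: int = 0

    @property
    def dev_matrix(self) -> np.ndarray:
        """d x K matrix of deviation columns (d x 0 when empty)."""
        if not self.dev_columns:
            return np.empty((self.theta_bar.size, 0))
        return np.stack(self.dev_columns, axis=1)


def swag_init(theta0: np.ndarray) -> SwagState:
    theta0 = np.asarray(theta0, dtype=float)
    return SwagState(theta_bar=theta0.copy(), theta_sq_bar=theta0 ** 2)


def swag_collect(state: SwagState, theta_i: np.ndarray, step_index: int,
                 cfg: SwagConfig) -> SwagState:
    """Fold iterate theta_i (at SGD step ``step_index``) into the moments.

    Steps that are not multiples of the update frequency are a no-op. The
    deviation column appended is theta_i minus the *updated* running mean;
    the oldest column is evicted once K_cols is exceeded.
    """
    c = 1 if cfg.c is None else cfg.c
    if step_index % c != 0:
        return state
    theta_i = np.asarray(theta_i, dtype=float)
    n = step_index // c
    state.theta_bar = (n * state.theta_bar + theta_i) / (n + 1)
    state.theta_sq_bar = (n * state.theta_sq_bar + theta_i ** 2) / (n + 1)
    state.dev_columns.append(theta_i - state.theta_bar)
    if len(state.dev_columns) > cfg.K_cols:
        state.dev_columns.pop(0)
    state.n_collected += 1
    return state


def swag_covariance(state: SwagState) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal variance vector and the low-rank factor D / sqrt(K_used - 1).

    The Gram product of the factor equals the low-rank covariance term. The
    diagonal is clamped at zero (running moments can go marginally negative
    in floating point).
    """
    if state.n_collected < 2:
        raise ValueError("need at least 2 collected iterates")
    diag = np.clip(state.theta_sq_bar - state.theta_bar ** 2, 0.0, None)
    D = state.dev_matrix
    factor = D / np.sqrt(D.shape[1] - 1)
    return diag, factor


def swag_sample(state: SwagState, cfg: SwagConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Draw a weight vector from N(theta_bar, Sigma_diag/2 + D D^T/(2(K-1)))."""
    diag, _ = swag_covariance(state)
    D = state.dev_matrix
    K_used = D.shape[1]
    z1 = rng.standard_normal(state.theta_bar.size)
    z2 = rng.standard_normal(K_used)
    return (state.theta_bar
            + np.sqrt(0.5 * diag) * z1
            + D @ z2 / np.sqrt(2.0 * (K_used - 1)))


def mixture_moments(mus: np.ndarray, sigmas_sq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First two moments of an equal-weight Gaussian mixture along axis 0.

    mu* = mean(mu_m); sigma*^2 = mean(sigma_m^2) + mean(mu_m^2) - mu*^2.
    """
    mus = np.asarray(mus, dtype=float)
    sigmas_sq = np.asarray(sigmas_sq, dtype=float)
    mu_star = mus.mean(axis=0)
    var_star = sigmas_sq.mean(axis=0) + (mus ** 2).mean(axis=0) - mu_star ** 2
    return mu_star, var_star


def multiswag_predict(states: list[tuple[SwagState, NetworkSpec]], incs: np.ndarray,
                      cfg: SwagConfig, rng: np.random.Generator
                      ) -> RegressionPrediction | ClassificationPrediction:
    """Bayesian model averaging over M weight samples split equally per state.

    Classification averages the probability vectors; regression collapses
    the equal-weight Gaussian mixture to its first two moments:
    mu* = mean(mu_m), sigma*^2 = mean(sigma_m^2) + mean(mu_m^2) - mu*^2.
    """
    if not states:
        raise ValueError("need at least one SWAG state")
    if cfg.M % len(states) != 0:
        raise ValueError("M must be divisible by the number of states")
    per = cfg.M // len(states)
    head = states[0][1].head
    mus, vars_, probs = [], [], []
    for state, spec in states:
        for _ in range(per):
            theta = swag_sample(state, cfg, rng)
            pred = forward(unflatten(theta, spec), spec, incs)
            if head == "regression":
                mus.append(pred.mu)
                vars_.append(pred.sigma ** 2)
            else:
                probs.append(pred.probs)
    if head == "regression":
        mu_star, var_star = mixture_moments(np.stack(mus), np.stack(vars_))
        sigma_star = np.sqrt(np.maximum(var_star, SIGMA_FLOOR ** 2))
        return RegressionPrediction(mu_star, sigma_star)
    return ClassificationPrediction(np.stack(probs).mean(axis=0))


# -------------------------------------------------------------- persistence

def state_arrays(state: SwagState) -> dict[str, np.ndarray]:
    """Arrays for embedding a state in a checkpoint file."""
    return {"swag_theta_bar": state.theta_bar,
            "swag_theta_sq_bar": state.theta_sq_bar,
            "swag_dev": state.dev_matrix,
            "swag_n": np.array([state.n_collected])}


def state_from_arrays(arrays: dict[str, np.ndarray]) -> SwagState:
    dev = arrays["swag_dev"]
    return SwagState(theta_bar=arrays["swag_theta_bar"].copy(),
                     theta_sq_bar=arrays["swag_theta_sq_bar"].copy(),
                     dev_columns=[dev[:, j].copy() for j in range(dev.shape[1])],
                     n_collected=int(arrays["swag_n"][0]))
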