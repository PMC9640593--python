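"""Generators for labelled 1-D anomalous-diffusion trajectories.

Five stochastic processes are supported, all producing an ensemble mean
squared displacement (MSD) of the form <x^2(t)> ~ 2 K_alpha t^alpha:

* CTRW — continuous-time random walk: Gaussian jumps separated by
  heavy-tailed waiting times Psi(tau) ~ tau^(-1-alpha), 0 < alpha <= 1.
* FBM — fractional Brownian motion: Gaussian process whose increments are
  fractional Gaussian noise with Hurst exponent H = alpha/2, 0 < alpha < 2.
* LW — Levy walk: constant-speed flights of heavy-tailed duration; the
  flight-time exponent sigma maps to alpha = 3 - sigma (superdiffusion) or
  alpha = 2 for 0 < sigma < 1 (ballistic band).
* SBM — scaled Brownian motion: Brownian motion with deterministic
  time-dependent diffusivity K(t) = alpha K_alpha t^(alpha-1).
* ATTM — annealed transient time motion: Brownian epochs with random
  diffusivity D ~ D^(sigma-1) held for a deterministic time tau = D^(-gamma),
  giving alpha = sigma/gamma <= 1.

Trajectories are sampled at integer times 0..T-1 starting at the origin and
can be corrupted with additive white Gaussian localisation noise whose
standard deviation is sigma_dx / snr, with sigma_dx the empirical standard
deviation of the clean increment process of that same trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "MODELS",
    "SimParams",
    "PriorSpec",
    "Trajectory",
    "LabeledDataset",
    "sample_ctrw",
    "sample_fbm",
    "sample_lw",
    "sample_sbm",
    "sample_attm",
    "sample_model",
    "add_noise",
    "truncate",
    "admissible_models",
    "admissible_alphas",
    "generate_dataset",
    "ensemble_msd",
    "msd_loglog_slope",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_SNR_SET",
]

#: canonical model ordering, used for probability vectors and confusion matrices
MODELS: tuple[str, ...] = ("ATTM", "CTRW", "FBM", "LW", "SBM")

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 41) * 0.05, 2))
DEFAULT_SNR_SET: tuple[float, ...] = (1.0, 2.0, 10.0)


@dataclass(frozen=True)
class SimParams:
    """Scale parameters of the generators.

    All amplitudes are destroyed downstream by the per-trajectory unit-std
    normalisation of the increments, so the defaults of 1 are inconsequential
    for inference; they only set the absolute units of raw trajectories.
    """

    K_alpha: float = 1.0      # generalised diffusion coefficient
    v_lw: float = 1.0         # Levy-walk speed
    tau_min: float = 1.0      # waiting-time scale (Pareto lower cutoff)
    D_max: float = 1.0        # ATTM diffusivity upper support
    dimension: int = 1

    def __post_init__(self) -> None:
        if min(self.K_alpha, self.v_lw, self.tau_min, self.D_max) <= 0:
            raise ValueError("all scale parameters must be positive")
        if self.dimension != 1:
            raise NotImplementedError("only 1-D trajectories are supported")


@dataclass(frozen=True)
class PriorSpec:
    """Task-dependent prior over (model, alpha, snr).

    For regression the exponent is uniform on the alpha grid and the model
    uniform over those admissible at that exponent; for classification the
    model is uniform over the five classes and the exponent uniform over the
    model's admissible grid. In both cases snr is uniform over ``snr_set``.
    """

    task: str = "regression"
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    snr_set: tuple[float, ...] = DEFAULT_SNR_SET
    models: tuple[str, ...] = MODELS   # restrict for single-model studies

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.models or any(m not in MODELS for m in self.models):
            raise ValueError("models must be a non-empty subset of the five")


@dataclass
class Trajectory:
    positions: np.ndarray        # noisy positions (equals clean if snr = inf)
    clean_positions: np.ndarray  # pre-noise positions
    model: str
    alpha: float
    snr: float
    seed: int = -1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.clean_positions = np.asarray(self.clean_positions, dtype=float)
        if self.positions.shape != self.clean_positions.shape:
            raise ValueError("positions and clean_positions must share shape")
        if len(self.positions) < 2:
            raise ValueError("trajectory length must be >= 2")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class LabeledDataset:
    trajectories: list[Trajectory]
    task: str
    prior: PriorSpec
    master_seed: int = 0
    length: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.trajectories}
        if len(lengths) > 1:
            raise ValueError("all trajectories in a dataset must share length")
        self.length = lengths.pop() if lengths else 0

    def __len__(self) -> int:
        return len(self.trajectories)


def _check_alpha(alpha: float, lo: float, hi: float, model: str,
                 lo_open: bool = True, hi_open: bool = False) -> None:
    ok = (alpha > lo if lo_open else alpha >= lo) and (alpha < hi if hi_open else alpha <= hi)
    if not ok:
        lo_b = "(" if lo_open else "["
        hi_b = ")" if hi_open else "]"
        raise ValueError(f"{model} requires alpha in {lo_b}{lo}, {hi}{hi_b}, got {alpha}")


def _pareto_waits(exponent: float, n: int, tau_min: float, rng: np.random.Generator,
                  cap: float = np.inf) -> np.ndarray:
    """Inverse-CDF sampling of Psi(tau) ~ tau^(-1-exponent) on [tau_min, inf).

    Waits are capped at ``cap`` (callers pass a value beyond the observation
    window, where the truncation is statistically invisible); this also
    guards the power against float overflow at very small tail exponents.
    """
    u = rng.random(n)
    with np.errstate(over="ignore"):
        w = tau_min * u ** (-1.0 / exponent)
    return np.minimum(w, cap)


def sample_ctrw(alpha: float, T_traj: int, params: SimParams = SimParams(),
                rng: np.random.Generator | None = None, *, seed: int = -1) -> Trajectory:
    """Continuous-time random walk with Psi(tau) ~ tau^(-1-alpha), 0 < alpha <= 1."""
    _check_alpha(alpha, 0.0, 1.0, "CTRW")
    rng = np.random.default_rng() if rng is None else rng
    # waits >= tau_min = 1 in units of the sampling step, so at most T jumps
    # fall inside the window; T draws always suffice.
    n_max = int(np.ceil(T_traj / params.tau_min)) + 1
    waits = _pareto_waits(alpha, n_max, params.tau_min, rng, cap=T_traj + 2.0)
    jump_times = np.cumsum(waits)
    disp = rng.standard_normal(n_max) * np.sqrt(2.0 * params.K_alpha)
    walk = np.concatenate(([0.0], np.cumsum(disp)))
    times = np.arange(T_traj)
    x = walk[np.searchsorted(jump_times, times, side="right")]
    return Trajectory(x, x.copy(), "CTRW", alpha, np.inf, seed)


@lru_cache(maxsize=256)
def _fgn_spectrum(alpha: float, n: int, K_alpha: float) -> np.ndarray | None:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Returns None when the embedding is not nonnegative definite, signalling
    the Cholesky fallback.
    """
    k = np.arange(n + 1, dtype=float)
    cov = K_alpha * ((k + 1) ** alpha - 2 * k ** alpha + np.abs(k - 1) ** alpha)
    circ = np.concatenate([cov, cov[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-9 * lam.max():
        return None
    return np.clip(lam, 0.0, None)


@lru_cache(maxsize=64)
def _fgn_cholesky(alpha: float, n: int, K_alpha: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    cov = K_alpha * ((k + 1) ** alpha - 2 * k ** alpha + np.abs(k - 1) ** alpha)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return np.linalg.cholesky(cov[idx])


def _fgn(alpha: float, n: int, K_alpha: float, rng: np.random.Generator,
         size: int = 1) -> np.ndarray:
    """Exact fractional Gaussian noise, shape (size, n), Hurst H = alpha/2.

    Davies-Harte circulant embedding; exact-covariance Cholesky fallback when
    the embedding fails (rare at these exponents and lengths).
    """
    lam = _fgn_spectrum(float(alpha), int(n), float(K_alpha))
    if lam is None:
        L = _fgn_cholesky(float(alpha), int(n), float(K_alpha))
        return (L @ rng.standard_normal((n, size))).T
    m = lam.size  # m = 2n
    # Hermitian-symmetric complex normal vector w with E|w_j|^2 = 1
    w = np.empty((size, m), dtype=complex)
    half = m // 2
    w[:, 0] = rng.standard_normal(size)
    w[:, half] = rng.standard_normal(size)
    re = rng.standard_normal((size, half - 1)) / np.sqrt(2.0)
    im = rng.standard_normal((size, half - 1)) / np.sqrt(2.0)
    w[:, 1:half] = re + 1j * im
    w[:, half + 1:] = (re - 1j * im)[:, ::-1]
    y = np.fft.fft(w * np.sqrt(lam / m), axis=1)
    return y[:, :n].real


def sample_fbm(alpha: float, T_traj: int, params: SimParams = SimParams(),
               rng: np.random.Generator | None = None, *, seed: int = -1) -> Trajectory:
    """Fractional Brownian motion, 0 < alpha < 2 (alpha = 2 excluded)."""
    _check_alpha(alpha, 0.0, 2.0, "FBM", hi_open=True)
    rng = np.random.default_rng() if rng is None else rng
    incs = _fgn(alpha, T_traj - 1, params.K_alpha, rng)[0]
    x = np.concatenate(([0.0], np.cumsum(incs)))
    return Trajectory(x, x.copy(), "FBM", alpha, np.inf, seed)


def sample_lw(alpha: float, T_traj: int, params: SimParams = SimParams(),
              rng: np.random.Generator | None = None, *, seed: int = -1) -> Trajectory:
    """Levy walk, 1 < alpha <= 2; alpha = 2 draws sigma ~ U(0,1) (ballistic band)."""
    _check_alpha(alpha, 1.0, 2.0, "LW")
    rng = np.random.default_rng() if rng is None else rng
    sigma = rng.uniform(0.0, 1.0) if alpha == 2.0 else 3.0 - alpha
    n_max = int(np.ceil(T_traj / params.tau_min)) + 1
    waits = _pareto_waits(sigma, n_max, params.tau_min, rng, cap=T_traj + 2.0)
    dirs = rng.choice((-1.0, 1.0), size=n_max)
    node_t = np.concatenate(([0.0], np.cumsum(waits)))
    node_x = np.concatenate(([0.0], np.cumsum(dirs * params.v_lw * waits)))
    x = np.interp(np.arange(T_traj, dtype=float), node_t, node_x)
    return Trajectory(x, x.copy(), "LW", alpha, np.inf, seed)


def sample_sbm(alpha: float, T_traj: int, params: SimParams = SimParams(),
               rng: np.random.Generator | None = None, *, seed: int = -1) -> Trajectory:
    """Scaled Brownian motion, 0 < alpha <= 2.

    The increment over [t, t+1] integrates K(t) = alpha K_alpha t^(alpha-1)
    exactly: Var = 2 K_alpha ((t+1)^alpha - t^alpha).
    """
    _check_alpha(alpha, 0.0, 2.0, "SBM")
    rng = np.random.default_rng() if rng is None else rng
    t = np.arange(T_traj - 1, dtype=float)
    var = 2.0 * params.K_alpha * ((t + 1) ** alpha - t ** alpha)
    incs = rng.standard_normal(T_traj - 1) * np.sqrt(var)
    x = np.concatenate(([0.0], np.cumsum(incs)))
    return Trajectory(x, x.copy(), "SBM", alpha, np.inf, seed)


def _attm_gamma(alpha: float, rng: np.random.Generator) -> float:
    # the regime sigma < gamma < sigma + 1 with sigma = alpha*gamma translates
    # to gamma < 1/(1-alpha); capped at 3 to avoid extreme exponents
    if alpha >= 1.0:
        return 1.0
    hi = min(3.0, 1.0 / (1.0 - alpha))
    return rng.uniform(1.0, hi)


def sample_attm(alpha: float, T_traj: int, params: SimParams = SimParams(),
                rng: np.random.Generator | None = None, *, seed: int = -1) -> Trajectory:
    """Annealed transient time motion, 0 < alpha <= 1.

    Brownian epochs with diffusivity D ~ P(D) ~ D^(sigma-1) on (0, D_max],
    each held for tau = D^(-gamma); alpha = sigma/gamma.
    """
    _check_alpha(alpha, 0.0, 1.0, "ATTM")
    rng = np.random.default_rng() if rng is None else rng
    gamma = _attm_gamma(alpha, rng)
    sigma = alpha * gamma
    # D <= D_max <= 1 and gamma >= 1 give tau = D^(-gamma) >= 1, so at most
    # T epochs cover the window
    n_max = T_traj + 1
    D = params.D_max * rng.random(n_max) ** (1.0 / sigma)
    with np.errstate(divide="ignore", over="ignore"):
        tau = np.minimum(D ** (-gamma), T_traj + 2.0)
    node_t = np.concatenate(([0.0], np.cumsum(tau)))
    # integrated diffusivity I(t) = int_0^t 2 D(s) ds, piecewise linear
    node_I = np.concatenate(([0.0], np.cumsum(2.0 * D * tau)))
    I = np.interp(np.arange(T_traj, dtype=float), node_t, node_I)
    incs = rng.standard_normal(T_traj - 1) * np.sqrt(np.diff(I))
    x = np.concatenate(([0.0], np.cumsum(incs)))
    return Trajectory(x, x.copy(), "ATTM", alpha, np.inf, seed)


_SAMPLERS = {
    "ATTM": sample_attm,
    "CTRW": sample_ctrw,
    "FBM": sample_fbm,
    "LW": sample_lw,
    "SBM": sample_sbm,
}


def sample_model(model: str, alpha: float, T_traj: int,
                 params: SimParams = SimParams(),
                 rng: np.random.Generator | None = None, *, seed: int = -1) -> Trajectory:
    """Dispatch to the named model's sampler."""
    try:
        fn = _SAMPLERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None
    return fn(alpha, T_traj, params, rng, seed=seed)


def add_noise(traj: Trajectory, snr: float, rng: np.random.Generator | None = None) -> Trajectory:
    """Corrupt a clean trajectory with white Gaussian localisation noise.

    The noise standard deviation is sigma_dx / snr where sigma_dx is the
    empirical (population) standard deviation of this trajectory's clean
    increments; snr = inf returns the clean trajectory unchanged.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = traj.clean_positions
    if np.isinf(snr):
        return Trajectory(clean.copy(), clean.copy(), traj.model, traj.alpha, snr, traj.seed)
    rng = np.random.default_rng() if rng is None else rng
    sigma_dx = float(np.std(np.diff(clean)))
    if sigma_dx == 0.0:
        warnings.warn("constant clean trajectory: no noise added", RuntimeWarning)
        return Trajectory(clean.copy(), clean.copy(), traj.model, traj.alpha, snr, traj.seed)
    noisy = clean + rng.standard_normal(len(clean)) * (sigma_dx / snr)
    return Trajectory(noisy, clean.copy(), traj.model, traj.alpha, snr, traj.seed)


def truncate(traj: Trajectory, T: int) -> Trajectory:
    """Keep the first T points (noise should be added AFTER truncation)."""
    if T < 2 or T > len(traj):
        raise ValueError("invalid truncation length")
    return Trajectory(traj.positions[:T].copy(), traj.clean_positions[:T].copy(),
                      traj.model, traj.alpha, traj.snr, traj.seed)


def admissible_models(alpha: float) -> tuple[str, ...]:
    """Models defined at a given exponent (canonical order)."""
    out = []
    for m in MODELS:
        if m in ("ATTM", "CTRW") and alpha > 1.0:
            continue
        if m == "LW" and alpha <= 1.0:
            continue
        if m == "FBM" and alpha >= 2.0:
            continue
        out.append(m)
    return tuple(out)


def admissible_alphas(model: str, grid: Sequence[float] = DEFAULT_ALPHA_GRID) -> tuple[float, ...]:
    return tuple(a for a in grid if model in admissible_models(a))


def _exact_counts(n: int, k: int) -> np.ndarray:
    """Split n into k counts differing by at most one (first bins get extras)."""
    base, rem = divmod(n, k)
    counts = np.full(k, base, dtype=int)
    counts[:rem] += 1
    return counts


def generate_dataset(task: str, n: int, T_traj: int,
                     prior: PriorSpec | None = None,
                     params: SimParams = SimParams(),
                     master_seed: int = 0) -> LabeledDataset:
    """Assemble a labelled dataset under the task prior.

    Regression stratifies exponent counts exactly over the alpha grid with the
    model uniform over those admissible at each exponent; classification
    stratifies model counts exactly with the exponent uniform over the model's
    admissible grid. snr is uniform over the prior's snr set; noise is added
    after generation at the target length. Fully reproducible from
    ``master_seed`` via per-trajectory seed-sequence substreams.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prior = PriorSpec(task=task) if prior is None else prior
    if prior.task != task:
        raise ValueError("prior.task does not match task")
    root = np.random.SeedSequence(master_seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    labels: list[tuple[str, float]] = []
    if task == "classification":
        for model, cnt in zip(prior.models, _exact_counts(n, len(prior.models))):
            grid = admissible_alphas(model, prior.alpha_grid)
            if not grid:
                raise RuntimeError(f"empty admissible alpha set for {model}")
            alphas = assign_rng.choice(grid, size=cnt)
            labels.extend((model, float(a)) for a in alphas)
    else:
        grid = [a for a in prior.alpha_grid
                if any(m in prior.models for m in admissible_models(a))]
        if not grid:
            raise RuntimeError("empty admissible exponent grid")
        for alpha, cnt in zip(grid, _exact_counts(n, len(grid))):
            models = [m for m in admissible_models(alpha) if m in prior.models]
            picks = assign_rng.choice(models, size=cnt)
            labels.extend((str(m), float(alpha)) for m in picks)
    snrs = assign_rng.choice(prior.snr_set, size=n)
    order = assign_rng.permutation(n)

    children = root.spawn(n + 1)[1:]
    trajectories = []
    for new_idx, old_idx in enumerate(order):
        model, alpha = labels[old_idx]
        ss = children[new_idx]
        rng = np.random.default_rng(ss)
        seed = int(ss.generate_state(1)[0] % (2 ** 31))
        clean = sample_model(model, alpha, T_traj, params, rng, seed=seed)
        trajectories.append(add_noise(clean, float(snrs[old_idx]), rng))
    return LabeledDataset(trajectories, task, prior, master_seed)


def _renewal_times(total: float, exponent: float, tau_min: float,
                   rng: np.random.Generator, guess: int) -> np.ndarray:
    """Cumulative Pareto event times covering [0, total] (last entry > total)."""
    waits = _pareto_waits(exponent, guess, tau_min, rng, cap=total + 2.0)
    s = np.cumsum(waits)
    while s[-1] <= total:
        extra = _pareto_waits(exponent, max(64, guess // 2), tau_min, rng, cap=total + 2.0)
        s = np.concatenate([s, s[-1] + np.cumsum(extra)])
    return s


def _event_count_guess(total: float, exponent: float, tau_min: float) -> int:
    t = total / tau_min
    if exponent >= 1.0:
        est = t / max(np.log(t), 1.0)
    else:
        est = t ** exponent
    return max(64, int(3 * est))


def ensemble_positions(model: str, alpha: float, n: int,
                       times: np.ndarray | None = None, T_traj: int | None = None,
                       params: SimParams = SimParams(),
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Clean positions of n independent trajectories at the given sample times.

    Built for ensemble-MSD validation at large horizons: jump processes
    (CTRW, ATTM, LW) generate only their events and evaluate positions at
    the requested times, so log-spaced grids over 10^5 time units stay cheap.
    FBM requires the full unit grid (times = 0..T-1).
    """
    rng = np.random.default_rng() if rng is None else rng
    if times is None:
        if T_traj is None:
            raise ValueError("give either times or T_traj")
        times = np.arange(T_traj, dtype=float)
    times = np.asarray(times, dtype=float)
    total = float(times[-1])
    k = len(times)
    out = np.empty((n, k))

    if model == "FBM":
        _check_alpha(alpha, 0.0, 2.0, "FBM", hi_open=True)
        if not np.array_equal(times, np.arange(k)):
            raise ValueError("FBM ensemble sampling needs the unit time grid")
        incs = _fgn(alpha, k - 1, params.K_alpha, rng, size=n)
        out[:, 0] = 0.0
        out[:, 1:] = np.cumsum(incs, axis=1)
        return out
    if model == "SBM":
        _check_alpha(alpha, 0.0, 2.0, "SBM")
        var = 2.0 * params.K_alpha * np.diff(times ** alpha)
        incs = rng.standard_normal((n, k - 1)) * np.sqrt(var)
        out[:, 0] = 0.0 if times[0] == 0 else np.nan
        out[:, 1:] = np.cumsum(incs, axis=1)
        out[:, 0] = rng.standard_normal(n) * np.sqrt(2 * params.K_alpha * times[0] ** alpha)
        out[:, 1:] += out[:, :1]
        return out

    if model == "CTRW":
        _check_alpha(alpha, 0.0, 1.0, "CTRW")
        guess = _event_count_guess(total, alpha, params.tau_min)
        scale = np.sqrt(2.0 * params.K_alpha)
        for r in range(n):
            jumps = _renewal_times(total, alpha, params.tau_min, rng, guess)
            counts = np.searchsorted(jumps, times, side="right")
            steps = rng.standard_normal(k - 1) * scale * np.sqrt(np.diff(counts))
            x0 = rng.standard_normal() * scale * np.sqrt(counts[0]) if counts[0] else 0.0
            out[r, 0] = x0
            out[r, 1:] = x0 + np.cumsum(steps)
        return out
    if model == "LW":
        _check_alpha(alpha, 1.0, 2.0, "LW")
        for r in range(n):
            sig = rng.uniform(0.0, 1.0) if alpha == 2.0 else 3.0 - alpha
            guess = _event_count_guess(total, sig, params.tau_min)
            node_t = _renewal_times(total, sig, params.tau_min, rng, guess)
            waits = np.diff(np.concatenate(([0.0], node_t)))
            dirs = rng.choice((-1.0, 1.0), size=len(waits))
            node_x = np.cumsum(dirs * params.v_lw * waits)
            out[r] = np.interp(times, np.concatenate(([0.0], node_t)),
                               np.concatenate(([0.0], node_x)))
        return out
    if model == "ATTM":
        _check_alpha(alpha, 0.0, 1.0, "ATTM")
        for r in range(n):
            gamma = _attm_gamma(alpha, rng)
            sigma = alpha * gamma
            # tau >= 1, so the event count is bounded by the marginal case
            guess = _event_count_guess(total, min(alpha, 1.0), 1.0)
            node_t = [0.0]
            node_I = [0.0]
            while node_t[-1] <= total:
                m = guess
                D = params.D_max * rng.random(m) ** (1.0 / sigma)
                with np.errstate(divide="ignore", over="ignore"):
                    tau = np.minimum(D ** (-gamma), total + 2.0)
                node_t.extend(node_t[-1] + np.cumsum(tau))
                node_I.extend(node_I[-1] + np.cumsum(2.0 * D * tau))
            I = np.interp(times, np.asarray(node_t), np.asarray(node_I))
            steps = rng.standard_normal(k - 1) * np.sqrt(np.diff(I))
            x0 = rng.standard_normal() * np.sqrt(I[0]) if I[0] > 0 else 0.0
            out[r, 0] = x0
            out[r, 1:] = x0 + np.cumsum(steps)
        return out
    raise ValueError(f"unknown model {model!r}")


def msd_scaling_slope(model: str, alpha: float, n: int = 10_000,
                      params: SimParams = SimParams(),
                      rng: np.random.Generator | None = None) -> float:
    """Fitted ensemble-MSD power-law exponent for a clean-trajectory ensemble.

    The fit window is chosen inside each model's scaling regime: FBM and SBM
    obey <x^2(t)> = 2 K_alpha t^alpha exactly, so the unit grid up to T = 100
    suffices; LW uses T = 1000. The renewal processes (CTRW, ATTM) approach
    their power law slowly when the minimum waiting time equals the sampling
    step, so their MSD is evaluated on a log-spaced grid out to t = 10^5 and
    fitted over the last two decades.
    """
    rng = np.random.default_rng() if rng is None else rng
    if model in ("FBM", "SBM"):
        times = np.arange(100, dtype=float)
        fit_from = 1.0
    elif model == "LW":
        times = np.arange(1000, dtype=float)
        fit_from = 1.0
    else:
        times = np.unique(np.round(np.logspace(0, 5, 60)))
        times = np.concatenate(([0.0], times))
        fit_from = 1e3
    pos = ensemble_positions(model, alpha, n, times=times, params=params, rng=rng)
    msd = np.mean((pos - pos[:, :1]) ** 2, axis=0)
    fit_to = times[-1] / 2 if model in ("FBM", "SBM", "LW") else times[-1]
    sel = (times >= fit_from) & (times <= fit_to) & (msd > 0)
    t_fit, m_fit = times[sel], msd[sel]
    return float(np.polyfit(np.log(t_fit), np.log(m_fit), 1)[0])


def ensemble_msd(positions: np.ndarray) -> np.ndarray:
    """Ensemble-averaged MSD <(x(t) - x(0))^2> from an (n, T) position array."""
    positions = np.asarray(positions, dtype=float)
    disp = positions - positions[:, :1]
    return np.mean(disp ** 2, axis=0)


def msd_loglog_slope(msd: np.ndarray, lags: np.ndarray | None = None) -> float:
    """Least-squares slope of log MSD vs log t over the given lags.

    Defaults to lags 1..T/2; lags with non-positive MSD (possible at lag 1
    for jump processes whose minimum waiting time equals the sampling step)
    are excluded from the fit.
    """
    msd = np.asarray(msd, dtype=float)
    if lags is None:
        lags = np.arange(1, max(2, len(msd) // 2))
    lags = np.asarray(lags)
    keep = msd[lags] > 0
    lags = lags[keep]
    if len(lags) < 2:
        raise ValueError("fewer than two lags with positive MSD")
    return float(np.polyfit(np.log(lags), np.log(msd[lags]), 1)[0])
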