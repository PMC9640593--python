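"""Dataset and prediction I/O plus deterministic test fixtures.

A dataset on disk is a directory holding three files:

* ``trajectories.csv`` — long format: traj_id, t, x_noisy, x_clean
* ``metadata.csv``     — per trajectory: traj_id, model, alpha, snr, seed
* ``dataset.json``     — task, prior and master seed

Floats are serialised with round-trip (17 significant digit) precision so a
CSV round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulators import (DEFAULT_ALPHA_GRID, DEFAULT_SNR_SET, LabeledDataset,
                         PriorSpec, SimParams, Trajectory, admissible_alphas,
                         MODELS, sample_model, add_noise)

_TRAJ_COLS = ["traj_id", "t", "x_noisy", "x_clean"]
_META_COLS = ["traj_id", "model", "alpha", "snr", "seed"]


def save_dataset(ds: LabeledDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_t = ds.length
    ids = np.repeat(np.arange(len(ds)), n_t)
    t = np.tile(np.arange(n_t), len(ds))
    noisy = np.concatenate([tr.positions for tr in ds.trajectories])
    clean = np.concatenate([tr.clean_positions for tr in ds.trajectories])
    traj = pd.DataFrame({"traj_id": ids, "t": t, "x_noisy": noisy, "x_clean": clean})
    traj.to_csv(path / "trajectories.csv", index=False, float_format="%.17g")
    meta = pd.DataFrame({
        "traj_id": np.arange(len(ds)),
        "model": [tr.model for tr in ds.trajectories],
        "alpha": [tr.alpha for tr in ds.trajectories],
        "snr": [tr.snr for tr in ds.trajectories],
        "seed": [tr.seed for tr in ds.trajectories],
    })
    meta.to_csv(path / "metadata.csv", index=False, float_format="%.17g")
    info = {"task": ds.task, "master_seed": ds.master_seed,
            "alpha_grid": list(ds.prior.alpha_grid),
            "snr_set": list(ds.prior.snr_set)}
    (path / "dataset.json").write_text(json.dumps(info, indent=1))


def load_dataset(path) -> LabeledDataset:
    path = Path(path)
    try:
        traj = pd.read_csv(path / "trajectories.csv", float_precision="round_trip")
        meta = pd.read_csv(path / "metadata.csv", float_precision="round_trip")
        info = json.loads((path / "dataset.json").read_text())
    except FileNotFoundError as e:
        raise FileNotFoundError(f"incomplete dataset directory {path}: {e}") from e
    for cols, df, name in ((_TRAJ_COLS, traj, "trajectories.csv"),
                           (_META_COLS, meta, "metadata.csv")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} missing columns {sorted(missing)}")
    prior = PriorSpec(task=info["task"],
                      alpha_grid=tuple(info["alpha_grid"]),
                      snr_set=tuple(info["snr_set"]))
    trajectories = []
    grouped = traj.sort_values(["traj_id", "t"]).groupby("traj_id", sort=True)
    meta = meta.set_index("traj_id")
    lengths = grouped.size()
    if lengths.nunique() > 1:
        raise ValueError("trajectories.csv holds unequal trajectory lengths")
    for tid, g in grouped:
        if tid not in meta.index:
            raise ValueError(f"traj_id {tid} missing from metadata.csv")
        row = meta.loc[tid]
        trajectories.append(Trajectory(
            positions=g["x_noisy"].to_numpy(),
            clean_positions=g["x_clean"].to_numpy(),
            model=str(row["model"]), alpha=float(row["alpha"]),
            snr=float(row["snr"]), seed=int(row["seed"])))
    return LabeledDataset(trajectories, info["task"], prior, int(info["master_seed"]))


def save_regression_predictions(path, mu: np.ndarray, sigma: np.ndarray) -> None:
    pd.DataFrame({"traj_id": np.arange(len(mu)), "mu": mu, "sigma": sigma}) \
        .to_csv(path, index=False, float_format="%.17g")


def save_classification_predictions(path, probs: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(probs), columns=[f"p_{m}" for m in MODELS])
    df.insert(0, "traj_id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.17g")


def load_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "traj_id" not in df.columns:
        raise ValueError("predictions file missing traj_id column")
    return df


def make_fixtures(seed: int = 0, lengths: tuple[int, ...] = (10, 50),
                  n_each: int = 20) -> dict[tuple[str, float, int], LabeledDataset]:
    """Deterministic miniature datasets for tests.

    For every model, three admissible exponents (low / middle / high of the
    model's admissible grid) and each requested length, ``n_each``
    noise-corrupted trajectories are generated. Keyed by (model, alpha, T).
    """
    root = np.random.SeedSequence(seed)
    out: dict[tuple[str, float, int], LabeledDataset] = {}
    params = SimParams()
    for model in MODELS:
        grid = admissible_alphas(model)
        alphas = (grid[0], grid[len(grid) // 2], grid[-1])
        for alpha in alphas:
            for T in lengths:
                ss = np.random.SeedSequence(
                    entropy=root.entropy,
                    spawn_key=(MODELS.index(model), int(round(alpha * 100)), T))
                rng = np.random.default_rng(ss)
                trajs = []
                for i in range(n_each):
                    snr = float(rng.choice(DEFAULT_SNR_SET))
                    clean = sample_model(model, alpha, T, params, rng, seed=i)
                    trajs.append(add_noise(clean, snr, rng))
                task = "regression"
                out[(model, alpha, T)] = LabeledDataset(
                    trajs, task, PriorSpec(task=task), master_seed=seed)
    return out
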