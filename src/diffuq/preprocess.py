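"""Position series -> normalised increment series fed to the network.

The pipeline order matters and is truncate -> add noise -> increments ->
normalise: the signal-to-noise ratio is defined with respect to the increment
statistics of the trajectory at its final length, so noise is added only
after any truncation.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-10


def to_increments(positions: np.ndarray) -> np.ndarray:
    """First differences Delta x_t = x_{t+1} - x_t (length T-1)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or len(positions) < 2:
        raise ValueError("need a 1-D position series of length >= 2")
    return np.diff(positions)


def normalize(incs: np.ndarray) -> np.ndarray:
    """Scale a per-trajectory increment series to unit (population) std.

    The mean is not subtracted. Degenerate all-equal series are left at
    whatever ``x / max(std, EPS)`` gives (all zeros for an all-zero input),
    never NaN.
    """
    incs = np.asarray(incs, dtype=float)
    return incs / max(float(np.std(incs)), EPS)


def pipeline(positions: np.ndarray) -> np.ndarray:
    """Increments then unit-std normalisation."""
    return normalize(to_increments(positions))


def batch_pipeline(position_rows: np.ndarray) -> np.ndarray:
    """Vectorised pipeline over an (n, T) array -> (n, T-1) network input."""
    rows = np.asarray(position_rows, dtype=float)
    incs = np.diff(rows, axis=1)
    std = np.maximum(np.std(incs, axis=1, keepdims=True), EPS)
    return incs / std
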