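"""Performance and calibration diagnostics.

Regression: mean absolute error, reliability diagram built by binning the
predicted standard deviation in fixed-width bins (default 0.02) and
comparing the root mean (predicted) variance (RMV) against the observed root
mean squared error (RMSE) in each bin; ENCE averages the relative deviation
|RMV - RMSE| / RMV over non-empty bins, ECE the absolute deviation.

Classification: accuracy, confidence-binned expected calibration error
(count-weighted, 10 equal-width bins) for the rank-k class, column-normalised
confusion matrices, and mean predicted confidences stratified by ground-truth
model and exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulators import MODELS

__all__ = [
    "RegressionEvalRecord", "CalibrationBin", "CalibrationReport",
    "mae", "accuracy", "reliability_regression", "ence", "ece_regression",
    "ece_classification", "confusion_matrix", "mean_confidence_table",
    "predicted_error_histogram", "regression_report", "classification_report",
]


@dataclass
class RegressionEvalRecord:
    mu: float
    sigma: float
    alpha_true: float
    model_true: str = ""
    snr: float = np.inf
    T_traj: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class CalibrationBin:
    lower: float
    upper: float
    rmv: float     # root mean predicted variance in the bin
    rmse: float    # root mean squared residual in the bin
    count: int


@dataclass
class CalibrationReport:
    bins: list[CalibrationBin] = field(default_factory=list)
    mae: float | None = None
    accuracy: float | None = None
    ence: float | None = None
    ece: float | None = None
    confusion: np.ndarray | None = None
    mean_confidence: pd.DataFrame | None = None


def _records_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = np.array([r.mu for r in records], dtype=float)
    sigma = np.array([r.sigma for r in records], dtype=float)
    alpha = np.array([r.alpha_true for r in records], dtype=float)
    return mu, sigma, alpha


def mae(records) -> float:
    """Mean absolute error of the predicted exponent."""
    if len(records) == 0:
        raise ValueError("no records")
    mu, _, alpha = _records_arrays(records)
    return float(np.mean(np.abs(mu - alpha)))


def accuracy(probs: np.ndarray, true_idx: np.ndarray) -> float:
    probs = np.asarray(probs, dtype=float)
    pred = _rank_class(probs, 1)
    return float(np.mean(pred == np.asarray(true_idx, dtype=int)))


def reliability_regression(records, bin_width: float = 0.02) -> list[CalibrationBin]:
    """Reliability-diagram bins over predicted std, fixed width from zero.

    Each non-empty bin carries RMV = sqrt(mean sigma^2) and
    RMSE = sqrt(mean (mu - alpha)^2); empty bins are dropped.
    """
    mu, sigma, alpha = _records_arrays(records)
    if len(mu) == 0:
        return []
    idx = np.floor(sigma / bin_width).astype(int)
    bins = []
    for b in np.unique(idx):
        sel = idx == b
        rmv = float(np.sqrt(np.mean(sigma[sel] ** 2)))
        rmse = float(np.sqrt(np.mean((mu[sel] - alpha[sel]) ** 2)))
        bins.append(CalibrationBin(lower=b * bin_width, upper=(b + 1) * bin_width,
                                   rmv=rmv, rmse=rmse, count=int(sel.sum())))
    return bins


def ence(bins: list[CalibrationBin]) -> float:
    """Expected normalised calibration error: mean |RMV - RMSE| / RMV.

    Unweighted over non-empty bins; bins with RMV = 0 are excluded.
    """
    vals = [abs(b.rmv - b.rmse) / b.rmv for b in bins if b.count > 0 and b.rmv > 0]
    if not vals:
        raise ValueError("no usable bins")
    return float(np.mean(vals))


def ece_regression(bins: list[CalibrationBin]) -> float:
    """Expected calibration error: mean |RMV - RMSE|, unweighted over bins."""
    vals = [abs(b.rmv - b.rmse) for b in bins if b.count > 0]
    if not vals:
        raise ValueError("no usable bins")
    return float(np.mean(vals))


def _rank_class(probs: np.ndarray, rank: int) -> np.ndarray:
    """Class index receiving the rank-th highest probability per row.

    Ties are broken toward the lower class index.
    """
    # stable sort on -p: equal probabilities keep ascending index order
    order = np.argsort(-probs, axis=1, kind="stable")
    return order[:, rank - 1]


def ece_classification(probs: np.ndarray, true_idx: np.ndarray,
                       n_bins: int = 10, rank: int = 1) -> float:
    """Count-weighted expected calibration error of the rank-k prediction.

    Confidences of the rank-k class are binned into equal-width bins on
    [0, 1]; ECE = sum_b (n_b / n) |accuracy_b - mean confidence_b|, with
    accuracy_b the fraction of bin members whose rank-k class is the truth.
    """
    probs = np.asarray(probs, dtype=float)
    true_idx = np.asarray(true_idx, dtype=int)
    if not 1 <= rank <= probs.shape[1]:
        raise ValueError("rank out of range")
    cls = _rank_class(probs, rank)
    conf = probs[np.arange(len(cls)), cls]
    correct = (cls == true_idx).astype(float)
    bin_idx = np.minimum((conf * n_bins).astype(int), n_bins - 1)
    n = len(conf)
    total = 0.0
    for b in range(n_bins):
        sel = bin_idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        total += (nb / n) * abs(correct[sel].mean() - conf[sel].mean())
    return float(total)


def confusion_matrix(probs: np.ndarray, true_idx: np.ndarray) -> np.ndarray:
    """5x5 relative-frequency matrix: predicted model (row) given truth (column).

    Columns with at least one example sum to 1.
    """
    probs = np.asarray(probs, dtype=float)
    true_idx = np.asarray(true_idx, dtype=int)
    k = len(MODELS)
    pred = _rank_class(probs, 1)
    counts = np.zeros((k, k))
    np.add.at(counts, (pred, true_idx), 1.0)
    col = counts.sum(axis=0, keepdims=True)
    return counts / np.where(col == 0, 1.0, col)


def mean_confidence_table(probs: np.ndarray, true_models, true_alphas) -> pd.DataFrame:
    """Mean predicted probability vector per (ground-truth model, exponent)."""
    probs = np.asarray(probs, dtype=float)
    df = pd.DataFrame(probs, columns=list(MODELS))
    df["model_true"] = list(true_models)
    df["alpha_true"] = np.asarray(true_alphas, dtype=float)
    return df.groupby(["model_true", "alpha_true"], sort=True)[list(MODELS)].mean()


def predicted_error_histogram(values: np.ndarray, strata: dict[str, np.ndarray],
                              bin_width: float = 0.02) -> pd.DataFrame:
    """Histogram of predicted errors (sigma or top confidence) per stratum.

    ``strata`` maps column names (e.g. model, alpha, snr) to per-record
    labels; counts are reported per (stratum..., bin) combination.
    """
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(strata)
    df["bin_lower"] = np.floor(values / bin_width) * bin_width
    keys = list(strata.keys()) + ["bin_lower"]
    out = df.groupby(keys, sort=True).size().rename("count").reset_index()
    return out


def regression_report(records, bin_width: float = 0.02) -> CalibrationReport:
    bins = reliability_regression(records, bin_width)
    return CalibrationReport(bins=bins, mae=mae(records), ence=ence(bins),
                             ece=ece_regression(bins))


def classification_report(probs: np.ndarray, true_models,
                          true_alphas=None) -> CalibrationReport:
    probs = np.asarray(probs, dtype=float)
    true_idx = np.array([MODELS.index(m) for m in true_models])
    rep = CalibrationReport(accuracy=accuracy(probs, true_idx),
                            ece=ece_classification(probs, true_idx),
                            confusion=confusion_matrix(probs, true_idx))
    if true_alphas is not None:
        rep.mean_confidence = mean_confidence_table(probs, true_models, true_alphas)
    return rep
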