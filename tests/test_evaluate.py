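"""Calibration metrics: reliability diagrams, ENCE/ECE, confusion, confidences."""

import numpy as np
import pandas as pd
import pytest

from diffuq.evaluate import (CalibrationBin, RegressionEvalRecord, accuracy,
                             classification_report, confusion_matrix,
                             ece_classification, ece_regression, ence, mae,
                             mean_confidence_table, predicted_error_histogram,
                             regression_report, reliability_regression)
from diffuq.simulators import MODELS


def _recs(mu, sigma, alpha):
    return [RegressionEvalRecord(m, s, a) for m, s, a in zip(mu, sigma, alpha)]


def _calibrated_records(n, rng):
    """mu = alpha + sigma * z with z ~ N(0,1): calibrated by construction."""
    sigma = rng.uniform(0.02, 0.3, n)
    alpha = rng.uniform(0.05, 2.0, n)
    mu = alpha + sigma * rng.standard_normal(n)
    return _recs(mu, sigma, alpha)


def test_mae_hand_values_and_permutation_invariance():
    recs = _recs([0.6, 0.2], [0.1, 0.1], [0.5, 0.5])
    assert mae(recs) == pytest.approx(0.2)
    assert mae(recs[::-1]) == pytest.approx(0.2)
    assert mae(_recs([1.0], [0.1], [1.0])) == 0.0
    with pytest.raises(ValueError):
        mae([])


def test_reliability_point_mass_single_bin():
    recs = _recs([0.55] * 10, [0.05] * 10, [0.5] * 10)
    bins = reliability_regression(recs)
    assert len(bins) == 1
    b = bins[0]
    assert b.count == 10
    assert b.rmv == pytest.approx(0.05)
    assert b.rmse == pytest.approx(0.05)
    assert b.lower <= b.rmv <= b.upper


def test_reliability_bin_membership_exact():
    recs = _recs([0.5, 0.5], [0.01, 0.03], [0.5, 0.5])
    bins = reliability_regression(recs)
    assert [b.count for b in bins] == [1, 1]
    assert bins[0].lower == pytest.approx(0.0)
    assert bins[1].lower == pytest.approx(0.02)


def test_ence_ece_hand_example():
    b = [CalibrationBin(0.08, 0.10, rmv=0.10, rmse=0.12, count=5)]
    assert ence(b) == pytest.approx(0.20)
    assert ece_regression(b) == pytest.approx(0.02)
    perfect = [CalibrationBin(0.0, 0.02, 0.01, 0.01, 3)]
    assert ence(perfect) == 0.0 and ece_regression(perfect) == 0.0


def test_calibrated_generator_bins_and_ence(rng):
    recs = _calibrated_records(100_000, rng)
    bins = reliability_regression(recs)
    occupied = [b for b in bins if b.count >= 100]
    for b in occupied:
        assert abs(b.rmse - b.rmv) / b.rmv < 0.05
    assert ence(bins) < 0.03


def test_reliability_converges_at_root_n_rate(rng):
    small = ence(reliability_regression(_calibrated_records(2000, rng)))
    large = ence(reliability_regression(_calibrated_records(100_000, rng)))
    assert large < small


def test_ece_classification_hand_example():
    probs = np.array([
        [0.9, 0.1, 0.0, 0.0, 0.0],   # correct, confidence 0.9
        [0.7, 0.3, 0.0, 0.0, 0.0],   # wrong, confidence 0.7
    ])
    true_idx = np.array([0, 1])
    assert ece_classification(probs, true_idx, n_bins=1) == pytest.approx(0.3)
    one_hot = np.eye(5)
    assert ece_classification(one_hot, np.arange(5)) == 0.0
    with pytest.raises(ValueError):
        ece_classification(probs, true_idx, rank=6)


def test_rank_with_zero_probability_contributes_nothing():
    # rank-4 class has probability 0 and is never the truth: |0 - 0| = 0
    probs = np.tile(np.array([0.5, 0.3, 0.2, 0.0, 0.0]), (50, 1))
    true_idx = np.zeros(50, dtype=int)
    assert ece_classification(probs, true_idx, rank=4) == pytest.approx(0.0)


def test_ece_classification_calibrated_generator(rng):
    probs = rng.dirichlet(np.ones(5), size=100_000)
    u = rng.random(len(probs))
    true_idx = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    for rank in (1, 2, 3):
        assert ece_classification(probs, true_idx, rank=rank) < 0.03


def test_ece_invariant_under_consistent_relabelling(rng):
    probs = rng.dirichlet(np.ones(5), size=2000)
    true_idx = rng.integers(0, 5, 2000)
    perm = rng.permutation(5)
    e1 = ece_classification(probs, true_idx)
    e2 = ece_classification(probs[:, perm], np.argsort(perm)[true_idx])
    assert e1 == pytest.approx(e2, abs=1e-12)


def test_confusion_matrix_perfect_and_columns():
    one_hot = np.eye(5)
    cm = confusion_matrix(one_hot, np.arange(5))
    np.testing.assert_allclose(cm, np.eye(5))
    probs = np.random.default_rng(0).dirichlet(np.ones(5), size=200)
    cm = confusion_matrix(probs, np.random.default_rng(1).integers(0, 5, 200))
    np.testing.assert_allclose(cm.sum(axis=0), 1.0, atol=1e-12)


def test_confusion_matrix_hand_example():
    probs = np.array([
        [0.6, 0.4, 0.0, 0.0, 0.0],   # pred 0, truth 0
        [0.6, 0.4, 0.0, 0.0, 0.0],   # pred 0, truth 1
        [0.1, 0.8, 0.1, 0.0, 0.0],   # pred 1, truth 1
        [0.2, 0.2, 0.2, 0.2, 0.2],   # tie -> lowest index 0, truth 0
    ])
    cm = confusion_matrix(probs, np.array([0, 1, 1, 0]))
    assert cm[0, 0] == pytest.approx(1.0)     # both truth-0 predicted 0
    assert cm[0, 1] == pytest.approx(0.5)
    assert cm[1, 1] == pytest.approx(0.5)


def test_accuracy_ties_break_to_lowest_index():
    probs = np.array([[0.2, 0.2, 0.2, 0.2, 0.2]])
    assert accuracy(probs, np.array([0])) == 1.0
    assert accuracy(probs, np.array([1])) == 0.0


def test_mean_confidence_table_cells():
    probs = np.array([
        [1.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0, 0.0],
        [0.5, 0.5, 0.0, 0.0, 0.0],
    ])
    tbl = mean_confidence_table(probs, ["FBM", "FBM", "SBM"], [0.5, 0.5, 1.0])
    np.testing.assert_allclose(tbl.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(tbl.loc[("FBM", 0.5)].to_numpy(),
                               [0.5, 0.5, 0.0, 0.0, 0.0])
    np.testing.assert_allclose(tbl.loc[("SBM", 1.0)].to_numpy(), probs[2])


def test_predicted_error_histogram_partitions(rng):
    sigma = rng.uniform(0, 0.4, 500)
    models = rng.choice(MODELS, 500)
    hist = predicted_error_histogram(sigma, {"model": models})
    assert hist["count"].sum() == 500
    # stratified counts match brute-force filtering
    for m in MODELS:
        assert hist.loc[hist["model"] == m, "count"].sum() == np.sum(models == m)


def test_predicted_error_histogram_single_bin():
    hist = predicted_error_histogram(np.full(7, 0.05), {"model": ["FBM"] * 7})
    assert len(hist) == 1 and hist["count"].iloc[0] == 7


def test_reports_bundle_metrics(rng):
    recs = _calibrated_records(5000, rng)
    rep = regression_report(recs)
    assert rep.mae is not None and rep.ence is not None and rep.ece is not None
    probs = rng.dirichlet(np.ones(5), size=2000)
    models = [MODELS[i] for i in rng.integers(0, 5, 2000)]
    crep = classification_report(probs, models, rng.uniform(0, 2, 2000))
    assert crep.confusion.shape == (5, 5)
    assert crep.mean_confidence is not None
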