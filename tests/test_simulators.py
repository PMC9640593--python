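"""Unit and statistical tests for the trajectory generators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from diffuq.simulators import (MODELS, PriorSpec, SimParams, add_noise,
                               admissible_alphas, admissible_models,
                               ensemble_msd, ensemble_positions,
                               generate_dataset, msd_loglog_slope,
                               sample_attm, sample_ctrw, sample_fbm,
                               sample_lw, sample_model, sample_sbm, truncate)
from diffuq.simulators import _fgn  # exact fGn generator, tested directly


@pytest.mark.parametrize("fn,bad_alpha", [
    (sample_ctrw, 1.2), (sample_ctrw, 0.0),
    (sample_fbm, 2.0), (sample_fbm, -0.1),
    (sample_lw, 1.0), (sample_lw, 2.3),
    (sample_attm, 1.5), (sample_attm, 0.0),
    (sample_sbm, 2.1), (sample_sbm, 0.0),
])
def test_alpha_domain_errors(fn, bad_alpha, rng):
    with pytest.raises(ValueError):
        fn(bad_alpha, 50, SimParams(), rng)


@pytest.mark.parametrize("model,alpha", [
    ("ATTM", 0.5), ("CTRW", 0.5), ("FBM", 1.2), ("LW", 1.5), ("SBM", 0.8)])
def test_origin_convention_and_length(model, alpha, rng):
    t = sample_model(model, alpha, 64, rng=rng)
    assert len(t) == 64
    assert t.clean_positions[0] == 0.0
    assert np.isinf(t.snr)


def test_ctrw_no_jump_inside_window_stays_at_origin():
    # some seed among the first 50 must put the first Pareto wait beyond T=10
    for seed in range(50):
        rng = np.random.default_rng(seed)
        first_wait = rng.random() ** (-1.0 / 0.5)
        if first_wait > 10:
            t = sample_ctrw(0.5, 10, SimParams(), np.random.default_rng(seed))
            assert np.all(t.clean_positions == 0.0)
            return
    pytest.fail("no seed with a long first waiting time found")


def test_ctrw_is_piecewise_constant(rng):
    # strongly subdiffusive walks spend most unit intervals jump-free
    zero_frac = np.mean([
        np.mean(np.diff(sample_ctrw(0.2, 100, SimParams(), rng).clean_positions) == 0)
        for _ in range(50)])
    assert zero_frac > 0.5


def test_fbm_alpha_one_is_white_noise(rng):
    incs = _fgn(1.0, 100, 1.0, rng, size=1000).ravel()
    r1 = np.corrcoef(incs[:-1], incs[1:])[0, 1]
    assert abs(r1) < 0.01
    assert incs.std() == pytest.approx(np.sqrt(2.0), rel=0.01)


@pytest.mark.parametrize("alpha,lag", [(1.5, 10), (0.5, 1), (0.7, 5)])
def test_fbm_exact_increment_autocovariance(alpha, lag, rng):
    """Empirical fGn autocovariance matches the discrete closed form (z-test)."""
    n_series, L = 4000, 40
    x = _fgn(alpha, L, 1.0, rng, size=n_series)
    prods = (x[:, :-lag] * x[:, lag:]).mean(axis=1)
    expected = (lag + 1) ** alpha - 2 * lag ** alpha + abs(lag - 1) ** alpha
    se = prods.std(ddof=1) / np.sqrt(n_series)
    assert abs(prods.mean() - expected) < 3 * se


def test_fbm_rejects_alpha_two(rng):
    with pytest.raises(ValueError):
        sample_fbm(2.0, 50, SimParams(), rng)


def test_lw_speed_bound_and_ballistic_case(rng):
    v = 1.0
    for _ in range(20):
        t = sample_lw(1.5, 100, SimParams(v_lw=v), rng)
        assert np.all(np.abs(np.diff(t.clean_positions)) <= v + 1e-12)
    # alpha = 2: increments have magnitude exactly v unless a turn falls
    # inside the interval, so the maximum must reach v
    t = sample_lw(2.0, 100, SimParams(v_lw=v), rng)
    steps = np.abs(np.diff(t.clean_positions))
    assert np.all(steps <= v + 1e-12)
    assert steps.max() == pytest.approx(v, abs=1e-9)


def test_sbm_increment_variance_closed_form(rng):
    # increment over [99, 100] at alpha = 0.5 has variance 2K(100^0.5 - 99^0.5)
    alpha, K = 0.5, 1.0
    pos = ensemble_positions("SBM", alpha, 100_000, times=np.array([99.0, 100.0]),
                             params=SimParams(K_alpha=K), rng=rng)
    var = np.var(np.diff(pos, axis=1))
    expected = 2 * K * (100 ** alpha - 99 ** alpha)
    assert var == pytest.approx(expected, rel=0.02)


def test_sbm_alpha_one_is_brownian(rng):
    t = sample_sbm(1.0, 5000, SimParams(), rng)
    incs = np.diff(t.clean_positions)
    assert incs.var() == pytest.approx(2.0, rel=0.1)


def test_attm_diffusivity_persistence(rng):
    """Squared increments correlate at lag 1: the diffusivity is held in epochs."""
    corrs = []
    for _ in range(200):
        t = sample_attm(0.5, 200, SimParams(), rng)
        s = np.diff(t.clean_positions) ** 2
        if s.std() > 0:
            corrs.append(np.corrcoef(s[:-1], s[1:])[0, 1])
    assert np.mean(corrs) > 0.05


def test_attm_alpha_one_uses_gamma_one(rng):
    from diffuq.simulators import _attm_gamma
    assert _attm_gamma(1.0, rng) == 1.0
    g = np.array([_attm_gamma(0.5, rng) for _ in range(200)])
    assert np.all((g >= 1.0) & (g <= 2.0))   # 1/(1-0.5) = 2 caps the interval


# ------------------------------------------------------------------- noise

def test_noise_std_matches_snr(rng):
    t = sample_sbm(1.0, 10_000, SimParams(), rng)
    for snr in (1.0, 2.0, 10.0):
        noisy = add_noise(t, snr, rng)
        sigma_dx = np.std(np.diff(t.clean_positions))
        measured = np.std(noisy.positions - noisy.clean_positions)
        assert measured == pytest.approx(sigma_dx / snr, rel=0.03)


def test_noise_infinite_snr_is_identity(rng):
    t = sample_fbm(0.8, 50, SimParams(), rng)
    noisy = add_noise(t, np.inf, rng)
    np.testing.assert_array_equal(noisy.positions, t.clean_positions)


def test_brownian_snr_one_triples_increment_variance(rng):
    t = sample_sbm(1.0, 100_000, SimParams(), rng)
    noisy = add_noise(t, 1.0, rng)
    sigma2 = np.var(np.diff(t.clean_positions))
    assert np.var(np.diff(noisy.positions)) == pytest.approx(3 * sigma2, rel=0.05)


def test_constant_trajectory_warns_and_adds_no_noise():
    t = sample_ctrw(0.5, 10, SimParams(), np.random.default_rng(0))
    t.clean_positions[:] = 0.0
    t.positions[:] = 0.0
    with pytest.warns(RuntimeWarning, match="constant"):
        noisy = add_noise(t, 2.0, np.random.default_rng(1))
    np.testing.assert_array_equal(noisy.positions, t.clean_positions)


def test_truncate_keeps_prefix(rng):
    t = sample_fbm(1.2, 100, SimParams(), rng)
    short = truncate(t, 30)
    assert len(short) == 30
    np.testing.assert_array_equal(short.clean_positions, t.clean_positions[:30])


# ------------------------------------------------------------ admissibility

@given(st.sampled_from([round(0.05 * k, 2) for k in range(1, 41)]),
       st.sampled_from(MODELS))
def test_admissibility_is_symmetric(alpha, model):
    in_models = model in admissible_models(alpha)
    in_alphas = alpha in admissible_alphas(model)
    assert in_models == in_alphas


def test_admissible_ranges():
    assert admissible_models(0.5) == ("ATTM", "CTRW", "FBM", "SBM")
    assert admissible_models(1.5) == ("FBM", "LW", "SBM")
    assert admissible_models(2.0) == ("LW", "SBM")


# ----------------------------------------------------------------- datasets

def test_classification_counts_exactly_stratified():
    ds = generate_dataset("classification", 500, 20, master_seed=3)
    counts = {m: 0 for m in MODELS}
    for t in ds.trajectories:
        counts[t.model] += 1
        assert t.model in admissible_models(t.alpha)
    assert all(c == 100 for c in counts.values())


def test_regression_counts_exactly_stratified():
    ds = generate_dataset("regression", 400, 20, master_seed=4)
    alphas = np.array([t.alpha for t in ds.trajectories])
    vals, counts = np.unique(alphas, return_counts=True)
    assert len(vals) == 40 and np.all(counts == 10)
    for t in ds.trajectories:
        assert t.model in admissible_models(t.alpha)


def test_regression_overrepresents_full_range_models():
    ds = generate_dataset("regression", 4000, 10, master_seed=5)
    freq = {m: 0 for m in MODELS}
    for t in ds.trajectories:
        freq[t.model] += 1
    assert freq["FBM"] / 4000 > 0.2
    assert freq["SBM"] / 4000 > 0.2


def test_dataset_determinism():
    a = generate_dataset("classification", 3, 15, master_seed=77)
    b = generate_dataset("classification", 3, 15, master_seed=77)
    for ta, tb in zip(a.trajectories, b.trajectories):
        np.testing.assert_array_equal(ta.positions, tb.positions)
        assert (ta.model, ta.alpha, ta.snr) == (tb.model, tb.alpha, tb.snr)


def test_single_model_prior_restriction():
    prior = PriorSpec(task="regression", models=("FBM",))
    ds = generate_dataset("regression", 50, 15, prior, master_seed=6)
    assert all(t.model == "FBM" for t in ds.trajectories)
    assert all(t.alpha < 2.0 for t in ds.trajectories)


# ---------------------------------------------------------------------- MSD

def test_msd_slope_recovers_pure_power_law():
    t = np.arange(100, dtype=float)
    msd = 3.0 * t ** 1.4
    assert msd_loglog_slope(msd) == pytest.approx(1.4, abs=1e-12)


def test_ensemble_msd_matches_brute_force(rng):
    pos = rng.standard_normal((50, 20)).cumsum(axis=1)
    msd = ensemble_msd(pos)
    brute = [np.mean([(row[t] - row[0]) ** 2 for row in pos]) for t in range(20)]
    np.testing.assert_allclose(msd, brute, rtol=1e-12)


@pytest.mark.parametrize("model,alpha", [("FBM", 0.5), ("SBM", 1.5)])
def test_exact_gaussian_models_scale_exactly(model, alpha, rng):
    """FBM/SBM obey <x^2(t)> = 2 K t^alpha exactly; slope fits at modest n."""
    pos = ensemble_positions(model, alpha, 3000, T_traj=100, rng=rng)
    slope = msd_loglog_slope(ensemble_msd(pos))
    assert slope == pytest.approx(alpha, abs=0.1)
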