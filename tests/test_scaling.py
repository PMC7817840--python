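import itertools

import numpy as np
import pytest

from infoscale import fisher, popsim, scaling
from infoscale.fisher import InfoEstimate
from infoscale.popsim import PopulationConfig, make_population, sample_trials, shuffle_trials
from conftest import make_exact_dataset


def test_increments_telescope_to_full_estimate(ds_small):
    full = fisher.bias_corrected_info(ds_small)
    f, s = fisher.empirical_moments(ds_small)
    rng = np.random.default_rng(30)
    for _ in range(5):
        ordering = rng.permutation(ds_small.n_neurons)
        infos = scaling.ordering_prefix_infos(
            f, s, ordering, T=ds_small.n_trials, delta_theta=ds_small.delta_theta
        )
        increments = np.diff(infos, prepend=0.0)
        assert abs(increments.sum() - full.value) < 1e-12


def test_exhaustive_ordering_oracle_three_independent_neurons():
    # per-neuron infos (3, 2, 1) with diagonal covariance: averaging over all
    # 6 orderings, the expected increment at every position is 2
    f = np.sqrt(np.array([3.0, 2.0, 1.0]))
    sigma = np.eye(3)
    orderings = list(itertools.permutations(range(3)))
    curve = scaling.increment_curve_from_moments(
        f, sigma, T=None, delta_theta=np.deg2rad(45.0),
        bias_corrected=False, orderings=orderings,
    )
    assert np.allclose(curve.mu, 2.0, atol=1e-12)
    assert np.allclose(curve.cum_mean, [2.0, 4.0, 6.0], atol=1e-12)


def test_sampled_orderings_match_exact_enumeration():
    rng = np.random.default_rng(31)
    a = rng.standard_normal((5, 5)) * 0.3
    sigma = a @ a.T + np.eye(5)
    f = rng.standard_normal(5)
    exact = scaling.increment_curve_from_moments(
        f, sigma, T=None, delta_theta=1.0, bias_corrected=False,
        orderings=list(itertools.permutations(range(5))),
    )
    sampled = scaling.increment_curve_from_moments(
        f, sigma, T=None, delta_theta=1.0, bias_corrected=False,
        n_orderings=4000, seed=32,
    )
    se = np.sqrt(exact.sigma2 / 4000)
    assert np.all(np.abs(sampled.mu - exact.mu) < 4 * np.maximum(se, 1e-12))


def test_increment_means_flat_for_independent_neurons():
    # diagonal ground truth: information is additive, so mu_N is flat in N
    cfg = PopulationConfig(n_neurons=30, i_inf=np.inf, sigma0_kind="diagonal")
    gt = make_population(cfg, seed=33)
    ds = sample_trials(gt, T=150, seed=34)
    curve = scaling.increment_curve(ds, n_orderings=400, seed=35)
    slope, _ = np.polyfit(curve.sizes, curve.mu, 1)
    # slope consistent with zero at 3 across-ordering SE
    se_slope = np.sqrt(curve.sigma2 / curve.n_orderings).mean() / curve.n_max
    assert abs(slope) < 3 * max(se_slope, 1e-4)


def test_shuffling_linearizes_limited_information_scaling():
    cfg = PopulationConfig(n_neurons=40, i_inf=4.0, rho_max=0.3)
    gt = make_population(cfg, seed=36)
    ds = sample_trials(gt, T=200, seed=37)
    raw = scaling.increment_curve(ds, n_orderings=300, seed=38)
    shuf = scaling.increment_curve(shuffle_trials(ds, seed=39), n_orderings=300, seed=38)
    slope_raw = np.polyfit(raw.sizes, raw.mu, 1)[0]
    slope_shuf = np.polyfit(shuf.sizes, shuf.mu, 1)[0]
    # limited-info increments decline with N; shuffled increments stay flat
    assert slope_raw < slope_shuf
    assert abs(slope_shuf) < 0.5 * abs(slope_raw)
    assert shuf.total_info > raw.total_info


def test_increment_curve_requires_enough_trials(ds_small):
    with pytest.raises(ValueError, match="maximum admissible"):
        scaling.increment_curve(ds_small, n_orderings=10, seed=0, n_max=ds_small.n_trials)


def test_greedy_ordering_diagonal_sorts_by_info():
    f = np.sqrt(np.array([3.0, 2.0, 1.0]))
    ds = make_exact_dataset(np.zeros(3), f, np.eye(3), T=40, conditions=(0.0, popsim.np.rad2deg(1.0)))
    assert list(scaling.greedy_ordering(ds)) == [0, 1, 2]


def test_greedy_prefixes_dominate_same_first_pick_orderings():
    # weakly correlated 5-neuron instance: every greedy prefix encodes at
    # least as much information as any other prefix of the same length that
    # starts from the same first neuron (verified by exhaustive enumeration)
    rng = np.random.default_rng(5)
    a = rng.standard_normal((5, 5)) * 0.25
    sigma = a @ a.T + np.eye(5)
    f = rng.standard_normal(5) + 1.0
    ds = make_exact_dataset(np.zeros(5), f, sigma, T=60, conditions=(0.0, popsim.np.rad2deg(1.0)))
    order = scaling.greedy_ordering(ds)

    def info(subset):
        s = list(subset)
        return f[s] @ np.linalg.solve(sigma[np.ix_(s, s)], f[s])

    first = order[0]
    assert info([first]) == max(info([j]) for j in range(5))
    for L in range(1, 6):
        greedy_info = info(order[:L])
        for comb in itertools.permutations(range(5), L):
            if comb[0] != first:
                continue
            assert info(comb) <= greedy_info + 1e-10


def test_greedy_average_objective_balances_discriminations():
    # neuron 0 is best for the first discrimination, neuron 1 for the second,
    # but neuron 2 maximizes the mean information gain
    conds = (0.0, popsim.np.rad2deg(1.0))
    ds1 = make_exact_dataset(np.zeros(3), [2.0, 0.0, 1.7], np.eye(3), T=40, conditions=conds)
    ds2 = make_exact_dataset(np.zeros(3), [0.0, 2.0, 1.7], np.eye(3), T=40, conditions=conds)
    assert scaling.greedy_ordering(ds1)[0] == 0
    assert scaling.greedy_ordering(ds2)[0] == 1
    assert scaling.greedy_ordering([ds1, ds2], objective="average")[0] == 2
    with pytest.raises(ValueError, match="share the neuron set"):
        ds_bad = make_exact_dataset(np.zeros(2), np.ones(2), np.eye(2), T=40, conditions=conds)
        scaling.greedy_ordering([ds1, ds_bad], objective="average")


def test_fixed_order_curve_zero_variance_collapses(monkeypatch, ds_small):
    monkeypatch.setattr(scaling, "_analytic_variance", lambda *a, **k: 0.0)
    curve = scaling.fixed_order_curve(ds_small, np.arange(ds_small.n_neurons), n_boot=50, seed=40)
    assert np.allclose(curve.boot_curves, curve.point[None, :])


def test_fixed_order_bootstrap_sd_is_running_sum_of_increment_variance(ds_corr):
    curve = scaling.fixed_order_curve(ds_corr, np.arange(ds_corr.n_neurons), n_boot=4000, seed=41)
    # independence: bootstrap variance of I_N accumulates increment variances,
    # hence the SD is non-decreasing in N and matches the analytic total
    sd = curve.boot_sd
    assert np.all(np.diff(sd) > -1e-9)
    assert curve.boot_mean == pytest.approx(curve.point, rel=0.05, abs=0.05)


def test_fixed_order_band_covers_true_curve(gt_corr):
    ds = sample_trials(gt_corr, T=400, seed=42)
    curve = scaling.fixed_order_curve(ds, np.arange(gt_corr.n_neurons), n_boot=800, seed=43)
    truth = np.array(
        [popsim.closed_form_info(gt_corr, np.arange(k + 1)) for k in range(gt_corr.n_neurons)]
    )
    inside = np.abs(curve.point - truth) <= 2.0 * curve.boot_sd
    assert inside.mean() >= 0.9


def test_capture_size_examples():
    linear = np.arange(1.0, 11.0)
    assert scaling.capture_size(linear, 0.9) == (9, None)
    # lim-model curve c=1, I_inf=100, N_max=300: I_300 = 75, target 67.5,
    # smallest N with I_N >= 67.5 is 1/(1/67.5 - 1/100) = 207.7 -> 208
    n = np.arange(1, 301)
    curve = 1.0 / (1.0 / n + 1.0 / 100.0)
    assert scaling.capture_size(curve, 0.9)[0] == 208
    assert scaling.capture_size(linear, 0.999999)[0] == 10
    with pytest.raises(ValueError):
        scaling.capture_size(linear, 1.5)


def test_capture_size_bootstrap_ci(ds_corr):
    curve = scaling.fixed_order_curve(ds_corr, np.arange(ds_corr.n_neurons), n_boot=500, seed=44)
    size, ci = scaling.capture_size(curve, 0.9)
    assert ci is not None and 1 <= ci[0] <= size <= ci[1] <= curve.n_max


def _est(value, variance):
    return InfoEstimate(value=value, variance=variance, n_neurons=10, n_trials=50,
                        delta_theta=np.deg2rad(45.0))


def test_info_difference_test_conventions():
    assert scaling.info_difference_test(_est(2.0, 1.0), _est(2.0, 1.0)) == pytest.approx(0.5)
    # A exceeding B by 5 SD of the difference leaves ~Phi(-5) probability
    pa = scaling.info_difference_test(_est(5.0, 0.5), _est(0.0, 0.5))
    assert pa == pytest.approx(2.8665e-7, rel=1e-3)
    pb = scaling.info_difference_test(_est(0.0, 0.5), _est(5.0, 0.5))
    assert pa + pb == pytest.approx(1.0)
    # degenerate zero-variance cases
    assert scaling.info_difference_test(_est(1.0, 0.0), _est(1.0, 0.0)) == 0.5
    assert scaling.info_difference_test(_est(2.0, 0.0), _est(1.0, 0.0)) == 0.0


def test_threshold_equality_test_null_and_power():
    null = [_est(3.0, 0.25) for _ in range(4)]
    assert scaling.threshold_equality_test(null, n_boot=20_000, seed=45) >= 0.3
    displaced = [_est(3.0, 0.25), _est(3.0, 0.25), _est(3.0, 0.25), _est(8.0, 0.25)]
    assert scaling.threshold_equality_test(displaced, n_boot=20_000, seed=46) < 0.01
    degenerate = [_est(3.0, 0.0), _est(3.0, 0.0)]
    assert scaling.threshold_equality_test(degenerate, n_boot=100, seed=47) == 0.5
    with pytest.raises(ValueError):
        scaling.threshold_equality_test([_est(1.0, 1.0)])


def test_ordering_file_roundtrip(tmp_path):
    path = tmp_path / "ordering.txt"
    order = np.array([3, 0, 2, 1])
    scaling.save_ordering(order, path)
    assert path.read_text() == "3\n0\n2\n1\n"
    assert np.array_equal(scaling.load_ordering(path), order)
    path.write_text("0\n0\n1\n")
    with pytest.raises(ValueError, match="duplicate"):
        scaling.load_ordering(path)


def test_curve_serialization_roundtrip(tmp_path, ds_small):
    curve = scaling.increment_curve(ds_small, n_orderings=50, seed=48)
    path = tmp_path / "curve.tsv"
    curve.to_csv(path)
    back = scaling.ScalingCurve.from_csv(path, delta_theta=curve.delta_theta)
    assert np.allclose(back.mu, curve.mu)
    assert np.allclose(back.sigma2, curve.sigma2)
    assert np.allclose(back.cum_mean, curve.cum_mean)
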