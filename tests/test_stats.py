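"""Exact Mann-Whitney, Spearman, Cox and meta-analysis."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurogg.stats import (
    cox_fit_single,
    mann_whitney_exact,
    mann_whitney_u,
    meta_fixed_random,
    midranks,
    spearman_rho,
)
from neurogg.synthetic import SurvivalSimParams, simulate_survival_study


# --- Mann-Whitney -----------------------------------------------------------

def test_complete_separation_7_vs_4():
    res = mann_whitney_exact([1, 2, 3, 4, 5, 6, 7], [8, 9, 10, 11])
    assert res.method == "exact"
    assert res.U == 0.0
    assert res.p_two_sided == pytest.approx(2 / 330)
    assert round(res.p_two_sided, 4) == 0.0061


def test_one_inversion_7_vs_4():
    res = mann_whitney_exact([1, 2, 3, 4, 5, 6, 7], [6.5, 8, 9, 10])
    assert res.U == 1.0
    assert res.p_two_sided == pytest.approx(4 / 330)
    assert round(res.p_two_sided, 4) == 0.0121


def test_single_tied_pair_gives_p_one():
    res = mann_whitney_exact([3.0], [3.0])
    assert res.U == 0.5
    assert res.p_two_sided == 1.0


def test_empty_group_raises():
    with pytest.raises(ValueError):
        mann_whitney_exact([], [1.0])


def _brute_force_p(x, y):
    """Independent oracle: rank-sum U over every assignment of pooled values."""
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))
    u_obs = mann_whitney_u(x, y)
    us = []
    for chosen in combinations(idx, n1):
        xs = [pooled[i] for i in chosen]
        ranks = midranks(pooled)
        r1 = sum(ranks[i] for i in chosen)
        us.append(r1 - n1 * (n1 + 1) / 2.0)  # U from the rank-sum identity
    us = np.asarray(us)
    le = float(np.mean(us <= u_obs + 1e-9))
    ge = float(np.mean(us >= u_obs - 1e-9))
    return min(1.0, 2 * min(le, ge))


@pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (4, 4), (3, 7), (5, 5)])
def test_exact_p_matches_rank_sum_oracle(n1, n2, rng):
    for _ in range(40):
        x = rng.integers(0, 6, n1).astype(float)  # coarse grid forces ties
        y = rng.integers(0, 6, n2).astype(float)
        res = mann_whitney_exact(x, y)
        assert res.p_two_sided == pytest.approx(_brute_force_p(x, y))


def test_exact_p_matches_scipy_without_ties(rng):
    from scipy.stats import mannwhitneyu
    for _ in range(30):
        x = rng.permutation(np.arange(9, dtype=float))[:5]
        y = rng.permutation(np.arange(9, 20, dtype=float))[:4]
        ours = mann_whitney_exact(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


@given(st.lists(st.integers(0, 30), min_size=1, max_size=5),
       st.lists(st.integers(0, 30), min_size=1, max_size=5))
def test_exact_p_invariant_under_monotone_transform(xs, ys):
    base = mann_whitney_exact(xs, ys).p_two_sided
    fx = [math.exp(0.3 * v) + 5 for v in xs]
    fy = [math.exp(0.3 * v) + 5 for v in ys]
    assert mann_whitney_exact(fx, fy).p_two_sided == pytest.approx(base)


def test_large_samples_fall_back_to_normal_approx(rng):
    x = rng.normal(0, 1, 60)
    y = rng.normal(0.8, 1, 60)
    res = mann_whitney_exact(x, y)
    assert res.method == "normal_approx"
    from scipy.stats import mannwhitneyu
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


# --- Spearman ---------------------------------------------------------------

def test_spearman_examples():
    assert spearman_rho([1, 2, 3, 4], [2, 4, 6, 8]).rho == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3, 4], [8, 6, 4, 2]).rho == pytest.approx(-1.0)
    assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]).rho == pytest.approx(0.8)


def test_spearman_matches_scipy_with_ties(rng):
    from scipy.stats import spearmanr
    for _ in range(25):
        x = rng.integers(0, 5, 12).astype(float)
        y = x + rng.integers(-2, 3, 12)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        assert spearman_rho(x, y).rho == pytest.approx(spearmanr(x, y).statistic, rel=1e-9)


def test_spearman_degenerate_inputs():
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [3, 4])
    with pytest.raises(ValueError):
        spearman_rho([1, 1, 1], [1, 2, 3])


# --- Cox --------------------------------------------------------------------

def test_cox_constant_covariate_raises():
    with pytest.raises(ValueError):
        cox_fit_single([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])


def test_cox_antisymmetry():
    time = [5, 8, 2, 9, 4, 7, 1, 6]
    event = [1, 0, 1, 1, 0, 1, 1, 1]
    x = [0, 0, 0, 0, 1, 1, 1, 1]
    a = cox_fit_single(time, event, x)
    b = cox_fit_single(time, event, [1 - v for v in x])
    assert a.log_hr == pytest.approx(-b.log_hr, abs=1e-8)
    assert a.se == pytest.approx(b.se, rel=1e-8)


def test_cox_matches_lifelines_on_simulated_cohort():
    lifelines = pytest.importorskip("lifelines")
    df = simulate_survival_study(SurvivalSimParams(n=500, hazard_ratio=0.6, seed=3))
    fit = cox_fit_single(df["time"], df["event"], df["x"])
    assert fit.converged
    cph = lifelines.CoxPHFitter().fit(df, duration_col="time", event_col="event")
    # no tied event times, so Breslow and Efron coincide
    assert fit.log_hr == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
    assert fit.se == pytest.approx(float(cph.standard_errors_.iloc[0]), rel=1e-6)
    true_beta = math.log(0.6)
    assert abs(fit.log_hr - true_beta) < 3 * fit.se


def test_cox_fit_properties():
    df = simulate_survival_study(SurvivalSimParams(n=200, hazard_ratio=1.5, seed=4))
    fit = cox_fit_single(df["time"], df["event"], df["x"])
    lo, hi = fit.ci95
    assert lo < fit.hr < hi
    assert fit.hr > 0
    assert (fit.z > 0) == (fit.log_hr > 0)


def test_cox_handles_tied_event_times():
    time = [3, 3, 3, 5, 5, 8, 9, 9]
    event = [1, 1, 0, 1, 1, 1, 0, 1]
    x = [0.5, -1.0, 0.2, 1.5, -0.3, 0.9, -0.7, 0.1]
    fit = cox_fit_single(time, event, x)
    assert fit.converged and np.isfinite(fit.se)


# --- meta-analysis ----------------------------------------------------------

def test_meta_single_study():
    r = meta_fixed_random([-0.3], [0.1])
    assert r.common_effect == pytest.approx(-0.3)
    assert r.q == 0.0 and r.tau2 == 0.0 and r.i2 == 0.0
    assert r.random_effect == pytest.approx(-0.3)


def test_meta_homogeneous_inputs():
    r = meta_fixed_random([-0.4, -0.4, -0.4], [0.2, 0.25, 0.1])
    assert r.tau2 == 0.0
    assert r.i2 == 0.0
    assert r.common_effect == pytest.approx(r.random_effect)


def test_meta_three_study_worked_example():
    # hand inverse-variance arithmetic: w = 25, 16, 100
    # pooled = (25*-0.5 + 16*-0.3 + 100*-0.4)/141 = -57.3/141
    r = meta_fixed_random([-0.5, -0.3, -0.4], [0.2, 0.25, 0.1])
    assert r.common_effect == pytest.approx(-57.3 / 141, rel=1e-12)
    assert r.common_se == pytest.approx(1 / math.sqrt(141), rel=1e-12)
    assert r.q == pytest.approx(0.4042553191489313, rel=1e-9)
    assert r.tau2 == 0.0  # Q < df
    assert r.i2 == 0.0
    assert sum(r.common_weights) == pytest.approx(1.0)
    assert sum(r.random_weights) == pytest.approx(1.0)


def test_meta_matches_statsmodels():
    sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
    theta = [-0.6, -0.1, -0.45, 0.05]
    se = [0.25, 0.15, 0.3, 0.2]
    ours = meta_fixed_random(theta, se)
    ref = sm_meta.combine_effects(np.array(theta), np.array(se) ** 2,
                                  method_re="dl")
    assert ours.common_effect == pytest.approx(ref.mean_effect_fe, rel=1e-9)
    assert ours.random_effect == pytest.approx(ref.mean_effect_re, rel=1e-9)
    assert ours.tau2 == pytest.approx(ref.tau2, rel=1e-9)
    assert ours.q == pytest.approx(ref.q, rel=1e-9)


def test_meta_pooled_equals_precision_weighted_mean(rng):
    theta = rng.normal(-0.4, 0.3, 6)
    se = rng.uniform(0.05, 0.4, 6)
    r = meta_fixed_random(theta, se)
    w = 1 / se**2
    assert r.common_effect == pytest.approx(float((w * theta).sum() / w.sum()), rel=1e-14)
    assert r.tau2 >= 0.0
    assert 0.0 <= r.i2 <= 1.0


def test_random_effects_se_not_below_common_se(rng):
    for _ in range(20):
        theta = rng.normal(-0.4, 0.02, 3)
        se = rng.uniform(0.1, 0.3, 3)
        r = meta_fixed_random(theta, se)
        assert r.random_se >= r.common_se - 1e-12


def test_meta_validation():
    with pytest.raises(ValueError):
        meta_fixed_random([], [])
    with pytest.raises(ValueError):
        meta_fixed_random([0.1], [0.0])
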