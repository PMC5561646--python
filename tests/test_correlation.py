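"""Random-effect, marginal, conditional and pointwise correlation summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bivlmm import (
    ConditionalQuery,
    DegenerateInputError,
    LongitudinalDataset,
    RandomEffectsCov,
    conditional_correlation,
    empirical_bootstrap_ci,
    joint_moments,
    marginal_correlation,
    marginal_curve,
    pointwise_pearson,
    re_correlations,
)
from conftest import PRESET_SIGMA, make_fit


# -- association of evolution ---------------------------------------------


def test_re_correlations_preset_values():
    est = re_correlations(RandomEffectsCov(PRESET_SIGMA))
    assert est.rho_intercept == pytest.approx(1.13 / np.sqrt(1.65 * 36.5), rel=1e-12)
    assert est.rho_slope == pytest.approx(0.03 / np.sqrt(0.09 * 0.81), rel=1e-12)
    # printed to three decimals these are 0.146 and 0.111
    assert round(est.rho_intercept, 3) == 0.146
    assert round(est.rho_slope, 3) == 0.111


def test_re_correlations_diagonal_and_degenerate():
    est = re_correlations(RandomEffectsCov(np.diag([1.0, 2.0, 3.0, 4.0])))
    assert est.rho_intercept == 0.0 and est.rho_slope == 0.0
    with pytest.raises(DegenerateInputError):
        re_correlations(RandomEffectsCov(np.diag([0.0, 1.0, 1.0, 1.0])))


def test_re_correlation_cohort_intercept_arithmetic():
    # Cov(I1,I2)=3.88, Var(I1)=5.09, Var(I2)=38.77 -> 0.276
    rho = 3.88 / np.sqrt(5.09 * 38.77)
    S = np.diag([5.09, 38.77, 0.29, 1.35])
    S[0, 1] = S[1, 0] = 3.88
    est = re_correlations(RandomEffectsCov(S))
    assert est.rho_intercept == pytest.approx(rho, rel=1e-12)
    assert round(est.rho_intercept, 3) == 0.276


# -- evolution of association ---------------------------------------------


def test_marginal_zero_cross_covariance_gives_zero():
    S = PRESET_SIGMA.copy()
    S[0, 1] = S[1, 0] = S[0, 3] = S[3, 0] = S[1, 2] = S[2, 1] = S[2, 3] = S[3, 2] = 0.0
    fit = make_fit(Sigma=S)
    t = np.linspace(0, 10, 25)
    np.testing.assert_allclose(marginal_correlation(fit, t), 0.0, atol=1e-15)


def test_marginal_at_zero_hand_value():
    # cohort bivariate column: 3.88 / (sqrt(5.09+2.02) * sqrt(38.77+19.19))
    S = np.diag([5.09, 38.77, 0.29, 1.35])
    S[0, 1] = S[1, 0] = 3.88
    fit = make_fit(Sigma=S, s1sq=2.02, s2sq=19.19)
    rho0 = marginal_correlation(fit, 0.0)
    assert rho0 == pytest.approx(3.88 / (np.sqrt(7.11) * np.sqrt(57.96)), rel=1e-12)
    assert rho0 == pytest.approx(0.191, abs=5e-4)


def test_marginal_large_t_converges_to_slope_correlation(preset_fit):
    est = re_correlations(preset_fit.re_cov)
    assert marginal_correlation(preset_fit, 1e4) == pytest.approx(est.rho_slope, abs=1e-3)


def test_marginal_consistent_with_joint_moments(preset_fit):
    for t in (0.0, 1.0, 3.7):
        _, cov = joint_moments(preset_fit, None, t)
        expected = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert marginal_correlation(preset_fit, t) == pytest.approx(expected, rel=1e-12)


def test_marginal_correlated_errors_adds_sigma12():
    fit_c = make_fit(s12=0.8 * np.sqrt(2.0 * 19.0), error_model="correlated")
    fit_i = make_fit()
    t = 1.3
    S, e = PRESET_SIGMA, fit_c.err
    d1 = S[0, 0] + 2 * t * S[0, 2] + t**2 * S[2, 2] + e.sigma1_sq
    d2 = S[1, 1] + 2 * t * S[1, 3] + t**2 * S[3, 3] + e.sigma2_sq
    gap = e.sigma12 / np.sqrt(d1 * d2)
    assert marginal_correlation(fit_c, t) - marginal_correlation(fit_i, t) == pytest.approx(gap, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.lists(st.floats(-2, 2), min_size=16, max_size=16),
    e1=st.floats(0.1, 5.0),
    e2=st.floats(0.1, 5.0),
    t=st.floats(0.0, 50.0),
)
def test_marginal_correlation_bounded_property(a, e1, e2, t):
    """|rho(t)| <= 1 for any PSD random-effect covariance and any time."""
    A = np.array(a).reshape(4, 4)
    S = A @ A.T + 1e-3 * np.eye(4)
    fit = make_fit(Sigma=S, s1sq=e1, s2sq=e2)
    assert abs(marginal_correlation(fit, t)) <= 1.0 + 1e-12


def test_marginal_curve_frame_layout(preset_fit):
    curve = marginal_curve(preset_fit)
    frame = curve.to_frame()
    assert list(frame.columns) == ["time", "rho", "ci_lower", "ci_upper", "flavor", "n_eff"]
    assert frame["time"].iloc[0] == 0.0 and frame["time"].iloc[-1] == 7.5
    assert (frame["rho"].abs() <= 1).all()


# -- joint moments ---------------------------------------------------------


def test_joint_moments_at_time_zero(preset_fit):
    mean, cov = joint_moments(preset_fit, None, 0.0)
    S = PRESET_SIGMA
    assert cov[0, 2] == pytest.approx(S[0, 0])          # nu13 = var(a0)
    assert cov[0, 3] == pytest.approx(S[0, 2])          # nu14 = cov(a0,a1)
    assert cov[0, 0] == pytest.approx(S[0, 0] + 2.0)    # nu11 = var(a0)+sigma1^2
    assert cov[2, 2] == pytest.approx(S[0, 0])          # nu33
    assert cov[3, 3] == pytest.approx(S[2, 2])          # nu44
    np.testing.assert_allclose(mean, [-2.0, 53.0, -2.0, -0.2])


def test_joint_moments_cross_term_hand_value(preset_fit):
    # nu12(1) = 1.13 + 0.13 + 0.40 + 0.03 = 1.69 with the preset Sigma
    _, cov = joint_moments(preset_fit, None, 1.0)
    assert cov[0, 1] == pytest.approx(1.69, abs=1e-12)


def _draw_joint(fit, t, n, rng):
    """Direct draws of (Y1(t), Y2(t), gamma0, gamma1) from the generating model."""
    S = fit.re_cov.Sigma
    re = rng.multivariate_normal(np.zeros(4), S, size=n)
    e1 = rng.normal(0, np.sqrt(fit.err.sigma1_sq), n)
    e2 = rng.normal(0, np.sqrt(fit.err.sigma2_sq), n)
    f = fit.fixed
    y1 = f.alpha0 + re[:, 0] + (f.alpha1 + re[:, 2]) * t + e1
    y2 = f.beta0 + re[:, 1] + (f.beta1 + re[:, 3]) * t + e2
    g0 = f.alpha0 + re[:, 0]
    g1 = f.alpha1 + re[:, 2]
    return np.column_stack([y1, y2, g0, g1])


def test_joint_moments_match_simulation_oracle(preset_fit):
    """Covariance of 1e6 generative draws reproduces the nu-matrix entrywise."""
    rng = np.random.default_rng(123)
    n = 1_000_000
    draws = _draw_joint(preset_fit, 1.0, n, rng)
    mean, cov = joint_moments(preset_fit, None, 1.0)
    emp = np.cov(draws.T)
    # MC standard error of a covariance entry ~ sqrt((v_ii v_jj + v_ij^2)/n)
    for i in range(4):
        for j in range(4):
            se = np.sqrt((cov[i, i] * cov[j, j] + cov[i, j] ** 2) / n)
            assert abs(emp[i, j] - cov[i, j]) < 3 * se, (i, j)
    np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.05)


def test_marginal_equals_empirical_pearson_of_draws(preset_fit):
    rng = np.random.default_rng(7)
    n = 1_000_000
    for t in (0.0, 2.5):
        draws = _draw_joint(preset_fit, t, n, rng)
        emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        rho = marginal_correlation(preset_fit, t)
        se = (1 - rho**2) / np.sqrt(n)
        assert abs(emp - rho) < 3 * se


# -- conditional correlation -----------------------------------------------


def test_conditional_without_truncation_equals_marginal(preset_fit):
    q = ConditionalQuery(c1=-np.inf, c2=-np.inf, n_subjects=300, n_boot=400, seed=1)
    for t in (0.0, 3.0):
        est = conditional_correlation(preset_fit, q, t)
        se = np.std(est.replicates) / np.sqrt(len(est.replicates))
        assert est.n_dropped == 0
        assert abs(est.estimate - marginal_correlation(preset_fit, t)) < 3 * se + 1e-4


def test_conditional_zero_cross_covariance_stays_zero():
    S = PRESET_SIGMA.copy()
    S[0, 1] = S[1, 0] = S[0, 3] = S[3, 0] = S[1, 2] = S[2, 1] = S[2, 3] = S[3, 2] = 0.0
    fit = make_fit(Sigma=S)
    q = ConditionalQuery(c1=-5.0, c2=-0.5, n_subjects=300, n_boot=400, seed=2)
    for t in (0.0, 2.0):
        est = conditional_correlation(fit, q, t)
        se = np.std(est.replicates) / np.sqrt(len(est.replicates))
        assert abs(est.estimate) < 3 * se + 1e-3


def test_conditional_matches_brute_force_truncation_oracle(preset_fit):
    """Single-pass Monte-Carlo truncated-normal Pearson vs the bootstrap path."""
    t = 1.0
    rng = np.random.default_rng(99)
    n = 2_000_000
    draws = _draw_joint(preset_fit, t, n, rng)
    keep = (draws[:, 2] > -5.0) & (draws[:, 3] > -0.5)
    oracle = np.corrcoef(draws[keep, 0], draws[keep, 1])[0, 1]

    q = ConditionalQuery(c1=-5.0, c2=-0.5, n_subjects=300, n_boot=800, seed=3)
    est = conditional_correlation(preset_fit, q, t)
    se = np.std(est.replicates) / np.sqrt(len(est.replicates))
    oracle_se = (1 - oracle**2) / np.sqrt(keep.sum())
    assert abs(est.estimate - oracle) < 3 * (se + oracle_se)
    assert est.ci[0] <= est.estimate <= est.ci[1]


def test_conditional_is_deterministic_given_seed(preset_fit):
    q = ConditionalQuery(n_subjects=100, n_boot=50, seed=42)
    a = conditional_correlation(preset_fit, q, 1.0)
    b = conditional_correlation(preset_fit, ConditionalQuery(n_subjects=100, n_boot=50, seed=42), 1.0)
    assert a.estimate == b.estimate and a.ci == b.ci


def test_conditional_extreme_thresholds_flagged_unreliable(preset_fit):
    q = ConditionalQuery(c1=50.0, c2=50.0, n_subjects=20, n_boot=40, seed=0)
    est = conditional_correlation(preset_fit, q, 0.0)
    assert est.unreliable


# -- pointwise Pearson -----------------------------------------------------


def _paired_dataset(x, y, t=1.0):
    n = len(x)
    obs = pd.DataFrame({
        "subject_id": np.repeat([f"s{i}" for i in range(n)], 2),
        "outcome": ["MD", "VA"] * n,
        "time": [t, t] * n,
        "value": np.column_stack([x, y]).ravel(),
    })
    return LongitudinalDataset.from_frames(obs, "MD", "VA")


def test_pointwise_pearson_perfect_line():
    x = np.arange(35.0)
    ds = _paired_dataset(x, 3.0 * x - 1.0)
    assert pointwise_pearson(ds, 1.0) == pytest.approx(1.0)


def test_pointwise_pearson_min_n_rule():
    x = np.arange(29.0)
    ds = _paired_dataset(x, x + np.sin(x))
    assert pointwise_pearson(ds, 1.0, min_n=30) is None
    assert pointwise_pearson(ds, 1.0, min_n=20) is not None


def test_pointwise_pearson_product_moment_formula():
    rng = np.random.default_rng(5)
    x = rng.normal(size=50)
    y = 0.5 * x + rng.normal(size=50)
    ds = _paired_dataset(x, y)
    # textbook product-moment formula, written out independently
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    expected = sxy / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert pointwise_pearson(ds, 1.0) == pytest.approx(expected, rel=1e-12)


def test_pointwise_pearson_pairs_nearest_visit_within_window():
    # outcome grids differ: VA at 1.1 pairs with t=1.0 inside window 0.25
    rows = []
    for i in range(31):
        rows += [(f"s{i}", "MD", 1.0, float(i)), (f"s{i}", "VA", 1.1, float(2 * i))]
    obs = pd.DataFrame(rows, columns=["subject_id", "outcome", "time", "value"])
    ds = LongitudinalDataset.from_frames(obs, "MD", "VA")
    assert pointwise_pearson(ds, 1.0, window=0.25) == pytest.approx(1.0)
    assert pointwise_pearson(ds, 1.0, window=0.05) is None


# -- empirical bootstrap ---------------------------------------------------


def test_empirical_bootstrap_constant_estimator(small_homogeneous):
    res = empirical_bootstrap_ci(small_homogeneous, lambda ds: 0.42, B=25, seed=0)
    assert res.estimate == pytest.approx(0.42)
    assert res.ci == (pytest.approx(0.42), pytest.approx(0.42))
    assert not res.flagged


def test_empirical_bootstrap_deterministic_and_counts_failures(small_homogeneous):
    calls = {"n": 0}

    def estimator(ds):
        calls["n"] += 1
        if calls["n"] % 5 == 0:
            raise RuntimeError("unstable resample")
        return float(ds.obs["value"].mean())

    res = empirical_bootstrap_ci(small_homogeneous, estimator, B=20, seed=3)
    assert res.n_failed == 4 and res.n_effective == 16
    calls["n"] = 0
    res2 = empirical_bootstrap_ci(small_homogeneous, estimator, B=20, seed=3)
    assert res.estimate == res2.estimate and res.ci == res2.ci


def test_empirical_bootstrap_mean_stability_across_seeds(small_homogeneous):
    est = lambda ds: float(ds.obs.loc[ds.obs["outcome"] == "Y1", "value"].mean())
    a = empirical_bootstrap_ci(small_homogeneous, est, B=500, seed=1)
    b = empirical_bootstrap_ci(small_homogeneous, est, B=500, seed=2)
    assert abs(a.estimate - b.estimate) < 0.05
    assert abs(a.ci[0] - b.ci[0]) < 0.1 and abs(a.ci[1] - b.ci[1]) < 0.1
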