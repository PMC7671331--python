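"""Abundance-variance trend and empirical-Bayes variance shrinkage."""

import numpy as np
import pytest

from combi.variance import (GaussianVariances, feature_weighted_variance,
                            fit_abundance_variance_trend, poisson_trend,
                            shrink_variances_eb)


def test_weighted_variance_exact_fit_is_zero():
    x = np.array([[1.0, 2.0], [3.0, 4.0]])
    out = feature_weighted_variance(x, np.ones_like(x, bool), x, np.array([10.0, 20.0]))
    np.testing.assert_allclose(out, 0.0)


def test_weighted_variance_hand_example():
    # one feature, s = (1, 1), x = (0, 2), E = (1, 1): (1 + 1) / 1 = 2
    x = np.array([[0.0], [2.0]])
    E = np.ones_like(x)
    out = feature_weighted_variance(x, np.ones_like(x, bool), E, np.array([1.0, 1.0]))
    np.testing.assert_allclose(out, [2.0])


def test_weighted_variance_depth_linearity_and_small_n():
    rng = np.random.default_rng(0)
    x = rng.poisson(50.0, size=(6, 4)).astype(float)
    E = np.full_like(x, 50.0)
    s = np.full(6, 100.0)
    v1 = feature_weighted_variance(x, np.ones_like(x, bool), E, s)
    v2 = feature_weighted_variance(x, np.ones_like(x, bool), E, 2 * s)
    np.testing.assert_allclose(v2, v1 / 2.0)
    obs = np.ones_like(x, bool)
    obs[1:, 0] = False                      # feature 0 observed once
    v3 = feature_weighted_variance(x, obs, E, s)
    assert np.isnan(v3[0]) and np.isfinite(v3[1:]).all()


def test_poisson_simulated_trend_near_identity():
    rng = np.random.default_rng(42)
    n, p = 100, 500
    w = rng.lognormal(0.0, 2.0, p)
    pi = w / w.sum()
    s = np.full(n, 5.0e4)
    E = pi[None, :] * s[:, None]
    x = rng.poisson(E).astype(float)
    trend = fit_abundance_variance_trend(
        pi, feature_weighted_variance(x, np.ones_like(x, bool), E, s))
    grid = np.quantile(pi, np.linspace(0.02, 0.98, 30))
    ratio = trend.per_unit_variance(grid) / grid
    assert ratio.min() > 0.75 and ratio.max() < 1.25


def test_nb_trend_above_poisson_at_high_abundance():
    rng = np.random.default_rng(43)
    n, p, phi = 100, 500, 0.5
    w = rng.lognormal(0.0, 2.0, p)
    pi = w / w.sum()
    s = np.full(n, 5.0e4)
    E = pi[None, :] * s[:, None]
    r = 1.0 / phi
    x = rng.negative_binomial(r, r / (r + E)).astype(float)
    trend = fit_abundance_variance_trend(
        pi, feature_weighted_variance(x, np.ones_like(x, bool), E, s))
    hi = float(np.quantile(pi, 0.9))
    assert float(trend.per_unit_variance(np.array([hi]))[0]) / hi > 2.0


def test_trend_poisson_floor_and_low_abundance_rule():
    rng = np.random.default_rng(1)
    pi = np.sort(rng.dirichlet(np.ones(200)))
    var = pi * rng.uniform(0.2, 0.6, 200)       # artificially below the Poisson line
    trend = fit_abundance_variance_trend(pi, var)
    grid = np.linspace(pi.min(), pi.max(), 50)
    assert np.all(trend.per_unit_variance(grid) >= grid - 1e-15)
    below = np.array([trend.cutoff * 0.5])
    np.testing.assert_allclose(trend.per_unit_variance(below), below)


def test_trend_continuity_at_cutoff_and_range_boundary():
    rng = np.random.default_rng(2)
    w = rng.lognormal(0.0, 2.0, 300)
    pi = w / w.sum()
    var = pi * (1.0 + 30.0 * pi / pi.max()) * rng.lognormal(0.0, 0.2, 300)
    trend = fit_abundance_variance_trend(pi, var)
    c = trend.cutoff
    eps = 1e-9 * c
    lo, hi = trend.per_unit_variance(np.array([c - eps, c + eps]))
    assert abs(np.log(hi) - np.log(lo)) < 1e-3
    top = np.exp(trend.log_range[1])
    a, b = trend.per_unit_variance(np.array([top * 0.999, top * 1.001]))
    assert abs(np.log(a) - np.log(b)) < 0.05    # boundary-slope extrapolation


def test_trend_prediction_linear_in_depth_and_domain_errors():
    trend = poisson_trend()
    np.testing.assert_allclose(trend.predict(np.array([0.01]), 1000.0), [10.0])
    np.testing.assert_allclose(trend.predict(np.array([0.01]), 2000.0), [20.0])
    with pytest.raises(ValueError, match="inside"):
        trend.per_unit_variance(np.array([1.5]))
    with pytest.raises(ValueError, match="positive"):
        trend.predict(np.array([0.1]), -1.0)


def test_trend_fallback_with_few_features():
    with pytest.warns(UserWarning, match="Poisson"):
        trend = fit_abundance_variance_trend(np.array([0.2, 0.8]), np.array([0.1, 0.5]))
    assert trend.is_poisson


def test_shrinkage_plugin_example():
    gv = shrink_variances_eb([1.0, 4.0], [4, 4], prior_df=4, prior_var=2.0)
    np.testing.assert_allclose(gv.variances, [1.5, 3.0])


def test_shrinkage_equal_variances_unchanged():
    gv = shrink_variances_eb(np.full(20, 3.3), 7)
    np.testing.assert_allclose(gv.variances, 3.3, rtol=1e-6)


def test_shrinkage_infinite_prior_collapses():
    gv = shrink_variances_eb([1.0, 2.0, 4.0], 5, prior_df=np.inf, prior_var=2.0)
    np.testing.assert_allclose(gv.variances, 2.0)


def test_shrinkage_monotone_and_bracketing():
    rng = np.random.default_rng(3)
    true = rng.lognormal(0.7, 0.8, size=100)           # genuinely heterogeneous
    raw = rng.chisquare(6, size=100) / 6 * true
    gv = shrink_variances_eb(raw, 6)
    assert np.isfinite(gv.prior_df)
    order_raw = np.argsort(raw)
    assert np.array_equal(np.argsort(gv.variances), order_raw)
    lo = np.minimum(raw, gv.prior_var) - 1e-12
    hi = np.maximum(raw, gv.prior_var) + 1e-12
    assert np.all(gv.variances >= lo) and np.all(gv.variances <= hi)


def test_shrinkage_errors():
    with pytest.raises(ValueError, match="degenerate"):
        shrink_variances_eb([0.0, 0.0], 4)
    with pytest.raises(ValueError, match="df"):
        shrink_variances_eb([1.0, 2.0], 0.5)
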