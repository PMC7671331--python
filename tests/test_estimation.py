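"""The quasi-likelihood fitter: oracles, restrictions, robustness properties."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from combi import Combi, fit_combi
from combi.data import COUNT, GAUSSIAN, filter_features
from combi.estimation import FitOptions, fit_quasi_glm
from combi.simulate import simulate_from_latent, simulate_parametric, SimConfig
from combi.evaluate import pseudo_f

from conftest import filtered


def test_fit_options_validation():
    with pytest.raises(ValueError):
        FitOptions(M=0)
    with pytest.raises(ValueError):
        FitOptions(tol=-1.0)


def test_quasi_poisson_matches_glm_oracle():
    """Quasi-score solution with V = mu equals Poisson IRLS (statsmodels)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(1)
    n = 60
    z = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), z])
    s = rng.lognormal(8.0, 0.4, n)
    y = rng.poisson(np.exp(-7.0 + 0.4 * z) * s)
    b = fit_quasi_glm(y, X, offset=np.log(s))
    oracle = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(s)).fit().params
    np.testing.assert_allclose(b, oracle, atol=1e-6)


def test_quasi_glm_identity_is_ols():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((30, 3))
    y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(30)
    np.testing.assert_allclose(fit_quasi_glm(y, X, link="identity", variance="const"),
                               np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-10)


def test_single_gaussian_view_recovers_svd():
    views, Z, _ = simulate_from_latent(n=35, p=80, families=(GAUSSIAN,), M=1, seed=5)
    with pytest.warns(UserWarning, match="single-view"):
        res = fit_combi(views, dims=1)
    X = views[0].matrix - views[0].matrix.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    assert abs(np.corrcoef(res.Z[:, 0], U[:, 0])[0, 1]) > 0.999


def test_rank_one_noiseless_initialization_is_solution():
    rng = np.random.default_rng(8)
    z = rng.standard_normal(20)
    z -= z.mean()
    g = rng.standard_normal(15)
    X = 5.0 + np.outer(z, g)
    v = dataclasses.replace(
        simulate_from_latent(n=20, p=15, families=(GAUSSIAN,), M=1, seed=0)[0][0],
        matrix=X)
    with pytest.warns(UserWarning, match="single-view"):
        res = fit_combi([v], dims=1)
    assert res.convergence["dim1"]["iterations"] == 0
    assert abs(np.corrcoef(res.Z[:, 0], z)[0, 1]) > 1 - 1e-10


def test_determinism_identical_runs():
    views, _, _ = simulate_from_latent(n=20, p=(30, 25), seed=13)
    views = filtered(views)
    r1 = fit_combi(views, dims=2)
    r2 = fit_combi(views, dims=2)
    np.testing.assert_array_equal(r1.Z, r2.Z)
    for a, b in zip(r1.params, r2.params):
        np.testing.assert_array_equal(a.loadings, b.loadings)


def test_sequential_dimension_property(latent_views):
    """Dimension 1 of an M=2 fit is identical to the M=1 fit."""
    views, _, _ = latent_views
    r1 = fit_combi(views, dims=1)
    r2 = fit_combi(views, dims=2)
    np.testing.assert_allclose(r1.Z[:, 0], r2.Z[:, 0], atol=1e-8)
    for a, b in zip(r1.params, r2.params):
        np.testing.assert_allclose(a.loadings[0], b.loadings[0], atol=1e-8)


def _check_restrictions(res, tol=1e-6):
    ZtZ = res.Z.T @ res.Z
    off = ZtZ - np.diag(np.diag(ZtZ))
    if res.gradient is None:
        assert np.abs(off).max() < tol * max(1.0, np.diag(ZtZ).max())
        assert np.abs(res.Z.sum(axis=0)).max() < tol * max(1.0, np.abs(res.Z).max() * len(res.Z))
    for p in res.params:
        GOG = (p.loadings * p.weights) @ p.loadings.T
        np.testing.assert_allclose(GOG, np.eye(res.M), atol=1e-6)
    if res.gradient is not None:
        lam = res.gradient.Lambda
        np.testing.assert_allclose(lam.T @ lam, np.eye(res.M), atol=1e-6)
        for cols in res.gradient.blocks.values():
            np.testing.assert_allclose(lam[cols].sum(axis=0), 0.0, atol=1e-6)
        cont = [j for j in range(res.gradient.design.shape[1])
                if not any(j in c for c in res.gradient.blocks.values())]
        for j in cont:
            assert abs(res.gradient.design.iloc[:, j].std(ddof=1) - 1.0) < 1e-10
    for key, diag in res.convergence.items():
        assert diag["max_scaled_score"] < 100 * res.options.tol, (key, diag)


def test_restrictions_after_unconstrained_fit(latent_fit):
    _check_restrictions(latent_fit)


def test_parameter_recovery_small():
    views, Z, _ = simulate_from_latent(n=40, p=120, seed=3)
    res = fit_combi(filtered(views), dims=2)
    for m in range(2):
        assert abs(np.corrcoef(res.Z[:, m], Z[:, m])[0, 1]) > 0.9


def test_identical_gaussian_views_symmetric_loadings():
    views, _, _ = simulate_from_latent(n=25, p=40, families=(GAUSSIAN,), M=1, seed=6)
    twin = dataclasses.replace(views[0], name="twin")
    res = fit_combi([views[0], twin], dims=1)
    a = res.params[0].loadings[0]
    b = res.params[1].loadings[0]
    sign = np.sign(a @ b)
    np.testing.assert_allclose(a, sign * b, atol=1e-6)


def test_sign_convention_first_view_largest_loading_positive(latent_fit):
    for m in range(latent_fit.M):
        g = latent_fit.params[0].loadings[m]
        assert g[int(np.argmax(np.abs(g)))] > 0


def test_missing_data_mcar_robustness():
    rng = np.random.default_rng(0)
    views, _, _ = simulate_from_latent(n=30, p=(60, 50), seed=9)
    views = filtered(views)
    full = fit_combi(views, dims=1)
    masked = [dataclasses.replace(v, missing_mask=v.missing_mask | (rng.random(v.matrix.shape) < 0.10))
              for v in views]
    part = fit_combi(masked, dims=1)
    assert abs(np.corrcoef(full.Z[:, 0], part.Z[:, 0])[0, 1]) > 0.95


def test_depth_insensitivity_poisson_regime():
    """With a correctly specified (Poisson) variance, scaling one sample's
    counts tenfold moves its fitted score by less than 10%."""
    views, _, _ = simulate_from_latent(n=40, p=200, dispersion=1e-9, seed=9)
    views = filtered(views)
    full = fit_combi(views, dims=1)
    scaled = [dataclasses.replace(v, matrix=v.matrix.copy()) for v in views]
    for v in scaled:
        if v.family == COUNT:
            v.matrix[0] *= 10
    res = fit_combi(scaled, dims=1)
    sign = np.sign(np.corrcoef(full.Z[:, 0], res.Z[:, 0])[0, 1])
    assert abs(sign * res.Z[0, 0] - full.Z[0, 0]) < 0.10 * abs(full.Z[0, 0])


def test_confounder_adjustment_removes_group_effect():
    views, truth = simulate_parametric(SimConfig(p=150, seed=21))
    views = filtered(views)
    md = pd.DataFrame({"grp": truth.groups}, index=views[0].sample_ids)
    plain = fit_combi(views, dims=1)
    adj = Combi(views, metadata=md,
                confounders={"view1": ["grp"], "view2": ["grp"]}).fit(dims=1)
    f_plain = pseudo_f(plain.scores, truth.groups)
    f_adj = pseudo_f(adj.scores, truth.groups)
    assert f_plain > 50
    assert f_adj < 3.0          # inside the null band of an F statistic


def test_constrained_fit_recovers_known_gradient():
    rng = np.random.default_rng(0)
    views, Z, _ = simulate_from_latent(seed=4)
    views = filtered(views)
    md = pd.DataFrame({
        "grad1": Z[:, 0] + 0.1 * rng.standard_normal(40),
        "grad2": Z[:, 1] + 0.1 * rng.standard_normal(40),
        "noise": rng.standard_normal(40),
    }, index=views[0].sample_ids)
    res = Combi(views, metadata=md,
                constraint_vars=["grad1", "grad2", "noise"]).fit(dims=2)
    _check_restrictions(res)
    lam = np.abs(res.gradient.Lambda)
    assert lam[0, 0] > 0.95 and lam[1, 1] > 0.95 and lam[2, :].max() < 0.2


def test_constrained_fit_with_categorical_blocks():
    views, truth = simulate_parametric(SimConfig(n=30, p=(80, 60), seed=5))
    views = filtered(views)
    rng = np.random.default_rng(1)
    md = pd.DataFrame({"grp": truth.groups, "x": rng.standard_normal(30)},
                      index=views[0].sample_ids)
    res = Combi(views, metadata=md, constraint_vars=["grp", "x"]).fit(dims=2)
    _check_restrictions(res)


def test_metadata_required_for_constraints():
    views, _, _ = simulate_from_latent(n=20, p=(30, 30), seed=1)
    with pytest.raises(ValueError, match="metadata"):
        Combi(filtered(views), constraint_vars=["g"])


def test_summary_mentions_views_and_convergence(latent_fit):
    text = latent_fit.summary()
    assert "view1" in text and "converged" in text and "psi" in text
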