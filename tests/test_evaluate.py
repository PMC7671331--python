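"""Evaluation statistics: score-sum correlations, Wilcoxon z, pseudo-F."""

import numpy as np
import pytest

from combi.data import GAUSSIAN, ViewData
from combi.evaluate import (evaluation_report, pca_scores, pseudo_f,
                            score_sum_correlation, wilcoxon_inner_product_stat)
from combi.simulate import SimConfig, simulate_parametric


def _views_from(mats):
    return [ViewData(matrix=m, family=GAUSSIAN, name=f"v{i}") for i, m in enumerate(mats)]


def test_score_sum_correlation_exact_cases():
    rng = np.random.default_rng(0)
    X = rng.random((12, 5))
    views = _views_from([X])
    sums = X.sum(axis=1)
    perfect = score_sum_correlation(sums, views)
    np.testing.assert_allclose(perfect.loc["overall"], 1.0, atol=1e-12)
    orth = sums - sums.mean()
    z = rng.standard_normal(12)
    z -= z @ orth / (orth @ orth) * orth    # orthogonal to the centered sums
    np.testing.assert_allclose(score_sum_correlation(z, views).loc["overall"], 0.0,
                               atol=1e-10)


def test_score_sum_correlation_matches_direct_formula():
    rng = np.random.default_rng(5)
    X1, X2 = rng.random((10, 4)), rng.random((10, 6))
    Z = rng.standard_normal((10, 2))
    out = score_sum_correlation(Z, _views_from([X1, X2]))
    direct = np.corrcoef(Z[:, 1], X2.sum(axis=1))[0, 1]
    np.testing.assert_allclose(out.loc["v1", "dim2"], direct, atol=1e-12)


def test_score_sum_correlation_constant_warns_zero():
    views = _views_from([np.ones((6, 3))])
    with pytest.warns(UserWarning, match="constant"):
        out = score_sum_correlation(np.arange(6.0), views)
    assert (out.loc["overall"] == 0.0).all()


def test_wilcoxon_extreme_ranks_closed_form():
    """Three correlated pairs holding ranks {4,5,6} of six: z = 1.9640."""
    g = np.array([[1.0, 2.0, 3.0, 4.0]])
    ip = (g.T @ g)
    iu = np.triu_indices(4, 1)
    vals = ip[iu]
    lab = np.zeros((4, 4), bool)
    top3 = np.argsort(vals)[-3:]
    lab[iu[0][top3], iu[1][top3]] = True
    z = wilcoxon_inner_product_stat({"v": g}, {("v", "v"): lab | lab.T})
    assert abs(z - 1.9640) < 5e-5


def test_wilcoxon_all_equal_is_zero_midranks():
    g = np.ones((1, 5))
    lab = np.zeros((5, 5), bool)
    lab[0, 1] = lab[1, 0] = lab[2, 3] = lab[3, 2] = True
    assert wilcoxon_inner_product_stat({"v": g}, {("v", "v"): lab}) == 0.0


def test_wilcoxon_null_mean_near_zero():
    rng = np.random.default_rng(7)
    zs = []
    g = rng.standard_normal((2, 12))
    for _ in range(200):
        lab = np.zeros((12, 12), bool)
        iu = np.triu_indices(12, 1)
        pick = rng.choice(len(iu[0]), size=20, replace=False)
        lab[iu[0][pick], iu[1][pick]] = True
        zs.append(wilcoxon_inner_product_stat({"v": g}, {("v", "v"): lab | lab.T}))
        g = rng.standard_normal((2, 12))
    assert abs(np.mean(zs)) < 0.2


def test_wilcoxon_empty_group_errors():
    g = np.ones((1, 4))
    with pytest.raises(ValueError, match="empty"):
        wilcoxon_inner_product_stat({"v": g}, {("v", "v"): np.zeros((4, 4), bool)})


def test_wilcoxon_between_view_only():
    rng = np.random.default_rng(9)
    La, Lb = rng.standard_normal((2, 6)), rng.standard_normal((2, 8))
    lab = rng.random((6, 8)) < 0.3
    lab[0, 0] = True
    z1 = wilcoxon_inner_product_stat({"a": La, "b": Lb}, {("a", "b"): lab},
                                     between_view_only=True)
    assert np.isfinite(z1)


def test_pseudo_f_hand_toy_and_degenerate():
    z = np.array([0.0, 0.0, 2.0, 2.0])
    assert pseudo_f(z, ["A", "A", "B", "B"]) == np.inf


def test_pseudo_f_null_mean_near_one():
    rng = np.random.default_rng(11)
    labels = np.repeat(["a", "b"], 20)
    stats = [pseudo_f(rng.standard_normal((40, 2)), labels) for _ in range(500)]
    assert abs(np.mean(stats) - 1.0) < 0.15


def test_pseudo_f_matches_sklearn_oracle():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(12)
    Z = rng.standard_normal((30, 3))
    labels = rng.choice(["a", "b", "c"], 30)
    mine = pseudo_f(Z, labels)
    np.testing.assert_allclose(mine, sk.calinski_harabasz_score(Z, labels), rtol=1e-10)


def test_pseudo_f_permanova_form_agrees_for_euclidean():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova, DistanceMatrix
    from scipy.spatial.distance import pdist, squareform
    rng = np.random.default_rng(13)
    Z = rng.standard_normal((24, 2)) + np.repeat([0, 1.0], 12)[:, None]
    labels = np.repeat(["a", "b"], 12)
    mine = pseudo_f(Z, labels, method="permanova")
    np.testing.assert_allclose(mine, pseudo_f(Z, labels, method="calinski"), rtol=1e-10)
    dm = DistanceMatrix(squareform(pdist(Z)))
    ref = permanova(dm, grouping=list(labels), permutations=0)["test statistic"]
    np.testing.assert_allclose(mine, ref, rtol=1e-8)


def test_pseudo_f_errors():
    with pytest.raises(ValueError, match="two groups"):
        pseudo_f(np.arange(4.0), ["a"] * 4)
    with pytest.raises(ValueError, match="singleton"):
        pseudo_f(np.arange(4.0), ["a", "a", "a", "b"])


def test_evaluation_report_roundtrip(latent_fit):
    views, truth = simulate_parametric(SimConfig(n=20, p=(40, 30), seed=2))
    from conftest import filtered
    from combi import fit_combi
    res = fit_combi(filtered(views), dims=2)
    rep = evaluation_report(res, truth=truth, groups=truth.groups)
    d = rep.to_dict()
    assert np.isfinite(rep.wilcoxon_all) and np.isfinite(rep.wilcoxon_between)
    assert "pseudo_f" in d and "score_sum_correlations" in d
    assert (rep.score_sum_correlations.abs() <= 1.0 + 1e-12).all().all()


def test_pca_baseline_tracks_depth():
    views, _ = simulate_parametric(SimConfig(n=30, p=(100, 60), seed=4))
    Z = pca_scores(views, M=2)
    sums = np.where(views[0].observed, views[0].matrix, 0).sum(axis=1)
    assert abs(np.corrcoef(Z[:, 0], sums)[0, 1]) > 0.8
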