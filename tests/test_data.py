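"""View containers, alignment, feature filtering, design encoding, I/O."""

import numpy as np
import pandas as pd
import pytest

from combi.data import (COUNT, GAUSSIAN, ViewData, align_views, encode_design,
                        filter_features)
from combi.io import read_metadata, read_view
from combi.model import estimate_independence_model, mean_matrix


def test_viewdata_validates_counts():
    with pytest.raises(ValueError, match="non-negative integers"):
        ViewData(matrix=[[1.5, 2, 3], [1, 2, 3]], family=COUNT)
    with pytest.raises(ValueError, match="non-negative"):
        ViewData(matrix=[[-1, 2, 3], [1, 2, 3]], family=COUNT)
    v = ViewData(matrix=[[1, 2, 3], [4, 5, 6]], family=COUNT)
    assert v.n_samples == 2 and v.n_features == 3


def test_viewdata_nan_becomes_missing():
    v = ViewData(matrix=[[1.0, np.nan], [3.0, 4.0]], family=GAUSSIAN)
    assert v.missing_mask[0, 1] and not v.missing_mask[0, 0]


def test_align_views_union_and_all_missing_rows():
    a = ViewData(matrix=[[1, 2, 3], [4, 5, 6]], family=COUNT,
                 sample_ids=["s1", "s2"], name="a")
    b = ViewData(matrix=[[1.0, 2.0], [3.0, 4.0]], family=GAUSSIAN,
                 sample_ids=["s2", "s3"], name="b")
    aligned = align_views([a, b])
    assert aligned[0].sample_ids == aligned[1].sample_ids == ["s1", "s2", "s3"]
    assert aligned[0].missing_mask[2].all()      # s3 absent from view a
    assert aligned[1].missing_mask[0].all()      # s1 absent from view b


def test_align_views_disjoint_errors():
    a = ViewData(matrix=[[1, 2, 3]], family=COUNT, sample_ids=["s1"], name="a")
    b = ViewData(matrix=[[1.0, 2.0]], family=GAUSSIAN, sample_ids=["s9"], name="b")
    with pytest.raises(ValueError, match="no sample ids"):
        align_views([a, b])


def test_filter_features_removes_zero_totals():
    v = ViewData(matrix=[[0, 2, 3], [0, 5, 6]], family=COUNT, name="v")
    out = filter_features(v)
    assert out.n_features == 2 and out.feature_ids == v.feature_ids[1:]


def test_independence_model_counts():
    v = ViewData(matrix=[[10, 20, 70], [10, 20, 70]], family=COUNT)
    ind = estimate_independence_model(v)
    np.testing.assert_allclose(ind.pi_indep, [0.1, 0.2, 0.7])
    np.testing.assert_allclose(ind.depths, [100, 100])
    # equal counts everywhere -> zero clr offset
    v2 = ViewData(matrix=np.full((3, 4), 5.0), family=COUNT)
    np.testing.assert_allclose(estimate_independence_model(v2).offset, 0.0, atol=1e-12)


def test_independence_model_masked_cell_excluded():
    mat = np.array([[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]], dtype=float)
    mask = np.zeros_like(mat, dtype=bool)
    mask[0, 0] = True
    v = ViewData(matrix=mat, family=COUNT, missing_mask=mask)
    ind = estimate_independence_model(v)
    total = mat.sum() - 1
    np.testing.assert_allclose(ind.depths, [9, 26, 42])
    np.testing.assert_allclose(ind.pi_indep, [14 / total, 18 / total, 21 / total, 24 / total])


def test_independence_model_zero_feature_instructs_filter():
    v = ViewData(matrix=[[0, 2, 3], [0, 5, 6]], family=COUNT)
    with pytest.raises(ValueError, match="filter_features"):
        estimate_independence_model(v)


def test_encode_design_categorical_all_levels():
    md = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=list("wxyz"))
    design, blocks = encode_design(md, ["g"])
    np.testing.assert_array_equal(design.to_numpy(), [[1, 0], [1, 0], [0, 1], [0, 1]])
    assert blocks == {"g": [0, 1]}


def test_encode_design_continuous_centered_sd1():
    md = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}, index=list("wxyz"))
    design, blocks = encode_design(md, ["x"])
    np.testing.assert_allclose(design["x"], [-1.161895, -0.387298, 0.387298, 1.161895],
                               atol=1e-5)
    assert blocks == {}


def test_encode_design_three_level_one_hot():
    md = pd.DataFrame({"g": ["A", "B", "C", "A"]}, index=list("wxyz"))
    design, blocks = encode_design(md, ["g"])
    assert design.shape == (4, 3)
    np.testing.assert_array_equal(design.sum(axis=1), 1.0)


def test_encode_design_errors():
    md = pd.DataFrame({"c": [1.0, 1.0, 1.0], "g": ["A", "A", "A"]}, index=list("xyz"))
    with pytest.raises(ValueError, match="constant"):
        encode_design(md, ["c"])
    with pytest.raises(ValueError, match="single level"):
        encode_design(md, ["g"])
    with pytest.raises(KeyError):
        encode_design(md, ["absent"])


def test_mean_matrix_trivial_and_row_sums(latent_fit):
    res = latent_fit
    for v in res.views:
        i = res._view_index(v.name)
        mm0 = mean_matrix(v, res.independence[i], res.params[i],
                          np.zeros_like(res.Z), dims=0)
        if v.family == COUNT:
            expect = res.independence[i].pi_indep * res.independence[i].depths[:, None]
            np.testing.assert_allclose(mm0, expect, rtol=1e-10)
            mm = res.mean_matrix(v.name).to_numpy()
            np.testing.assert_allclose(mm.sum(axis=1), res.independence[i].depths, rtol=1e-10)
        else:
            np.testing.assert_allclose(mm0 - res.independence[i].offset[None, :], 0.0,
                                       atol=1e-10)


def test_gaussian_location_equivariance():
    from combi import fit_combi
    from combi.simulate import simulate_from_latent
    views, Z, _ = simulate_from_latent(n=20, p=(30, 30), families=(GAUSSIAN, GAUSSIAN),
                                       M=1, seed=5)
    res1 = fit_combi(views, dims=1)
    import dataclasses
    shifted = [views[0], dataclasses.replace(views[1], matrix=views[1].matrix + 11.0)]
    res2 = fit_combi(shifted, dims=1)
    np.testing.assert_allclose(res2.independence[1].offset,
                               res1.independence[1].offset + 11.0, atol=1e-8)
    np.testing.assert_allclose(res2.Z, res1.Z, atol=1e-6)
    np.testing.assert_allclose(res2.params[1].loadings, res1.params[1].loadings, atol=1e-6)


def test_view_tsv_roundtrip(tmp_path):
    mat = np.array([[1.0, np.nan, 3.5], [2.0, 4.0, np.nan]])
    v = ViewData(matrix=mat, family=GAUSSIAN, sample_ids=["a", "b"],
                 feature_ids=["f1", "f2", "f3"], name="x")
    v.to_dataframe().to_csv(tmp_path / "x.tsv", sep="\t")
    back = read_view(tmp_path / "x.tsv", family=GAUSSIAN)
    assert back.missing_mask[0, 1] and back.missing_mask[1, 2]
    np.testing.assert_allclose(back.matrix[~back.missing_mask], mat[~np.isnan(mat)])


def test_read_metadata_string_index(tmp_path):
    pd.DataFrame({"g": ["A", "B"]}, index=[1, 2]).to_csv(tmp_path / "m.tsv", sep="\t")
    md = read_metadata(tmp_path / "m.tsv")
    assert list(md.index) == ["1", "2"]
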