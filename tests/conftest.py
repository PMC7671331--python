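import numpy as np
import pytest

from combi import Combi, fit_combi
from combi.data import COUNT, filter_features
from combi.simulate import simulate_from_latent


def filtered(views):
    return [filter_features(v) if v.family == COUNT else v for v in views]


@pytest.fixture(scope="session")
def latent_views():
    """Small two-view dataset drawn from the model with known structure."""
    views, Z, loadings = simulate_from_latent(n=30, p=(60, 50), seed=11)
    return filtered(views), Z, loadings


@pytest.fixture(scope="session")
def latent_fit(latent_views):
    views, Z, loadings = latent_views
    res = fit_combi(views, dims=2)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def count_fit():
    """Single count view fit, used by the compositional-identity tests."""
    views, Z, loadings = simulate_from_latent(n=24, p=40, families=(COUNT,), M=2, seed=7)
    with pytest.warns(UserWarning, match="single-view"):
        res = fit_combi(filtered(views), dims=2)
    assert res.converged
    return res
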