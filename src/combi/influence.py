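"""Influence of individual observations on the fitted latent structure.

Because the model is defined through explicit estimating equations, the
influence of a single cell (sample i, feature j) on an estimate follows the
M-estimator influence function: minus the inverse Jacobian of the solved
estimating function times that cell's contribution.  For the latent score
``Z_im`` the equation is per-sample (a sum over the view's features), so
the Jacobian is a scalar per sample; for the environmental gradient it is
the d x d matrix of the stacked equations.  Jacobians are analytic for
gaussian views (identity link, constant variance) and numerical (central
differences) for count views, where the softmax makes closed forms
error-prone.  A masked cell contributes nothing and has influence exactly 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import COUNT
from .estimation import _ViewState, _score_scores

__all__ = ["influence_on_scores", "influence_on_gradient", "view_influence_summary"]

_REL_STEP = 1e-6


def _require_converged(results):
    if not results.converged:
        raise ValueError("influence requires a converged fit; refit with more iterations")


def _states(results) -> list[_ViewState]:
    out = []
    for i, view in enumerate(results.views):
        p = results.params[i]
        st = _ViewState(view, results.independence[i], R=p.confounder_design,
                        conf_blocks=p.confounder_blocks)
        if p.confounder_coefs is not None:
            st.Phi = p.confounder_coefs
        st.G = p.loadings
        st.Omega = p.weights
        if view.family == COUNT:
            st.trend = results.variance_models[i]
        else:
            st.gvar = results.variance_models[i]
        out.append(st)
    return out


def _cell_contributions(st: _ViewState, Z: np.ndarray, m: int):
    """Per-cell contribution to the score equation of dimension m (n x p)."""
    pi, E, V, r = st.quantities(st.eta(Z))
    gm = st.G[m - 1]
    if st.family == COUNT:
        g = pi @ gm
        dEdz = st.s[:, None] * pi * (gm[None, :] - g[:, None])
        return np.where(st.obs, dEdz * r, 0.0)
    return np.where(st.obs, r * gm[None, :], 0.0)


def _score_jacobian(st: _ViewState, Z: np.ndarray, m: int) -> np.ndarray:
    """dU_i/dZ_im per sample: analytic (gaussian) or central differences (count)."""
    if st.family != COUNT:
        return -(st.obs @ (st.G[m - 1] ** 2 / st.gvar.variances))
    h = _REL_STEP * np.maximum(1.0, np.abs(Z[:, m - 1]))
    up, dn = Z.copy(), Z.copy()
    up[:, m - 1] += h
    dn[:, m - 1] -= h
    gm = st.G[m - 1]

    def total(Zx):
        pi, E, V, r = st.quantities(st.eta(Zx))
        return _score_scores(st, pi, V, r, gm)[0]

    return (total(up) - total(dn)) / (2.0 * h)


def influence_on_scores(results, view, dimension: int = 1) -> pd.DataFrame:
    """Influence of every cell of ``view`` on the sample scores of ``dimension``.

    Long-format frame with columns sample, feature, influence; the influence
    of cell (i, j) acts on that sample's own score ``Z_i,dim``.
    """
    _require_converged(results)
    if not 1 <= dimension <= results.M:
        raise ValueError(f"dimension must be in 1..{results.M}")
    states = _states(results)
    idx = results._view_index(view)
    Z = results.Z
    J = np.zeros(Z.shape[0])
    for st in states:
        J += _score_jacobian(st, Z, dimension)
    st = states[idx]
    contrib = _cell_contributions(st, Z, dimension)
    infl = -contrib / J[:, None]
    v = results.views[idx]
    return pd.DataFrame({
        "view": v.name,
        "sample": np.repeat(v.sample_ids, v.n_features),
        "feature": np.tile(v.feature_ids, v.n_samples),
        "dimension": dimension,
        "influence": infl.ravel(),
    })


def influence_on_gradient(results, view, dimension: int = 1) -> pd.DataFrame:
    """Influence of every cell on the environmental-gradient loadings.

    Constrained fits only.  The stacked gradient equation is
    ``c' U(Z) = 0`` with ``Z = c w``; the influence of cell (i, j) on the
    gradient component k is ``[-(c' J c)^{-1} c_i']_k`` times the cell's
    contribution.  Long format with a ``component`` column.
    """
    _require_converged(results)
    if results.gradient is None:
        raise ValueError("gradient influence requires a constrained fit")
    states = _states(results)
    idx = results._view_index(view)
    Z = results.Z
    c = results.gradient.design.to_numpy(dtype=float)
    J = np.zeros(Z.shape[0])
    for st in states:
        J += _score_jacobian(st, Z, dimension)
    Jw = (c * J[:, None]).T @ c
    Minv = -np.linalg.pinv(Jw) @ c.T          # (d, n)
    st = states[idx]
    contrib = _cell_contributions(st, Z, dimension)   # (n, p)
    v = results.views[idx]
    comps = results.gradient.design.columns
    rows = []
    for k, comp in enumerate(comps):
        infl = Minv[k][:, None] * contrib
        rows.append(pd.DataFrame({
            "view": v.name,
            "component": comp,
            "sample": np.repeat(v.sample_ids, v.n_features),
            "feature": np.tile(v.feature_ids, v.n_samples),
            "dimension": dimension,
            "influence": infl.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)


def view_influence_summary(results, dimension: int = 1) -> pd.DataFrame:
    """Per-view, per-sample total absolute influence on the latent scores.

    The view-level contribution is the sum of absolute cell influences over
    the view's features — the quantity shown as boxplots of log absolute
    influence in view-comparison diagnostics.
    """
    parts = []
    for v in results.views:
        tab = influence_on_scores(results, v.name, dimension)
        agg = tab.groupby("sample", sort=False)["influence"].apply(lambda s: np.abs(s).sum())
        parts.append(pd.DataFrame({"view": v.name, "sample": agg.index,
                                   "total_abs_influence": agg.to_numpy()}))
    return pd.concat(parts, ignore_index=True)
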