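"""The COMBI latent-variable model: containers, mean models, Model/Results API.

COMBI integrates several omics views measured on the same samples through a
set of view-specific mean models that share low-dimensional latent sample
scores ``Z``::

    g_x[E(X | Z)] = U_x + R Phi + Z Gamma        (one equation per view)

with a centered log-ratio link and multiplicative sequencing depths for
compositional count views, and an identity link for gaussian views.  The
offsets ``U_x`` define the *independence model* in which every sample has
the same feature composition and differs only by depth.  Identifiability
restrictions: ``Z' Z`` diagonal with centered columns, loadings orthonormal
in a view-specific weighted inner product ``Gamma Omega Gamma' = I``, and in
a constrained analysis ``Z = c Lambda`` with orthonormal environmental
gradients and zero-sum dummy blocks.

Usage follows the statsmodels pattern: build a :class:`Combi` model from
:class:`~combi.data.ViewData` objects, call :meth:`Combi.fit`, and work with
the returned :class:`CombiResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import clr, clr_inverse
from .data import COUNT, GAUSSIAN, ViewData, align_views, encode_design

__all__ = [
    "IndependenceModel",
    "ViewParams",
    "EnvironmentalGradient",
    "estimate_independence_model",
    "build_eta",
    "mean_from_eta",
    "mean_matrix",
    "Combi",
    "CombiResults",
    "fit_combi",
]


@dataclass
class IndependenceModel:
    """Baseline model: identical composition in every sample, free depths.

    For count views ``pi_indep`` holds the pooled feature proportions,
    ``depths`` the per-sample observed totals (treated as fixed ancillary
    constants) and ``offset = clr(pi_indep)``.  For gaussian views the
    offset is the vector of per-feature observed means and depths are 1.
    """

    offset: np.ndarray
    depths: np.ndarray
    pi_indep: np.ndarray | None = None


@dataclass
class ViewParams:
    """Fitted per-view parameters: loadings, Omega weights, confounder terms."""

    loadings: np.ndarray                      # (M, p)
    weights: np.ndarray                       # diagonal of Omega, length p
    confounder_coefs: np.ndarray | None = None   # (d_R, p)
    confounder_design: np.ndarray | None = None  # (n, d_R)
    confounder_blocks: dict = field(default_factory=dict)


@dataclass
class EnvironmentalGradient:
    """Constrained-fit gradient: ``Z = design @ Lambda @ diag(scale)``."""

    Lambda: np.ndarray          # (d, M), orthonormal columns
    design: pd.DataFrame        # (n, d)
    blocks: dict                # categorical variable -> column positions
    scale: np.ndarray           # (M,) positive per-dimension strengths

    def scores(self) -> np.ndarray:
        return self.design.to_numpy(dtype=float) @ (self.Lambda * self.scale)


def estimate_independence_model(view: ViewData) -> IndependenceModel:
    """Estimate the independence model of one view from observed cells.

    Count views: depths are per-sample observed totals and ``pi_indep`` the
    per-feature totals over the grand total; a feature with zero observed
    total has an unidentifiable clr parameter and raises (apply
    :func:`combi.data.filter_features` first).
    """
    if view.n_samples < 2 or view.n_features < 3:
        raise ValueError("independence model needs >= 2 samples and >= 3 features")
    obs = view.observed
    filled = np.where(obs, view.matrix, 0.0)
    if view.family == COUNT:
        depths = filled.sum(axis=1)
        if np.any(depths <= 0):
            # all-missing rows carry no information; give them the mean depth
            pos = depths > 0
            if not pos.any():
                raise ValueError("view has no observed counts")
            depths = np.where(pos, depths, depths[pos].mean())
        totals = filled.sum(axis=0)
        if np.any(totals <= 0):
            bad = [view.feature_ids[j] for j in np.flatnonzero(totals <= 0)][:5]
            raise ValueError(
                f"features with zero total count in view {view.name!r}: {bad} ...; "
                "remove them with combi.data.filter_features(view) before fitting"
            )
        pi = totals / totals.sum()
        return IndependenceModel(offset=clr(pi), depths=depths, pi_indep=pi)
    means = np.where(obs.any(axis=0), filled.sum(axis=0) / np.maximum(obs.sum(axis=0), 1), 0.0)
    return IndependenceModel(offset=means, depths=np.ones(view.n_samples), pi_indep=None)


def build_eta(offset: np.ndarray, confounder_design, confounder_coefs,
              Z: np.ndarray | None, loadings: np.ndarray | None, dims: int | None = None,
              n: int | None = None) -> np.ndarray:
    """Linear predictor ``U + R Phi + Z_{1..m} Gamma_{1..m}`` (single code path)."""
    if n is None:
        n = Z.shape[0] if Z is not None else confounder_design.shape[0]
    eta = np.tile(np.asarray(offset, dtype=float), (n, 1))
    if confounder_design is not None and confounder_coefs is not None:
        eta = eta + np.asarray(confounder_design, float) @ confounder_coefs
    if Z is not None and loadings is not None:
        m = Z.shape[1] if dims is None else int(dims)
        if m > Z.shape[1]:
            raise ValueError(f"requested {m} dimensions but only {Z.shape[1]} fitted")
        if m:
            eta = eta + Z[:, :m] @ loadings[:m]
    return eta


def mean_from_eta(family: str, eta: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Map the linear predictor to expected values (clr link or identity)."""
    if family == COUNT:
        return clr_inverse(eta) * np.asarray(depths, float)[:, None]
    return eta


def mean_matrix(view: ViewData, indep: IndependenceModel, params: ViewParams,
                Z: np.ndarray, dims: int | None = None) -> np.ndarray:
    """Expected values under the first ``dims`` latent dimensions (Eq. mean model)."""
    eta = build_eta(indep.offset, params.confounder_design, params.confounder_coefs,
                    Z, params.loadings, dims=dims, n=view.n_samples)
    return mean_from_eta(view.family, eta, indep.depths)


class Combi:
    """Model-based integration of compositional and gaussian omics views.

    Parameters
    ----------
    views
        List of :class:`ViewData` sharing sample ids (aligned on the union).
    metadata
        Sample metadata table indexed by sample id; required for constrained
        or confounder-adjusted fits.
    constraint_vars
        Variables defining the constrained analysis (``Z = c Lambda``).
    confounders
        Mapping ``view name -> list of variables`` whose effect is removed by
        conditioning before the latent variables are estimated.
    weights
        Optional per-view override of the Omega diagonal.
    """

    def __init__(self, views, metadata: pd.DataFrame | None = None,
                 constraint_vars: list[str] | None = None,
                 confounders: dict[str, list[str]] | None = None,
                 weights: dict[str, np.ndarray] | None = None):
        if isinstance(views, ViewData):
            views = [views]
        names = [v.name for v in views]
        if len(set(names)) != len(names):
            raise ValueError("view names must be unique")
        if len(views) == 1:
            warnings.warn("single-view analysis: integration reduces to a one-view ordination")
        self.views = align_views(list(views))
        self.sample_ids = self.views[0].sample_ids
        self.metadata = metadata
        self.constraint_vars = list(constraint_vars) if constraint_vars else None
        self.confounders = dict(confounders) if confounders else {}
        self.weights = dict(weights) if weights else {}
        if (self.constraint_vars or self.confounders) and metadata is None:
            raise ValueError("metadata is required for constrained or confounder-adjusted fits")
        if metadata is not None:
            missing = [s for s in self.sample_ids if s not in metadata.index.astype(str)]
            if missing:
                raise ValueError(f"metadata lacks samples: {missing[:5]}")
            self.metadata = metadata.copy()
            self.metadata.index = metadata.index.astype(str)
            self.metadata = self.metadata.loc[self.sample_ids]

    def fit(self, dims: int = 2, tol: float = 1e-6, max_iter: int = 1000,
            max_trend_iter: int = 5, seed: int = 0, max_step: float = 1.0) -> "CombiResults":
        """Fit the model dimension by dimension; returns :class:`CombiResults`."""
        from .estimation import FitOptions, fit_model
        mode = "constrained" if self.constraint_vars else "unconstrained"
        opts = FitOptions(M=int(dims), tol=float(tol), max_iter=int(max_iter),
                          max_trend_iter=int(max_trend_iter), seed=int(seed),
                          mode=mode, max_step=float(max_step))
        return fit_model(self, opts)


@dataclass
class CombiResults:
    """Fitted COMBI model: scores, per-view parameters, variance models.

    ``Z`` holds the latent sample scores (constrained fits: the metavariable
    scores ``c Lambda diag(scale)``); ``psi`` the diagonal of ``Z'Z``.
    ``convergence`` carries per-dimension iteration counts, parameter deltas
    and the Fisher-scaled projected quasi-scores at the solution.
    """

    model: Combi
    independence: list
    params: list
    variance_models: list
    Z: np.ndarray
    psi: np.ndarray
    gradient: EnvironmentalGradient | None
    M: int
    convergence: dict
    options: object

    # -- convenient accessors -------------------------------------------------
    @property
    def views(self):
        return self.model.views

    @property
    def view_names(self):
        return [v.name for v in self.model.views]

    def _view_index(self, view) -> int:
        if isinstance(view, int):
            return view
        try:
            return self.view_names.index(view)
        except ValueError:
            raise KeyError(f"unknown view {view!r}; have {self.view_names}") from None

    @property
    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.model.sample_ids,
                            columns=[f"dim{m + 1}" for m in range(self.M)])

    def loadings(self, view) -> pd.DataFrame:
        i = self._view_index(view)
        return pd.DataFrame(self.params[i].loadings,
                            index=[f"dim{m + 1}" for m in range(self.M)],
                            columns=self.model.views[i].feature_ids)

    def mean_matrix(self, view, dims: int | None = None) -> pd.DataFrame:
        i = self._view_index(view)
        v = self.model.views[i]
        mm = mean_matrix(v, self.independence[i], self.params[i], self.Z, dims=dims)
        return pd.DataFrame(mm, index=v.sample_ids, columns=v.feature_ids)

    @property
    def converged(self) -> bool:
        return all(d.get("converged", False) for d in self.convergence.values())

    # -- diagnostics and downstream analyses ----------------------------------
    def influence_on_scores(self, view, dimension: int = 1) -> pd.DataFrame:
        from .influence import influence_on_scores
        return influence_on_scores(self, view, dimension)

    def influence_on_gradient(self, view, dimension: int = 1) -> pd.DataFrame:
        from .influence import influence_on_gradient
        return influence_on_gradient(self, view, dimension)

    def multiplot_coordinates(self, dims=(1, 2), threshold=("top", 15)):
        from .viz import multiplot_coordinates
        return multiplot_coordinates(self, dims=dims, threshold=threshold)

    def plot(self, dims=(1, 2), threshold=("top", 15), **kwargs):
        from .viz import multiplot_coordinates, plot_multiplot
        return plot_multiplot(multiplot_coordinates(self, dims=dims, threshold=threshold),
                              metadata=self.model.metadata, **kwargs)

    def save(self, path):
        from .io import save_fit
        save_fit(self, path)

    def summary(self) -> str:
        """Human-readable summary table (statsmodels flavour)."""
        lines = []
        mode = "constrained" if self.gradient is not None else "unconstrained"
        lines.append("COMBI integration results".center(64))
        lines.append("=" * 64)
        lines.append(f"{'Views:':<22}{len(self.views)}   mode: {mode}")
        lines.append(f"{'Samples:':<22}{self.Z.shape[0]}")
        lines.append(f"{'Dimensions:':<22}{self.M}")
        psi_label = "psi (Z'Z diagonal):"
        lines.append(f"{psi_label:<22}" + "  ".join(f"{p:.4g}" for p in self.psi))
        lines.append("-" * 64)
        lines.append(f"{'view':<16}{'family':<22}{'features':>9}{'missing %':>11}")
        for v in self.views:
            miss = 100.0 * v.missing_mask.mean()
            lines.append(f"{v.name:<16}{v.family:<22}{v.n_features:>9}{miss:>10.1f}%")
        lines.append("-" * 64)
        for key, d in self.convergence.items():
            lines.append(
                f"{key:<12} iterations {d['iterations']:>4}   "
                f"max |step| {d['max_scaled_score']:.2e}   "
                f"{'converged' if d['converged'] else 'NOT converged'}"
            )
        if self.gradient is not None:
            lines.append("-" * 64)
            lines.append("environmental gradient (Lambda):")
            lam = pd.DataFrame(self.gradient.Lambda, index=self.gradient.design.columns,
                               columns=[f"dim{m + 1}" for m in range(self.M)])
            lines.append(lam.round(4).to_string())
        lines.append("=" * 64)
        return "\n".join(lines)


def fit_combi(views, dims: int = 2, metadata=None, constraint_vars=None,
              confounders=None, weights=None, **fit_kwargs) -> CombiResults:
    """One-call interface: build a :class:`Combi` model and fit it."""
    return Combi(views, metadata=metadata, constraint_vars=constraint_vars,
                 confounders=confounders, weights=weights).fit(dims=dims, **fit_kwargs)
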