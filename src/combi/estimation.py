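"""Sequential quasi-likelihood estimation of the COMBI model.

The estimating equations have the generic form

    sum over observed cells  (dE/dkappa) (x - E) / V[E]  =  0,

with ``V`` the abundance-variance trend times depth for count views and the
empirical-Bayes shrunken feature variance for gaussian views.  Missing cells
contribute nothing.  Dimensions are fitted one at a time and frozen, so the
estimates of lower dimensions never depend on how many dimensions are
requested.  Within a dimension the solver alternates Fisher-scoring block
updates of (a) the shared scores (or the environmental gradient), and
(b) each view's loading row, re-imposing the identifiability restrictions
(centering, orthogonality, weighted normalization, zero-sum dummy blocks)
by projection after every pass and re-estimating the variance models during
the first passes.  Identifiability constraints are handled by elimination
inside the Newton step, so at a fixed point the *projected* estimating
functions vanish; the reported "quasi-score" diagnostic is the Fisher-scaled
projected score, i.e. the length of the Newton step in parameter units, and
is comparable to the parameter-change tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .compositional import clr, clr_inverse
from .data import COUNT, GAUSSIAN
from .model import (CombiResults, EnvironmentalGradient, IndependenceModel, ViewParams,
                    build_eta, encode_design, estimate_independence_model, mean_from_eta)
from .variance import (feature_weighted_variance, fit_abundance_variance_trend,
                       poisson_trend, shrink_variances_eb)

__all__ = ["FitOptions", "fit_model", "fit_quasi_glm", "quasi_score"]

_FLOOR = 1e-12


@dataclass
class FitOptions:
    """Tuning knobs of the fitting algorithm (artifact plumbing, not science)."""

    M: int = 2
    tol: float = 1e-6
    max_iter: int = 1000
    max_trend_iter: int = 5
    seed: int = 0
    mode: str = "unconstrained"
    max_step: float = 1.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


# --------------------------------------------------------------------------
# per-view fitting state

class _ViewState:
    def __init__(self, view, indep: IndependenceModel, R=None, conf_blocks=None):
        self.view = view
        self.name = view.name
        self.family = view.family
        self.obs = view.observed
        self.X = np.where(self.obs, view.matrix, 0.0)
        self.indep = indep
        self.s = indep.depths
        self.u = indep.offset
        self.R = R
        self.conf_blocks = conf_blocks or {}
        self.Phi = None if R is None else np.zeros((R.shape[1], view.n_features))
        self.G = np.zeros((0, view.n_features))
        self.trend = poisson_trend() if view.family == COUNT else None
        self.gvar = None
        self.Omega = None

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def eta(self, Z: np.ndarray) -> np.ndarray:
        return build_eta(self.u, self.R, self.Phi, Z, self.G[: Z.shape[1]] if Z.shape[1] else None,
                         n=self.X.shape[0])

    def quantities(self, eta: np.ndarray):
        """Proportions, expected values, variances and weighted residuals."""
        if self.family == COUNT:
            pi = clr_inverse(eta)
            E = pi * self.s[:, None]
            V = self.trend.predict(pi, self.s)
        else:
            pi = None
            E = eta
            V = np.broadcast_to(self.gvar.variances, E.shape)
        r = np.where(self.obs, (self.X - E) / V, 0.0)
        return pi, E, V, r


# --------------------------------------------------------------------------
# quasi-score building blocks

def _score_scores(st: _ViewState, pi, V, r, gm: np.ndarray):
    """Estimating function and Fisher information for the per-sample scores."""
    if st.family == COUNT:
        g = pi @ gm
        C = np.where(st.obs, pi * (gm[None, :] - g[:, None]), 0.0)
        U = st.s * (r * C).sum(axis=1)
        D = st.s**2 * (C * C / V).sum(axis=1)
    else:
        U = r @ gm
        D = st.obs @ (gm**2 / st.gvar.variances)
    return U, D


def _score_loadings(st: _ViewState, pi, V, r, z: np.ndarray):
    """Estimating function and Fisher information for one loading row."""
    if st.family == COUNT:
        rho = (pi * r).sum(axis=1)            # residual pushed through the softmax
        zs = z * st.s
        U = (zs[:, None] * pi * (r - rho[:, None])).sum(axis=0)
        A = np.where(st.obs, pi * pi / V, 0.0).sum(axis=1)
        D = ((zs**2)[:, None] * pi**2
             * (np.where(st.obs, (1.0 - 2.0 * pi) / V, 0.0) + A[:, None])).sum(axis=0)
    else:
        U = (z[:, None] * r).sum(axis=0)
        D = ((z**2)[:, None] * (st.obs / st.gvar.variances)).sum(axis=0)
    return U, np.maximum(D, _FLOOR)


def quasi_score(view_state_or_results, *, what: str = "scores", dimension: int = 1,
                Z: np.ndarray | None = None):
    """Evaluate the raw estimating functions of a fitted model.

    For ``what="scores"`` returns the per-sample estimating function of the
    requested dimension summed over the view's features; for
    ``what="loadings"`` the per-feature function.  Intended for diagnostics
    and tests; the fitter uses the same building blocks internally.
    """
    from .model import CombiResults as _CR
    if isinstance(view_state_or_results, _ViewState):
        st = view_state_or_results
        if Z is None:
            raise ValueError("Z required with a raw view state")
    else:
        raise TypeError("pass a _ViewState; CombiResults expose scores via convergence diagnostics")
    m = dimension
    pi, E, V, r = st.quantities(st.eta(Z))
    if what == "scores":
        return _score_scores(st, pi, V, r, st.G[m - 1])[0]
    if what == "loadings":
        return _score_loadings(st, pi, V, r, Z[:, m - 1])[0]
    raise ValueError("what must be 'scores' or 'loadings'")


# --------------------------------------------------------------------------
# constrained Newton steps (constraints eliminated inside the step)

def _project_out(B: np.ndarray | None, v: np.ndarray) -> np.ndarray:
    if B is None or B.shape[1] == 0:
        return v
    coef, *_ = np.linalg.lstsq(B, v, rcond=None)
    return v - B @ coef


def _step_diag(U: np.ndarray, D: np.ndarray, B: np.ndarray | None, cap: float | None):
    """Newton step for a diagonal Fisher information under linear constraints.

    Solves ``P D delta = P U`` with ``B' delta = 0`` (P the projector onto
    the orthogonal complement of span(B)) by elimination.
    """
    D = np.maximum(D, _FLOOR * max(float(D.max(initial=0.0)), _FLOOR))
    Dinv = 1.0 / D
    if B is not None and B.shape[1]:
        M = B.T @ (B * Dinv[:, None])
        rhs = B.T @ (U * Dinv)
        mu = np.linalg.lstsq(M, rhs, rcond=None)[0]
        step = Dinv * (U - B @ mu)
    else:
        step = Dinv * U
    if cap is not None:
        step = np.clip(step, -cap, cap)
    return step


def _step_dense(U: np.ndarray, J: np.ndarray, B: np.ndarray | None, cap: float | None):
    d = U.shape[0]
    J = J + np.eye(d) * _FLOOR * max(float(np.trace(J)) / max(d, 1), _FLOOR)
    JiU = np.linalg.solve(J, U)
    if B is not None and B.shape[1]:
        JiB = np.linalg.solve(J, B)
        mu = np.linalg.lstsq(B.T @ JiB, B.T @ JiU, rcond=None)[0]
        step = JiU - JiB @ mu
    else:
        step = JiU
    if cap is not None:
        step = np.clip(step, -cap, cap)
    return step


# --------------------------------------------------------------------------
# the fitter

class _Fitter:
    def __init__(self, states: list[_ViewState], opts: FitOptions,
                 design: np.ndarray | None = None, blocks: dict | None = None):
        self.states = states
        self.opts = opts
        self.n = states[0].X.shape[0]
        self.design = design
        self.blocks = blocks or {}
        self.Z = np.zeros((self.n, 0))
        self.Lambda = None if design is None else np.zeros((design.shape[1], 0))
        self.scale: list[float] = []
        self.convergence: dict = {}
        # current-dimension working variables
        self._z = np.zeros(self.n)
        self._w = None
        self._prev_steps: dict = {}
        self._relax: dict = {}

    # -- variance models ------------------------------------------------------
    def _update_variance_models(self, Zall: np.ndarray) -> float:
        """Re-estimate trends / shrunken variances; return max relative change."""
        rel = 0.0
        ncol = Zall.shape[1]
        for st in self.states:
            eta = st.eta(Zall)
            E = mean_from_eta(st.family, eta, st.s)
            if st.family == COUNT:
                wvar = feature_weighted_variance(st.view.matrix, st.obs, E, st.s)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    new = fit_abundance_variance_trend(st.indep.pi_indep, wvar)
                grid = np.quantile(st.indep.pi_indep, np.linspace(0.02, 0.98, 25))
                old_v = st.trend.per_unit_variance(grid)
                new_v = new.per_unit_variance(grid)
                rel = max(rel, float(np.max(np.abs(new_v / old_v - 1.0))))
                st.trend = new
            else:
                res = np.where(st.obs, st.X - E, 0.0)
                nj = st.obs.sum(axis=0)
                k = ncol + (0 if st.R is None else st.R.shape[1])
                dfj = np.maximum(nj - 1 - k, 1)
                raw = (res**2).sum(axis=0) / dfj
                if np.all(raw <= _FLOOR):
                    continue  # numerically perfect fit: keep previous variances
                new = shrink_variances_eb(raw, dfj)
                new.variances = np.maximum(new.variances, _FLOOR)
                if st.gvar is not None:
                    rel = max(rel, float(np.max(np.abs(new.variances / st.gvar.variances - 1.0))))
                else:
                    rel = np.inf
                st.gvar = new
        return rel

    def _setup(self):
        # dimension-0 variance models, then Omega (frozen afterwards)
        self._update_variance_models(self.Z)
        for st in self.states:
            name = st.name
            if st.Omega is not None:
                continue
            if st.family == COUNT:
                w = st.indep.pi_indep.copy()
            else:
                w = 1.0 / st.gvar.variances
            st.Omega = w * (st.p / w.sum())
        # confounders are conditioned on before any latent dimension
        for st in self.states:
            if st.R is not None:
                self._fit_confounders(st)
        # variance models under the confounder-adjusted model
        self._update_variance_models(self.Z)

    # -- confounder pre-conditioning ------------------------------------------
    def _fit_confounders(self, st: _ViewState, max_iter: int = 500):
        """Estimate Phi by quasi-score before any latent dimension.

        With the independence offset frozen, Phi is fully identified (the
        no-reference dummy design has full column rank and the model carries
        no free intercept); the only freedom is the softmax gauge of count
        views — one constant per design column — which is pinned by
        feature-centering each coefficient row.
        """
        opts = self.opts
        ones = np.ones((st.p, 1)) if st.family == COUNT else None
        stable = False
        for it in range(max_iter):
            updated = False
            if it < opts.max_trend_iter and not stable:
                rel = self._update_variance_models(self.Z)
                stable = rel < 0.01
                updated = not stable
            old = st.Phi.copy()
            for k in range(st.R.shape[1]):
                pi, E, V, r = st.quantities(st.eta(self.Z))
                U, D = _score_loadings(st, pi, V, r, st.R[:, k])
                step = self._damp(("phi", st.name, k), _step_diag(U, D, ones, opts.max_step))
                st.Phi[k] += step
            if st.family == COUNT:
                st.Phi -= st.Phi.mean(axis=1, keepdims=True)
            delta = float(np.max(np.abs(st.Phi - old)))
            if delta < opts.tol and not updated:
                return
        warnings.warn(f"confounder fit for view {st.name!r} did not fully converge")

    # -- initialization --------------------------------------------------------
    def _initialize_dimension(self, m: int):
        """Deterministic start from the top singular pair of working residuals."""
        blocks, scales, slices = [], [], []
        col = 0
        for st in self.states:
            eta = st.eta(self.Z)
            if st.family == COUNT:
                work = clr((st.X + 0.5) / st.s[:, None])
                pred = eta - eta.mean(axis=1, keepdims=True)
            else:
                work = st.X
                pred = eta
            resid = np.where(st.obs, work - pred, 0.0)
            nobs = max(int(st.obs.sum()), 1)
            sc = float(np.sqrt((resid**2).sum() / nobs))
            sc = sc if sc > 0 else 1.0
            blocks.append(resid / sc)
            scales.append(sc)
            slices.append(slice(col, col + st.p))
            col += st.p
        W = np.hstack(blocks)
        Bc = np.hstack([np.ones((self.n, 1)), self.Z])
        W = W - Bc @ np.linalg.lstsq(Bc, W, rcond=None)[0]
        U_, S_, Vt_ = np.linalg.svd(W, full_matrices=False)
        z = U_[:, 0]
        norms = []
        for st, sc, sl in zip(self.states, scales, slices):
            g = S_[0] * Vt_[0, sl] * sc
            if st.family == COUNT:
                g = g - g.mean()
            g = self._orthogonalize_loadings(st, g, m)
            c = float(np.sqrt(max(g @ (st.Omega * g), _FLOOR)))
            st.G = np.vstack([st.G, g / c])
            norms.append(c)
        z = z * float(np.exp(np.mean(np.log(norms))))
        if self.design is not None:
            Bw = self._gradient_constraints()
            w, *_ = np.linalg.lstsq(self.design, z, rcond=None)
            w = _project_out(Bw, w)
            if np.linalg.norm(w) < 1e-10:
                rng = np.random.default_rng(self.opts.seed + m)
                w = _project_out(Bw, rng.standard_normal(w.shape))
            self._w = w
            self._z = self.design @ w
        else:
            self._w = None
            self._z = z

    def _orthogonalize_loadings(self, st: _ViewState, g: np.ndarray, m: int) -> np.ndarray:
        for l in range(m - 1):
            prev = st.G[l]
            g = g - (g @ (st.Omega * prev)) / (prev @ (st.Omega * prev)) * prev
        return g

    def _gradient_constraints(self) -> np.ndarray | None:
        cols = []
        d = self.design.shape[1]
        for positions in self.blocks.values():
            v = np.zeros(d)
            v[positions] = 1.0
            cols.append(v)
        if self.Lambda is not None and self.Lambda.shape[1]:
            cols.extend(self.Lambda.T)
        return np.column_stack(cols) if cols else None

    def _score_constraints(self) -> np.ndarray:
        return np.hstack([np.ones((self.n, 1)), self.Z])

    def _loading_constraints(self, st: _ViewState, m: int) -> np.ndarray:
        """Constraint gradients for a loading-row update.

        Rows 1..m in the Omega inner product (orthogonality plus the
        linearized normalization), and for count views the ones vector: the
        softmax is invariant to a constant shift of a loading row, so that
        direction carries no information and is fixed to zero mean.
        """
        B = (st.G[:m] * st.Omega).T
        if st.family == COUNT:
            B = np.hstack([np.ones((st.p, 1)), B])
        return B

    def _damp(self, key, step: np.ndarray) -> np.ndarray:
        """Halve a block's step when it reverses against the previous pass.

        The diagonal Fisher approximation ignores the softmax's cross-feature
        coupling in count views, which can turn the alternating updates into
        a two-cycle; direction-reversal damping restores contraction without
        slowing the well-behaved blocks.
        """
        prev = self._prev_steps.get(key)
        relax, streak = self._relax.get(key, (1.0, 0))
        if prev is not None and prev.shape == step.shape and float(prev @ step) < 0.0:
            relax, streak = max(0.2, 0.6 * relax), 0
        else:
            streak += 1
            if streak >= 10:             # long aligned run: ease the brake off
                relax, streak = min(1.0, 1.25 * relax), 0
        self._relax[key] = (relax, streak)
        step = relax * step
        self._prev_steps[key] = step.copy()
        return step

    # -- one alternating pass ---------------------------------------------------
    def _pass(self, m: int, cap: float | None):
        opts = self.opts
        z_old = self._z.copy()
        G_old = [st.G[m - 1].copy() for st in self.states]
        Zall = np.hstack([self.Z, self._z[:, None]])

        # (a) shared scores / environmental gradient
        U = np.zeros(self.n)
        D = np.zeros(self.n)
        for st in self.states:
            pi, E, V, r = st.quantities(st.eta(Zall))
            u_v, d_v = _score_scores(st, pi, V, r, st.G[m - 1])
            U += u_v
            D += d_v
        if self.design is None:
            B = self._score_constraints()
            step = self._damp("z", _step_diag(U, D, B, cap))
            self._z = _project_out(B, self._z + step)
        else:
            Bw = self._gradient_constraints()
            Uw = self.design.T @ U
            Jw = (self.design * D[:, None]).T @ self.design
            step = self._damp("w", _step_dense(Uw, Jw, Bw, cap))
            self._w = _project_out(Bw, self._w + step)
            self._z = self.design @ self._w
        Zall = np.hstack([self.Z, self._z[:, None]])

        # (b) loading rows, view by view; the normalization constraint is
        # linearized inside the step (its gradient is Omega * Gamma_m), so
        # the update moves tangent to the norm sphere and the shared score
        # equation alone determines the scale of z
        for st in self.states:
            pi, E, V, r = st.quantities(st.eta(Zall))
            U_j, D_j = _score_loadings(st, pi, V, r, self._z)
            Bj = self._loading_constraints(st, m)
            step = self._damp(("g", st.name), _step_diag(U_j, D_j, Bj, cap))
            st.G[m - 1] = st.G[m - 1] + step

        # (c) re-impose the restrictions exactly (second-order corrections)
        for st in self.states:
            g = st.G[m - 1]
            if st.family == COUNT:
                g = g - g.mean()          # softmax shift invariance: pin the gauge
            g = self._orthogonalize_loadings(st, g, m)
            c = float(np.sqrt(max(g @ (st.Omega * g), _FLOOR)))
            st.G[m - 1] = g / c

        delta = float(np.max(np.abs(self._z - z_old)))
        for st, g0 in zip(self.states, G_old):
            delta = max(delta, float(np.max(np.abs(st.G[m - 1] - g0))))
        return delta

    # -- final diagnostics ------------------------------------------------------
    def _diagnostics(self, m: int) -> dict:
        Zall = np.hstack([self.Z, self._z[:, None]])
        U = np.zeros(self.n)
        D = np.zeros(self.n)
        per_view = {}
        for st in self.states:
            pi, E, V, r = st.quantities(st.eta(Zall))
            u_v, d_v = _score_scores(st, pi, V, r, st.G[m - 1])
            U += u_v
            D += d_v
            U_j, D_j = _score_loadings(st, pi, V, r, self._z)
            Bj = self._loading_constraints(st, m)  # includes the scale direction of row m
            per_view[st.name] = float(np.max(np.abs(_step_diag(U_j, D_j, Bj, None))))
        if self.design is None:
            zscore = float(np.max(np.abs(_step_diag(U, D, self._score_constraints(), None))))
        else:
            Bw = self._gradient_constraints()
            Uw = self.design.T @ U
            Jw = (self.design * D[:, None]).T @ self.design
            zscore = float(np.max(np.abs(_step_dense(Uw, Jw, Bw, None))))
        return {"score_scores": zscore, "score_loadings": per_view,
                "max_scaled_score": max([zscore] + list(per_view.values()))}

    # -- main loops -------------------------------------------------------------
    def fit_dimension(self, m: int) -> bool:
        """Fit dimension ``m``; returns False when the dimension is degenerate."""
        opts = self.opts
        self._initialize_dimension(m)
        stable = False
        it = 0
        converged = False
        delta = np.inf
        for it in range(opts.max_iter):
            updated = False
            if it < opts.max_trend_iter and not stable:
                rel = self._update_variance_models(np.hstack([self.Z, self._z[:, None]]))
                stable = rel < 0.01
                updated = rel >= 0.01
            delta = self._pass(m, opts.max_step)
            if not np.isfinite(delta):
                raise FloatingPointError(f"non-finite update in dimension {m}")
            if delta < opts.tol and not updated:
                converged = True
                break
        psi_m = float(self._z @ self._z)
        if psi_m < 1e-10:
            warnings.warn(f"dimension {m} is degenerate (psi ~ 0); stopping early")
            for st in self.states:
                st.G = st.G[: m - 1]
            return False
        # sign convention: largest-|loading| entry of the first view positive
        g1 = self.states[0].G[m - 1]
        if g1[int(np.argmax(np.abs(g1)))] < 0:
            for st in self.states:
                st.G[m - 1] = -st.G[m - 1]
            self._z = -self._z
            if self._w is not None:
                self._w = -self._w
        diag = self._diagnostics(m)
        diag.update({"iterations": it, "converged": converged, "delta": delta, "psi": psi_m})
        if not converged:
            warnings.warn(f"dimension {m} did not converge in {opts.max_iter} iterations "
                          f"(last delta {delta:.3g})")
        self.convergence[f"dim{m}"] = diag
        self.Z = np.hstack([self.Z, self._z[:, None]])
        if self.design is not None:
            a = float(np.linalg.norm(self._w))
            self.Lambda = np.hstack([self.Lambda, (self._w / a)[:, None]])
            self.scale.append(a)
        return True

    def run(self) -> None:
        self._setup()
        for m in range(1, self.opts.M + 1):
            if not self.fit_dimension(m):
                break


# --------------------------------------------------------------------------
# public entry point

def fit_model(model, opts: FitOptions) -> CombiResults:
    """Fit a :class:`combi.model.Combi` description; used by ``Combi.fit``."""
    states = []
    for view in model.views:
        indep = estimate_independence_model(view)
        R, blocks = None, {}
        if view.name in model.confounders:
            dframe, blocks = encode_design(model.metadata, model.confounders[view.name])
            R = dframe.to_numpy(dtype=float)
        st = _ViewState(view, indep, R=R, conf_blocks=blocks)
        if view.name in model.weights:
            w = np.asarray(model.weights[view.name], dtype=float)
            if w.shape != (view.n_features,) or np.any(w <= 0):
                raise ValueError(f"weights for view {view.name!r} must be positive, length p")
            st.Omega = w * (view.n_features / w.sum())
        states.append(st)

    design_frame, dblocks = None, {}
    design = None
    if model.constraint_vars:
        design_frame, dblocks = encode_design(model.metadata, model.constraint_vars)
        design = design_frame.to_numpy(dtype=float)

    fitter = _Fitter(states, opts, design=design, blocks=dblocks)
    fitter.run()

    M = fitter.Z.shape[1]
    params = [
        ViewParams(loadings=st.G.copy(), weights=st.Omega.copy(),
                   confounder_coefs=None if st.Phi is None else st.Phi.copy(),
                   confounder_design=st.R, confounder_blocks=st.conf_blocks)
        for st in states
    ]
    variance_models = [st.trend if st.family == COUNT else st.gvar for st in states]
    gradient = None
    if design is not None:
        gradient = EnvironmentalGradient(Lambda=fitter.Lambda, design=design_frame,
                                         blocks=dblocks, scale=np.asarray(fitter.scale))
    return CombiResults(
        model=model,
        independence=[st.indep for st in states],
        params=params,
        variance_models=variance_models,
        Z=fitter.Z,
        psi=np.asarray([fitter.Z[:, m] @ fitter.Z[:, m] for m in range(M)]),
        gradient=gradient,
        M=M,
        convergence=fitter.convergence,
        options=opts,
    )


# --------------------------------------------------------------------------
# generic single-outcome quasi-likelihood fit (the estimating equations of
# one feature in isolation; useful for diagnostics and as a bridge to
# classical GLMs)

def fit_quasi_glm(y, X, offset=None, link: str = "log", variance: str = "mu",
                  tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Solve ``sum_i (dE/db)(y - E)/V = 0`` for a single outcome vector.

    ``link="log", variance="mu"`` reproduces quasi-Poisson (and hence
    Poisson) estimates; ``link="identity", variance="const"`` reproduces
    ordinary least squares.  Fisher scoring with analytic weights.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, q = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if link == "identity" and variance == "const":
        b, *_ = np.linalg.lstsq(X, y - off, rcond=None)
        return b
    if link != "log" or variance != "mu":
        raise ValueError("supported: (log, mu) and (identity, const)")
    mu = np.maximum(y, 0.5)
    b = np.linalg.lstsq(X, np.log(mu) - off, rcond=None)[0]
    for _ in range(max_iter):
        eta = X @ b + off
        mu = np.exp(np.clip(eta, -700, 700))
        score = X.T @ (y - mu)                 # (dmu/db)(y-mu)/mu
        info = (X * mu[:, None]).T @ X
        step = np.linalg.solve(info, score)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    return b
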