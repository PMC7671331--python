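"""Variance models: the abundance-variance trend and empirical-Bayes shrinkage.

Count views get a nonparametric trend ``v_m`` mapping a feature's modelled
relative abundance to its per-depth-unit variance,
``Var(X_ij) = v_m(pi_ij) * s_i``.  The trend is a cubic smoothing spline on
the log-log scale (smoothing chosen by generalized cross-validation), with
two restrictions taken from the Poisson variance model ``Var = mean``:
below a low-abundance cutoff the trend *is* the Poisson line, and everywhere
the prediction is floored at it — the variance can never drop below the
mean.  Gaussian views instead get per-feature variances shrunken towards a
common value by the standard empirical-Bayes squeeze (moment matching of
scaled F-distributed sample variances on the log scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = [
    "VarianceTrend",
    "GaussianVariances",
    "feature_weighted_variance",
    "fit_abundance_variance_trend",
    "poisson_trend",
    "shrink_variances_eb",
]


@dataclass
class VarianceTrend:
    """Smooth map from modelled relative abundance to per-depth-unit variance.

    ``spline`` operates on ``log(pi) -> log(variance)``; ``None`` encodes the
    pure Poisson fallback ``v(pi) = pi``.  ``cutoff`` is the low-abundance
    threshold below which the prediction is exactly the Poisson line, and
    ``shift`` anchors the spline to that line at the cutoff so the trend is
    continuous.  Outside the fitted range the spline is extended linearly
    with its boundary slope.
    """

    spline: BSpline | None = None
    cutoff: float = 0.0
    shift: float = 0.0
    log_range: tuple[float, float] = (0.0, 0.0)

    def _spline_eval(self, logpi: np.ndarray) -> np.ndarray:
        lo, hi = self.log_range
        x = np.clip(logpi, lo, hi)
        y = self.spline(x)
        d = self.spline.derivative()
        below, above = logpi < lo, logpi > hi
        if np.any(below):
            y = np.where(below, self.spline(lo) + d(lo) * (logpi - lo), y)
        if np.any(above):
            y = np.where(above, self.spline(hi) + d(hi) * (logpi - hi), y)
        return y

    def per_unit_variance(self, pi: np.ndarray) -> np.ndarray:
        """``v(pi)``: variance per unit of sequencing depth."""
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("modelled proportions must lie strictly inside (0, 1)")
        if self.spline is None:
            return pi.copy()
        out = pi.copy()
        high = pi >= self.cutoff
        if np.any(high):
            logv = self._spline_eval(np.log(pi[high])) - self.shift
            out[high] = np.maximum(np.exp(logv), pi[high])
        return out

    def predict(self, pi: np.ndarray, s) -> np.ndarray:
        """Predicted variance ``v(pi) * s`` (linear in the depth ``s``)."""
        s = np.asarray(s, dtype=float)
        if np.any(s <= 0):
            raise ValueError("depths must be strictly positive")
        v = self.per_unit_variance(pi)
        if s.ndim == 1 and np.ndim(pi) == 2:
            return v * s[:, None]
        return v * s

    @property
    def is_poisson(self) -> bool:
        return self.spline is None


def poisson_trend() -> VarianceTrend:
    """The pure Poisson trend ``v(pi) = pi``."""
    return VarianceTrend(spline=None)


def feature_weighted_variance(x: np.ndarray, observed: np.ndarray, expected: np.ndarray,
                              depths: np.ndarray) -> np.ndarray:
    """Feature-wise depth-weighted variances of counts around the model mean.

    ``Var_j = sum_i (x_ij - E_ij)^2 / s_i / (n_j - 1)`` over observed cells,
    with ``n_j`` the number of observed cells of feature j.  Features with
    fewer than two observations get NaN and are excluded from trend fitting.
    """
    x = np.asarray(x, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    contrib = np.where(observed, (np.where(observed, x, 0.0) - expected) ** 2, 0.0)
    contrib = contrib / np.asarray(depths, dtype=float)[:, None]
    n_j = observed.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = contrib.sum(axis=0) / (n_j - 1)
    out[n_j < 2] = np.nan
    return out


def fit_abundance_variance_trend(pi_indep: np.ndarray, variances: np.ndarray,
                                 low_quantile: float = 0.10,
                                 min_features: int = 10) -> VarianceTrend:
    """Fit the abundance-variance trend from per-feature weighted variances.

    A cubic smoothing spline of log variance on log independence-model
    abundance, fitted to features above the ``low_quantile`` abundance
    quantile; smoothing is selected by generalized cross-validation.  The
    spline is anchored to the Poisson line at the cutoff (continuity) and
    predictions are floored at ``v(pi) = pi``.  With fewer than
    ``min_features`` usable features the pure Poisson trend is returned with
    a warning.
    """
    pi_indep = np.asarray(pi_indep, dtype=float)
    variances = np.asarray(variances, dtype=float)
    ok = np.isfinite(variances) & (variances > 0) & (pi_indep > 0)
    if ok.sum() < min_features:
        warnings.warn(
            f"only {int(ok.sum())} features with usable variances; falling back to the Poisson trend"
        )
        return poisson_trend()
    cutoff = float(np.quantile(pi_indep[ok], low_quantile))
    use = ok & (pi_indep >= cutoff)
    x = np.log(pi_indep[use])
    y = np.log(variances[use])
    order = np.argsort(x)
    x, y = x[order], y[order]
    # collapse duplicate abscissae (make_smoothing_spline needs strict increase)
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < x.size:
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        x, y = ux, uy
    if x.size < 4:
        warnings.warn("too few distinct abundances for a spline; falling back to the Poisson trend")
        return poisson_trend()
    spline = make_smoothing_spline(x, y)  # GCV-selected smoothing
    logcut = np.log(cutoff)
    shift = float(spline(max(logcut, x[0])) - logcut)
    return VarianceTrend(spline=spline, cutoff=cutoff, shift=shift,
                         log_range=(float(x[0]), float(x[-1])))


@dataclass
class GaussianVariances:
    """Per-feature variances shrunken towards a common prior.

    ``posterior_j = (d0 * s0^2 + d_j * s_j^2) / (d0 + d_j)``; ``d0`` and
    ``s0^2`` come from moment matching of the log sample variances (the
    standard squeeze procedure).  Infinite prior df collapses every feature
    to ``s0^2``.
    """

    variances: np.ndarray
    prior_var: float
    prior_df: float
    raw: np.ndarray | None = None


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma, standard starting value 1/y + 0.5-ish
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def shrink_variances_eb(raw_variances: np.ndarray, df, prior_df: float | None = None,
                        prior_var: float | None = None) -> GaussianVariances:
    """Empirical-Bayes squeeze of per-feature sample variances.

    Parameters
    ----------
    raw_variances
        Per-feature residual variances ``s_j^2``.
    df
        Residual degrees of freedom per feature (scalar or vector), >= 1.
    prior_df, prior_var
        Optional explicit prior; when omitted both are estimated by moment
        matching on the log variances.
    """
    s2 = np.asarray(raw_variances, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    if np.any(d < 1):
        raise ValueError("residual df must be >= 1 for every feature")
    if np.all(s2 <= 0):
        raise ValueError("all raw variances are zero: degenerate view")
    if prior_df is None or prior_var is None:
        pos = s2 > 0
        z = np.log(s2[pos])
        dg = d[pos]
        e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
        emean = e.mean()
        if prior_df is None:
            evar = e.var(ddof=1) - np.mean(special.polygamma(1, dg / 2.0)) if e.size > 1 else 0.0
            prior_df = 2.0 * _trigamma_inverse(evar) if evar > 0 else np.inf
        if prior_var is None:
            if np.isfinite(prior_df):
                prior_var = float(np.exp(emean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0)))
            else:
                # no detectable spread beyond sampling noise: collapse to the
                # (geometric) common value so identical inputs stay identical
                prior_var = float(np.exp(np.mean(z)))
    if np.isfinite(prior_df):
        post = (prior_df * prior_var + d * s2) / (prior_df + d)
    else:
        post = np.full_like(s2, prior_var)
    return GaussianVariances(variances=post, prior_var=float(prior_var),
                             prior_df=float(prior_df), raw=s2)
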