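"""Aitchison-geometry primitives for compositional data.

A *composition* is a vector of strictly positive proportions summing to one;
sequence count data only carry compositional information.  The centered
log-ratio transform (clr) maps compositions to the zero-sum hyperplane of
real space; its inverse is the softmax.  The perturbation operator ``⊕`` is
the compositional analogue of addition.  All functions operate on the last
axis, so matrices of row-wise compositions are handled transparently.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "clr",
    "clr_inverse",
    "perturb",
    "power",
    "composition_chain",
    "check_composition",
    "check_clr",
]


def check_composition(x: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Validate that ``x`` is a composition: strictly positive, sums to 1."""
    x = np.asarray(x, dtype=float)
    if not np.all(x > 0):
        idx = np.argwhere(~(x > 0)).ravel()
        raise ValueError(f"composition entries must be strictly positive; offending index {idx[0]}")
    total = x.sum(axis=-1)
    if not np.allclose(total, 1.0, atol=tol, rtol=0):
        raise ValueError(f"composition entries must sum to 1 (got {np.atleast_1d(total)[0]!r})")
    return x


def check_clr(y: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Validate that ``y`` lies on the clr (zero-sum) hyperplane."""
    y = np.asarray(y, dtype=float)
    total = y.sum(axis=-1)
    if not np.allclose(total, 0.0, atol=tol, rtol=0):
        raise ValueError(f"clr vector entries must sum to 0 (got {np.atleast_1d(total)[0]!r})")
    return y


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform: ``log(x_j / g(x))`` with ``g`` the geometric mean.

    ``x`` need not sum to one (the transform is scale invariant), but every
    entry must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    bad = ~(x > 0) | ~np.isfinite(x)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise ValueError(f"clr requires strictly positive finite entries; offending index {tuple(idx)}")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def clr_inverse(y: np.ndarray) -> np.ndarray:
    """Inverse clr (softmax): ``exp(y_j) / sum_k exp(y_k)``.

    Shift invariant; computed with max-subtraction so linear predictors with
    magnitude beyond ~700 do not overflow.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        idx = np.argwhere(~np.isfinite(y))[0]
        raise ValueError(f"clr_inverse requires finite entries; offending index {tuple(idx)}")
    z = y - y.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def perturb(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Aitchison perturbation ``u ⊕ v``: entrywise product, renormalized.

    ``u`` must be a composition, ``v`` a strictly positive vector of the same
    length.  The result is again a composition.
    """
    u = check_composition(u)
    v = np.asarray(v, dtype=float)
    if u.shape[-1] != v.shape[-1]:
        raise ValueError(f"length mismatch: {u.shape[-1]} vs {v.shape[-1]}")
    if not np.all(v > 0):
        idx = np.argwhere(~(v > 0)).ravel()
        raise ValueError(f"perturbation vector must be strictly positive; offending index {idx[0]}")
    w = u * v
    return w / w.sum(axis=-1, keepdims=True)


def power(u: np.ndarray, a: float) -> np.ndarray:
    """Entrywise powering of a strictly positive vector (compositional scaling)."""
    u = np.asarray(u, dtype=float)
    if not np.all(u > 0):
        raise ValueError("powering requires strictly positive entries")
    return u**a


def composition_chain(u_x: np.ndarray, loadings: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Build a sample's composition by perturbing the independence composition.

    Each latent dimension ``m`` perturbs the composition with direction
    ``clr_inverse(loadings[m])`` raised to the sample score ``z[m]``::

        pi = clr_inverse(u_x) ⊕ clr_inverse(G_1)^z_1 ⊕ ... ⊕ clr_inverse(G_M)^z_M

    which is algebraically identical to ``clr_inverse(u_x + z @ loadings)``.
    The chain form is computed literally here; the identity is exercised in
    the test-suite.
    """
    u_x = np.asarray(u_x, dtype=float)
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if loadings.shape[0] != z.shape[0]:
        raise ValueError(f"dimension mismatch: {loadings.shape[0]} loading rows vs {z.shape[0]} scores")
    if loadings.shape[1] != u_x.shape[-1]:
        raise ValueError(f"dimension mismatch: {loadings.shape[1]} features vs {u_x.shape[-1]}")
    pi = clr_inverse(u_x)
    for m in range(z.shape[0]):
        pi = perturb(pi, power(clr_inverse(loadings[m]), z[m]))
    return pi
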