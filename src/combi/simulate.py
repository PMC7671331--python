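"""Synthetic multi-omics generators with ground truth for evaluation.

Two generation strategies are provided.  The *parametric* generator draws
negative-binomial count views and gaussian views for two equally sized
sample groups, introduces a fold change for a fraction of the features in
the second group (optionally with compositional compensation so the
remaining features' expected relative abundances are unchanged), and emits
the ground truth needed by the evaluation statistics.  The *permutation*
generator independently reshuffles the samples of each view, destroying all
cross-view correlation while preserving each view's marginal content — a
null setting with realistic single-view structure.

A third generator, :func:`simulate_from_latent`, draws data directly from
the fitted model form (known scores and loadings) for parameter-recovery
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compositional import clr, clr_inverse
from .data import COUNT, GAUSSIAN, ViewData

__all__ = ["SimConfig", "SimulationTruth", "simulate_parametric", "permute_views",
           "simulate_from_latent"]


@dataclass
class SimConfig:
    """Study conditions for the parametric generator.

    Defaults reproduce the benchmark conditions: n = 40 samples in two equal
    groups, p = 1000 features per view, 10% differentially abundant features,
    fold change 4 for count views and 0.1 (multiplicative, factor 1.1) for
    gaussian views.  Feature-level parameters are drawn from configurable
    parametric pools: log-normal mean abundances, gamma negative-binomial
    dispersions (mean 0.5), log-normal sequencing depths.
    """

    n: int = 40
    p: int | tuple = 1000
    families: tuple = (COUNT, GAUSSIAN)
    da_fraction: float = 0.10
    fold_change_count: float = 4.0
    fold_change_gaussian: float = 0.1
    compensation: bool = True
    nb_mean_pool: dict = field(default_factory=lambda: {"logmean": 0.0, "logsd": 2.0})
    nb_dispersion_pool: dict = field(default_factory=lambda: {"shape": 2.0, "scale": 0.25})
    gaussian_mean_pool: dict = field(default_factory=lambda: {"mean": 10.0, "sd": 2.0})
    gaussian_sd_pool: dict = field(default_factory=lambda: {"logmean": -0.7, "logsd": 0.4})
    depth: dict = field(default_factory=lambda: {"mean": 2.0e4, "logsd": 0.5})
    seed: int | None = None

    def __post_init__(self):
        if self.n % 2:
            raise ValueError("n must be even (two equally sized groups)")
        if not 0.0 < self.da_fraction < 1.0:
            raise ValueError("da_fraction must lie in (0, 1)")
        for key in ("shape", "scale"):
            if self.nb_dispersion_pool[key] <= 0:
                raise ValueError("invalid negative-binomial dispersion pool")
        if self.depth["mean"] <= 0:
            raise ValueError("invalid depth distribution")

    def p_for(self, k: int) -> int:
        return self.p[k] if isinstance(self.p, (tuple, list)) else self.p


@dataclass
class SimulationTruth:
    """Ground truth emitted by the parametric generator.

    ``features[view]`` holds per-feature DA flags, the applied fold change
    and the direction of the response (+1 up, -1 down, 0 unaffected).
    *Correlated pairs* are pairs of DA features that respond to the group
    signal in the same direction — within one view or across views.
    """

    groups: np.ndarray
    features: dict[str, pd.DataFrame]

    def directions(self, view: str) -> np.ndarray:
        return self.features[view]["direction"].to_numpy()

    def pair_labels(self, view_a: str, view_b: str) -> np.ndarray:
        """Boolean matrix: entry (i, j) True when the pair is truly correlated."""
        da_ = self.directions(view_a)
        db_ = self.directions(view_b)
        return (da_[:, None] == db_[None, :]) & (da_[:, None] != 0)

    def correlated_pairs(self, view_a: str, view_b: str) -> list[tuple[str, str]]:
        lab = self.pair_labels(view_a, view_b)
        fa = self.features[view_a].index
        fb = self.features[view_b].index
        ii, jj = np.nonzero(np.triu(lab, 1) if view_a == view_b else lab)
        return [(fa[i], fb[j]) for i, j in zip(ii, jj)]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, df in self.features.items():
            part = df.copy()
            part.insert(0, "view", name)
            part.insert(1, "feature", df.index)
            parts.append(part.reset_index(drop=True))
        return pd.concat(parts, ignore_index=True)


def _group_means_count(rng, p, cfg: SimConfig):
    w = rng.lognormal(cfg.nb_mean_pool["logmean"], cfg.nb_mean_pool["logsd"], size=p)
    n_da = round(cfg.da_fraction * p)
    da = rng.choice(p, size=n_da, replace=False)
    fc = np.ones(p)
    direction = np.zeros(p, dtype=int)
    f = cfg.fold_change_count
    if cfg.compensation:
        # the larger-mean half is pushed down by the factor that keeps the
        # total expected abundance equal across groups, so the remaining
        # features' relative abundances are unaltered
        order = da[np.argsort(w[da])]
        up = order[: n_da // 2]
        down = order[n_da // 2:]
        d = 1.0 - (f - 1.0) * w[up].sum() / w[down].sum()
        if d <= 0:
            raise ValueError("compensation infeasible: down-set total too small")
        fc[up] = f
        fc[down] = d
        direction[up] = 1
        direction[down] = -1
    else:
        fc[da] = f
        direction[da] = 1
    return w, w * fc, fc, direction


def _simulate_count_view(rng, name, p, cfg: SimConfig, groups):
    w1, w2, fc, direction = _group_means_count(rng, p, cfg)
    pi1 = w1 / w1.sum()
    pi2 = w2 / w2.sum()
    mu_depth = cfg.depth["mean"]
    sig = cfg.depth["logsd"]
    s = rng.lognormal(np.log(mu_depth) - sig**2 / 2.0, sig, size=cfg.n)
    phi = rng.gamma(cfg.nb_dispersion_pool["shape"], cfg.nb_dispersion_pool["scale"], size=p)
    mu = np.where(groups[:, None] == 0, pi1[None, :], pi2[None, :]) * s[:, None]
    counts = np.empty((cfg.n, p))
    small = phi < 1e-8
    if small.any():
        counts[:, small] = rng.poisson(mu[:, small])
    nb = ~small
    r = 1.0 / phi[nb]
    counts[:, nb] = rng.negative_binomial(r[None, :], r[None, :] / (r[None, :] + mu[:, nb]))
    view = ViewData(matrix=counts, family=COUNT, name=name,
                    feature_ids=[f"{name}_f{j:04d}" for j in range(p)])
    truth = pd.DataFrame({"da": direction != 0, "fold_change": fc, "direction": direction},
                         index=view.feature_ids)
    return view, truth


def _simulate_gaussian_view(rng, name, p, cfg: SimConfig, groups):
    m = rng.normal(cfg.gaussian_mean_pool["mean"], cfg.gaussian_mean_pool["sd"], size=p)
    sd = rng.lognormal(cfg.gaussian_sd_pool["logmean"], cfg.gaussian_sd_pool["logsd"], size=p)
    n_da = round(cfg.da_fraction * p)
    da = rng.choice(p, size=n_da, replace=False)
    fc = np.ones(p)
    fc[da] = 1.0 + cfg.fold_change_gaussian   # "fold change 0.1" = +10% on the mean
    direction = np.zeros(p, dtype=int)
    direction[da] = 1
    mu = np.where(groups[:, None] == 0, m[None, :], (m * fc)[None, :])
    x = rng.normal(mu, sd[None, :])
    view = ViewData(matrix=x, family=GAUSSIAN, name=name,
                    feature_ids=[f"{name}_f{j:04d}" for j in range(p)])
    truth = pd.DataFrame({"da": direction != 0, "fold_change": fc, "direction": direction},
                         index=view.feature_ids)
    return view, truth


def simulate_parametric(config: SimConfig | None = None, seed: int | None = None):
    """Strategy-1 generator: parametric draws with a two-group fold-change signal.

    Returns ``(views, truth)``; identical seeds give bit-identical output.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    groups = np.repeat([0, 1], cfg.n // 2)
    views, truths = [], {}
    for k, family in enumerate(cfg.families):
        name = f"view{k + 1}"
        p = cfg.p_for(k)
        if family == COUNT:
            v, t = _simulate_count_view(rng, name, p, cfg, groups)
        elif family == GAUSSIAN:
            v, t = _simulate_gaussian_view(rng, name, p, cfg, groups)
        else:
            raise ValueError(f"unknown family {family!r}")
        views.append(v)
        truths[name] = t
    labels = np.where(groups == 0, "g1", "g2")
    return views, SimulationTruth(groups=labels, features=truths)


def permute_views(views: list[ViewData], seed: int | None = None,
                  permutations: list[np.ndarray] | None = None) -> list[ViewData]:
    """Strategy-3 null: permute the samples of each view independently.

    Every view keeps exactly the same multiset of rows, but the cross-view
    sample alignment is destroyed.  Explicit ``permutations`` (one index
    array per view) override the seeded draws.
    """
    if len(views) < 2 and permutations is None:
        raise ValueError("permutation null needs at least two views")
    rng = np.random.default_rng(seed)
    out = []
    for k, v in enumerate(views):
        perm = permutations[k] if permutations is not None else rng.permutation(v.n_samples)
        out.append(replace(v, matrix=v.matrix[perm], missing_mask=v.missing_mask[perm],
                           sample_ids=list(v.sample_ids)))
    return out


def simulate_from_latent(n: int = 40, p: int | tuple = 200, families=(COUNT, GAUSSIAN),
                         M: int = 2, score_sd=(3.0, 1.8), dispersion: float = 0.3,
                         depth_mean: float = 2.0e4, depth_logsd: float = 0.3,
                         noise_sd: float = 0.5, seed: int | None = None):
    """Draw data directly from the model form with known scores and loadings.

    Scores are centered, orthogonalized columns with decreasing standard
    deviations ``score_sd``; loadings rows are random zero-sum directions.
    Returns ``(views, Z_true, loadings_true)`` for recovery studies.
    """
    rng = np.random.default_rng(seed)
    ps = [p] * len(families) if isinstance(p, int) else list(p)
    Z = rng.standard_normal((n, M))
    Z -= Z.mean(axis=0)
    Z, _ = np.linalg.qr(Z)
    Z = Z * (np.asarray(score_sd[:M]) * np.sqrt(n))
    views, loadings = [], {}
    for k, (family, pk) in enumerate(zip(families, ps)):
        name = f"view{k + 1}"
        G = rng.standard_normal((M, pk))
        G -= G.mean(axis=1, keepdims=True)
        G /= np.linalg.norm(G, axis=1, keepdims=True)   # unit rows, zero-sum
        if family == COUNT:
            base = rng.lognormal(0.0, 1.5, size=pk)
            u = clr(base / base.sum())
            s = rng.lognormal(np.log(depth_mean) - depth_logsd**2 / 2, depth_logsd, size=n)
            pi = clr_inverse(u[None, :] + Z @ G)
            mu = pi * s[:, None]
            r = 1.0 / dispersion
            x = rng.negative_binomial(r, r / (r + mu)).astype(float)
            views.append(ViewData(matrix=x, family=COUNT, name=name,
                                  feature_ids=[f"{name}_f{j:04d}" for j in range(pk)]))
        else:
            u = rng.normal(10.0, 1.0, size=pk)
            x = u[None, :] + Z @ G + rng.normal(0.0, noise_sd, size=(n, pk))
            views.append(ViewData(matrix=x, family=GAUSSIAN, name=name,
                                  feature_ids=[f"{name}_f{j:04d}" for j in range(pk)]))
        loadings[name] = G
    return views, Z, loadings
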