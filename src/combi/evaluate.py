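"""Evaluation statistics for integration methods.

Three statistics quantify the behaviour of an ordination: (1) the Pearson
correlation of the sample scores with the per-view and overall sample sums
(an ordination free of sequencing-depth artefacts should show none); (2)
the standardized Wilcoxon rank-sum statistic on the inner products of
feature-loading pairs, measuring how well truly correlated feature pairs
are ranked above uncorrelated ones; (3) the pseudo-F statistic measuring
separation of known sample groups in the score space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "score_sum_correlation",
    "wilcoxon_inner_product_stat",
    "pseudo_f",
    "pca_scores",
    "EvaluationReport",
    "evaluation_report",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant vector in correlation; reporting 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def score_sum_correlation(scores, views) -> pd.DataFrame:
    """Correlation of each score column with view-wise and overall sample sums.

    Missing cells count as 0 in the sums.  Rows: one per view plus
    ``"overall"``; columns: one per score dimension.
    """
    Z = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    sums = {}
    total = np.zeros(Z.shape[0])
    for v in views:
        row = np.where(v.observed, v.matrix, 0.0).sum(axis=1)
        sums[v.name] = row
        total += row
    sums["overall"] = total
    out = {name: [_pearson(Z[:, m], s) for m in range(Z.shape[1])] for name, s in sums.items()}
    return pd.DataFrame(out, index=[f"dim{m + 1}" for m in range(Z.shape[1])]).T


def _pair_inner_products(La: np.ndarray, Lb: np.ndarray, labels: np.ndarray, same_view: bool):
    ip = La.T @ Lb                      # (pa, pb) inner products of loading vectors
    if same_view:
        iu = np.triu_indices(ip.shape[0], k=1)
        return ip[iu], labels[iu]
    return ip.ravel(), labels.ravel()


def wilcoxon_inner_product_stat(loadings_by_view: dict[str, np.ndarray],
                                labels: dict[tuple[str, str], np.ndarray],
                                between_view_only: bool = False) -> float:
    """Standardized Wilcoxon rank-sum statistic on loading inner products.

    All feature pairs (within views and between views, or between views
    only) are ranked by the inner product of their loading vectors; group 1
    holds the truly correlated pairs.  With midranks for ties,

        z = (W - n1 (n1 + n2 + 1) / 2) / sqrt(n1 n2 (n1 + n2 + 1) / 12).

    ``labels[(a, b)]`` is the boolean (p_a x p_b) matrix of truly correlated
    pairs; missing view pairs are skipped.
    """
    names = list(loadings_by_view)
    vals, labs = [], []
    for i, a in enumerate(names):
        for b in names[i:]:
            if between_view_only and a == b:
                continue
            key = (a, b) if (a, b) in labels else (b, a)
            if key not in labels:
                continue
            lab = labels[key] if key == (a, b) else labels[key].T
            v, l = _pair_inner_products(np.asarray(loadings_by_view[a], float),
                                        np.asarray(loadings_by_view[b], float),
                                        np.asarray(lab, bool), a == b)
            vals.append(v)
            labs.append(l)
    if not vals:
        raise ValueError("no feature pairs with truth labels")
    x = np.concatenate(vals)
    g = np.concatenate(labs)
    n1 = int(g.sum())
    n2 = int((~g).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("one of the pair groups is empty; statistic undefined")
    ranks = rankdata(x)                 # midranks
    W = float(ranks[g].sum())
    mean = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sd == 0:
        return 0.0
    return float((W - mean) / sd)


def pseudo_f(scores, groups, method: str = "calinski") -> float:
    """Between- over within-group dispersion of the sample scores.

    ``method="calinski"`` is the Calinski-Harabasz form
    ``(SSB / (k - 1)) / (SSW / (n - k))`` on Euclidean coordinates;
    ``method="permanova"`` computes the same pseudo-F from the pairwise
    distance matrix (Anderson's form), which generalizes to non-Euclidean
    distances.  Perfect separation (SSW = 0) returns ``inf``.
    """
    Z = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    groups = np.asarray(groups)
    n = Z.shape[0]
    levels, counts = np.unique(groups, return_counts=True)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("each group needs at least two samples (singleton group)")
    if method == "calinski":
        grand = Z.mean(axis=0)
        ssb = ssw = 0.0
        for lev in levels:
            sub = Z[groups == lev]
            ssb += sub.shape[0] * float(((sub.mean(axis=0) - grand) ** 2).sum())
            ssw += float(((sub - sub.mean(axis=0)) ** 2).sum())
    elif method == "permanova":
        d2 = squareform(pdist(Z)) ** 2
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for lev in levels:
            idx = np.flatnonzero(groups == lev)
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssb = sst - ssw
    else:
        raise ValueError("method must be 'calinski' or 'permanova'")
    if ssw <= 1e-300:
        return float("inf")
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def pca_scores(views, M: int = 2) -> np.ndarray:
    """Scores of a plain concatenated-matrix PCA (internal baseline only)."""
    mats = [np.where(v.observed, v.matrix, 0.0) for v in views]
    X = np.hstack(mats)
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :M] * S[:M]


@dataclass
class EvaluationReport:
    """Bundle of the three evaluation statistics for one fitted ordination."""

    score_sum_correlations: pd.DataFrame
    wilcoxon_all: float | None = None
    wilcoxon_between: float | None = None
    pseudo_f: float | None = None
    pseudo_f_capped: bool = False
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "score_sum_correlations": self.score_sum_correlations.round(6).to_dict(),
            "wilcoxon_all": self.wilcoxon_all,
            "wilcoxon_between": self.wilcoxon_between,
            "pseudo_f": None if self.pseudo_f is None
            else ("inf" if np.isinf(self.pseudo_f) else self.pseudo_f),
            "pseudo_f_capped": self.pseudo_f_capped,
            "meta": self.meta,
        }


def evaluation_report(results, truth=None, groups=None) -> EvaluationReport:
    """Evaluate a :class:`~combi.model.CombiResults` against simulation truth."""
    report = EvaluationReport(
        score_sum_correlations=score_sum_correlation(results.scores, results.views),
        meta={"M": results.M, "n": results.Z.shape[0]},
    )
    if truth is not None:
        loadings = {v.name: results.loadings(v.name).to_numpy() for v in results.views}
        labels = {}
        names = [v.name for v in results.views]
        for i, a in enumerate(names):
            for b in names[i:]:
                fa = results.views[i].feature_ids
                fb = results.views[names.index(b)].feature_ids
                lab = truth.pair_labels(a, b)
                ia = truth.features[a].index.get_indexer(fa)
                ib = truth.features[b].index.get_indexer(fb)
                if np.any(ia < 0) or np.any(ib < 0):
                    raise KeyError("fitted features missing from simulation truth")
                labels[(a, b)] = lab[np.ix_(ia, ib)]
        report.wilcoxon_all = wilcoxon_inner_product_stat(loadings, labels, between_view_only=False)
        if len(names) > 1:
            report.wilcoxon_between = wilcoxon_inner_product_stat(loadings, labels,
                                                                  between_view_only=True)
        if groups is None:
            groups = truth.groups
    if groups is not None:
        f = pseudo_f(results.scores, groups)
        report.pseudo_f = f
        report.pseudo_f_capped = bool(np.isinf(f))
    return report
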