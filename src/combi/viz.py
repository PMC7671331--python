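"""Multiplots: joint display of sample scores, feature loadings and gradients.

Samples are dots at their score pairs, features labels at their loading
pairs (one colour per view), and — for constrained fits — the environmental
gradient components as black labels.  Because the model deliberately
reports no variance-explained fractions, the axes are forced to be square
so Euclidean distances between sample dots faithfully reflect
dissimilarities.  Thresholding only selects which feature labels are
*displayed* (the largest loading norms); stored loadings are never altered.

For compositional views individual labels must not be read alone: the
interpretable quantity is the *link* between two features a and b, whose
projection onto a sample's scores gives that sample's log-ratio shift
relative to the independence model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import COUNT

__all__ = ["MultiplotSpec", "multiplot_coordinates", "feature_link_projection",
           "plot_multiplot"]


@dataclass
class MultiplotSpec:
    """Coordinates of one multiplot; TSV round-trips are bit-exact."""

    samples: pd.DataFrame                      # index sample, columns x, y
    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    gradient: pd.DataFrame | None = None
    dims: tuple = (1, 2)
    threshold: tuple | str = "all"

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(path / "samples.tsv", sep="\t")
        for name, df in self.features.items():
            df.to_csv(path / f"features_{name}.tsv", sep="\t")
        if self.gradient is not None:
            self.gradient.to_csv(path / "gradient.tsv", sep="\t")
        meta = pd.Series({"dims": f"{self.dims[0]},{self.dims[1]}",
                          "threshold": str(self.threshold)})
        meta.to_csv(path / "spec.tsv", sep="\t", header=False)

    @classmethod
    def from_dir(cls, path) -> "MultiplotSpec":
        path = Path(path)
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col=0, float_precision="round_trip")
        features = {}
        for f in sorted(path.glob("features_*.tsv")):
            features[f.stem.removeprefix("features_")] = pd.read_csv(f, sep="\t", index_col=0, float_precision="round_trip")
        gradient = None
        if (path / "gradient.tsv").exists():
            gradient = pd.read_csv(path / "gradient.tsv", sep="\t", index_col=0, float_precision="round_trip")
        meta = pd.read_csv(path / "spec.tsv", sep="\t", index_col=0, header=None).squeeze("columns")
        dims = tuple(int(x) for x in str(meta.loc["dims"]).split(","))
        return cls(samples=samples, features=features, gradient=gradient, dims=dims,
                   threshold=str(meta.loc["threshold"]))


def _select(norms: np.ndarray, threshold) -> np.ndarray:
    """Display selection by loading norm; ties at the cutoff are all retained."""
    if threshold in (None, "all"):
        return np.ones(norms.shape, dtype=bool)
    kind, value = threshold
    if kind == "top":
        k = int(value)
        if k >= norms.size:
            return np.ones(norms.shape, dtype=bool)
        cut = np.sort(norms)[::-1][k - 1]
        return norms >= cut
    if kind == "quantile":
        return norms >= np.quantile(norms, float(value))
    raise ValueError("threshold must be 'all', ('top', k) or ('quantile', q)")


def multiplot_coordinates(results, dims=(1, 2), threshold=("top", 15)) -> MultiplotSpec:
    """Extract sample, feature and gradient coordinates for a multiplot."""
    d1, d2 = dims
    if not (1 <= d1 <= results.M and 1 <= d2 <= results.M):
        raise ValueError(f"dims out of range: fitted {results.M} dimensions")
    cols = [f"dim{d1}", f"dim{d2}"]
    samples = results.scores[cols].copy()
    features = {}
    for v in results.views:
        load = results.loadings(v.name).T[cols]
        norms = np.sqrt((load**2).sum(axis=1)).to_numpy()
        sel = _select(norms, threshold)
        df = load.copy()
        df["norm"] = norms
        df["selected"] = sel
        features[v.name] = df
    gradient = None
    if results.gradient is not None:
        lam = pd.DataFrame(results.gradient.Lambda, index=results.gradient.design.columns,
                           columns=[f"dim{m + 1}" for m in range(results.M)])
        gradient = lam[cols].copy()
    return MultiplotSpec(samples=samples, features=features, gradient=gradient,
                         dims=(d1, d2), threshold=threshold)


def feature_link_projection(results, view, feature_a: str, feature_b: str, sample) -> float:
    """Projection of a sample's scores onto the link between two features.

    Returns ``Z_i' (gamma_a - gamma_b)``, which equals the sample's log-ratio
    shift ``log(pi_ia / pi_ib) - log(pi_a_indep / pi_b_indep)`` in a
    compositional view.  Features must come from the same compositional
    view; cross-view ratios of compositional features are not interpretable.
    """
    i = results._view_index(view)
    v = results.views[i]
    if v.family != COUNT:
        raise ValueError("feature links are defined for compositional views")
    try:
        ja = v.feature_ids.index(feature_a)
        jb = v.feature_ids.index(feature_b)
    except ValueError as err:
        raise KeyError(f"feature not found in view {v.name!r}: {err}") from None
    si = v.sample_ids.index(sample) if isinstance(sample, str) else int(sample)
    G = results.params[i].loadings
    return float(results.Z[si] @ (G[:, ja] - G[:, jb]))


def plot_multiplot(spec: MultiplotSpec, metadata: pd.DataFrame | None = None,
                   color_by: str | None = None, shape_by: str | None = None,
                   ax=None, max_labels: int | None = None):
    """Render a multiplot with square axes; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 7))
    else:
        fig = ax.figure
    xcol, ycol = spec.samples.columns[:2]
    x = spec.samples[xcol].to_numpy()
    y = spec.samples[ycol].to_numpy()

    colors = None
    if color_by is not None:
        if metadata is None or color_by not in metadata.columns:
            raise KeyError(f"color_by variable {color_by!r} not in metadata")
        cvals = metadata.loc[spec.samples.index, color_by]
        levels = pd.unique(cvals)
        cmap = plt.get_cmap("tab10")
        lut = {lev: cmap(i % 10) for i, lev in enumerate(levels)}
        colors = [lut[v] for v in cvals]
    markers = ["o", "s", "^", "D", "v", "P", "X", "*"]
    if shape_by is not None:
        if metadata is None or shape_by not in metadata.columns:
            raise KeyError(f"shape_by variable {shape_by!r} not in metadata")
        svals = metadata.loc[spec.samples.index, shape_by]
        for i, lev in enumerate(pd.unique(svals)):
            sel = (svals == lev).to_numpy()
            ax.scatter(x[sel], y[sel], marker=markers[i % len(markers)],
                       c=None if colors is None else [c for c, s in zip(colors, sel) if s],
                       label=str(lev), zorder=3)
        ax.legend(loc="best", fontsize=8)
    else:
        ax.scatter(x, y, c=colors, zorder=3)

    view_colors = plt.get_cmap("Dark2")
    for k, (name, df) in enumerate(spec.features.items()):
        shown = df[df["selected"]]
        if max_labels is not None:
            shown = shown.nlargest(max_labels, "norm")
        for fid, row in shown.iterrows():
            ax.annotate(str(fid), (row.iloc[0], row.iloc[1]), fontsize=7,
                        color=view_colors(k % 8), zorder=2)
    if spec.gradient is not None:
        for gid, row in spec.gradient.iterrows():
            ax.annotate(str(gid), (row.iloc[0], row.iloc[1]), fontsize=8,
                        color="black", fontweight="bold", zorder=4)
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.axvline(0.0, lw=0.5, color="grey")
    ax.set_xlabel(f"Dimension {spec.dims[0]}")
    ax.set_ylabel(f"Dimension {spec.dims[1]}")
    ax.set_aspect("equal", adjustable="datalim")   # square axes: distances are honest
    return fig
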