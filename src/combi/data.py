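"""Data containers for omics views and sample-level design matrices.

A :class:`ViewData` wraps one sample-by-feature matrix with a declared
distribution family.  Count views hold non-negative integers (sequence
counts); gaussian views hold real values (e.g. log intensities).  Missing
entries are allowed in both and are carried as an explicit mask: they are
excluded from the estimating equations rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COUNT = "compositional_count"
GAUSSIAN = "gaussian"
FAMILIES = (COUNT, GAUSSIAN)

__all__ = [
    "COUNT",
    "GAUSSIAN",
    "ViewData",
    "align_views",
    "filter_features",
    "encode_design",
]


@dataclass
class ViewData:
    """One omics view: an ``n x p`` matrix with family and missingness mask.

    Parameters
    ----------
    matrix
        Values as floats; entries under ``missing_mask`` are ignored.
    family
        ``"compositional_count"`` or ``"gaussian"``.
    sample_ids, feature_ids
        Row and column labels; samples are aligned across views by id.
    missing_mask
        Boolean, True marks a missing cell.
    log_transformed
        Gaussian views only: whether the data were log-transformed on load.
    """

    matrix: np.ndarray
    family: str
    sample_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)
    missing_mask: np.ndarray | None = None
    log_transformed: bool = False
    name: str = "view"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("view matrix must be 2-D (samples x features)")
        n, p = self.matrix.shape
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"{self.name}_f{j}" for j in range(p)]
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("id lengths do not match matrix shape")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.matrix)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool) | ~np.isfinite(self.matrix)
        if self.missing_mask.shape != self.matrix.shape:
            raise ValueError("missing_mask shape does not match matrix")
        obs = ~self.missing_mask
        vals = self.matrix[obs]
        if self.family == COUNT:
            if vals.size and (np.any(vals < 0) or np.any(vals != np.round(vals))):
                raise ValueError("compositional_count entries must be non-negative integers where observed")
            if self.log_transformed:
                raise ValueError("log_transformed applies to gaussian views only")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed cells (inverse of ``missing_mask``)."""
        return ~self.missing_mask

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: str, name: str = "view",
                       log_transform: bool = False) -> "ViewData":
        """Build a view from a samples-by-features DataFrame (NaN = missing)."""
        matrix = df.to_numpy(dtype=float)
        if log_transform:
            if family != GAUSSIAN:
                raise ValueError("log_transform applies to gaussian views only")
            with np.errstate(divide="ignore", invalid="ignore"):
                matrix = np.log(matrix)
            matrix[~np.isfinite(matrix)] = np.nan
        return cls(
            matrix=matrix,
            family=family,
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            log_transformed=log_transform and family == GAUSSIAN,
            name=name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.feature_ids)
        out[pd.DataFrame(self.missing_mask, index=out.index, columns=out.columns)] = np.nan
        return out


def align_views(views: list[ViewData]) -> list[ViewData]:
    """Align views on the union of sample ids.

    A sample absent from one view is added there as an all-missing row, so
    every view shares the same ordered sample axis.  Samples missing from
    *every* view are dropped with a warning.
    """
    if not views:
        raise ValueError("no views supplied")
    all_ids: list[str] = []
    for v in views:
        for s in v.sample_ids:
            if s not in all_ids:
                all_ids.append(s)
    common = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    if len(views) > 1 and not common:
        raise ValueError("views share no sample ids; cannot integrate disjoint sample sets")

    out = []
    for v in views:
        idx = {s: i for i, s in enumerate(v.sample_ids)}
        mat = np.full((len(all_ids), v.n_features), np.nan)
        mask = np.ones((len(all_ids), v.n_features), dtype=bool)
        for i, s in enumerate(all_ids):
            if s in idx:
                mat[i] = v.matrix[idx[s]]
                mask[i] = v.missing_mask[idx[s]]
        out.append(replace(v, matrix=mat, missing_mask=mask, sample_ids=list(all_ids)))

    # drop samples unobserved everywhere
    any_obs = np.zeros(len(all_ids), dtype=bool)
    for v in out:
        any_obs |= v.observed.any(axis=1)
    if not any_obs.all():
        dropped = [s for s, keep in zip(all_ids, any_obs) if not keep]
        warnings.warn(f"dropping samples with no observations in any view: {dropped}")
        out = [
            replace(v, matrix=v.matrix[any_obs], missing_mask=v.missing_mask[any_obs],
                    sample_ids=[s for s, keep in zip(all_ids, any_obs) if keep])
            for v in out
        ]
    return out


def filter_features(view: ViewData, min_total_count: float = 1, min_prevalence: int = 1) -> ViewData:
    """Drop features that cannot support estimation.

    Count views: features whose observed total is below ``min_total_count``
    have unidentifiable clr parameters and must be removed before fitting.
    Both families: features observed in fewer than ``min_prevalence`` samples
    are dropped.
    """
    obs = view.observed
    filled = np.where(obs, view.matrix, 0.0)
    keep = obs.sum(axis=0) >= min_prevalence
    if view.family == COUNT:
        keep &= filled.sum(axis=0) >= min_total_count
    return replace(
        view,
        matrix=view.matrix[:, keep],
        missing_mask=view.missing_mask[:, keep],
        feature_ids=[f for f, k in zip(view.feature_ids, keep) if k],
    )


def encode_design(metadata: pd.DataFrame, variables: list[str]):
    """Expand sample metadata into a constrained-ordination design matrix.

    Categorical variables expand to one indicator column per level *without*
    dropping a reference level; the returned ``blocks`` mapping records which
    columns belong to each categorical variable so the zero-sum restriction
    on the environmental gradient can be imposed.  Continuous variables are
    centered and scaled to standard deviation 1 (ddof=1).

    Returns
    -------
    design : pandas.DataFrame (n x d)
    blocks : dict mapping variable name -> list of column positions
    """
    cols: dict[str, np.ndarray] = {}
    blocks: dict[str, list[int]] = {}
    for var in variables:
        if var not in metadata.columns:
            raise KeyError(f"variable {var!r} not in metadata")
        series = metadata[var]
        if series.isna().any():
            raise ValueError(f"variable {var!r} has missing metadata")
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            sd = series.std(ddof=1)
            if sd == 0:
                raise ValueError(f"continuous variable {var!r} is constant (sd 0)")
            cols[var] = ((series - series.mean()) / sd).to_numpy(dtype=float)
        else:
            levels = list(pd.unique(series.astype(str)))
            if len(levels) < 2:
                raise ValueError(f"categorical variable {var!r} has a single level")
            start = len(cols)
            for lev in levels:
                cols[f"{var}={lev}"] = (series.astype(str) == lev).to_numpy(dtype=float)
            blocks[var] = list(range(start, len(cols)))
    design = pd.DataFrame(cols, index=metadata.index)
    return design, blocks
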