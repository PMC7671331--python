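"""Reading views/metadata and (de)serializing fitted models.

Views are TSV/CSV sample-by-feature tables: first column sample id, header
feature ids, empty cells missing.  A fitted model is written as a directory
of plain-text artefacts — ``fit.json`` for scalars, shapes and the variance
models, TSV matrices for scores/loadings/offsets and echoes of the input
views — so a fit can be reloaded without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .data import COUNT, GAUSSIAN, ViewData
from .model import (Combi, CombiResults, EnvironmentalGradient, IndependenceModel, ViewParams)
from .variance import GaussianVariances, VarianceTrend

__all__ = ["read_view", "read_metadata", "save_fit", "load_fit"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_view(path, family: str, name: str | None = None, log_transform: bool = False) -> ViewData:
    """Load one view from a TSV/CSV table (first column = sample id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ViewData.from_dataframe(df, family=family, name=name or path.stem,
                                   log_transform=log_transform)


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def _trend_to_dict(t: VarianceTrend) -> dict:
    out = {"kind": "trend", "cutoff": t.cutoff, "shift": t.shift, "log_range": list(t.log_range)}
    if t.spline is not None:
        out["spline"] = {"t": t.spline.t.tolist(), "c": t.spline.c.tolist(), "k": int(t.spline.k)}
    return out


def _trend_from_dict(d: dict) -> VarianceTrend:
    spline = None
    if "spline" in d:
        s = d["spline"]
        spline = BSpline(np.asarray(s["t"]), np.asarray(s["c"]), int(s["k"]))
    return VarianceTrend(spline=spline, cutoff=d["cutoff"], shift=d["shift"],
                         log_range=tuple(d["log_range"]))


def save_fit(results: CombiResults, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "views").mkdir(exist_ok=True)
    results.scores.to_csv(path / "scores.tsv", sep="\t")
    meta: dict = {
        "M": results.M,
        "psi": results.psi.tolist(),
        "convergence": results.convergence,
        "options": {k: getattr(results.options, k)
                    for k in ("M", "tol", "max_iter", "max_trend_iter", "seed", "mode", "max_step")},
        "views": [],
    }
    for i, v in enumerate(results.views):
        results.loadings(v.name).to_csv(path / f"loadings_{v.name}.tsv", sep="\t")
        v.to_dataframe().to_csv(path / "views" / f"{v.name}.tsv", sep="\t")
        p = results.params[i]
        indep = results.independence[i]
        entry = {
            "name": v.name,
            "family": v.family,
            "log_transformed": v.log_transformed,
            "offset": indep.offset.tolist(),
            "depths": indep.depths.tolist(),
            "pi_indep": None if indep.pi_indep is None else indep.pi_indep.tolist(),
            "weights": p.weights.tolist(),
            "confounder_blocks": p.confounder_blocks,
        }
        if p.confounder_coefs is not None:
            pd.DataFrame(p.confounder_coefs, columns=v.feature_ids).to_csv(
                path / f"confounders_{v.name}.tsv", sep="\t")
            pd.DataFrame(p.confounder_design, index=v.sample_ids).to_csv(
                path / f"confounder_design_{v.name}.tsv", sep="\t")
        vm = results.variance_models[i]
        if isinstance(vm, VarianceTrend):
            entry["variance_model"] = _trend_to_dict(vm)
        else:
            entry["variance_model"] = {"kind": "gaussian", "variances": vm.variances.tolist(),
                                       "prior_var": vm.prior_var, "prior_df": vm.prior_df}
        meta["views"].append(entry)
    if results.gradient is not None:
        g = results.gradient
        pd.DataFrame(g.Lambda, index=g.design.columns,
                     columns=[f"dim{m + 1}" for m in range(results.M)]).to_csv(
            path / "gradient.tsv", sep="\t")
        g.design.to_csv(path / "gradient_design.tsv", sep="\t")
        meta["gradient"] = {"blocks": g.blocks, "scale": g.scale.tolist()}
    if results.model.metadata is not None:
        results.model.metadata.to_csv(path / "metadata.tsv", sep="\t")
    with open(path / "fit.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=float)


def load_fit(path) -> CombiResults:
    """Reload a fit directory written by :func:`save_fit` (views included)."""
    path = Path(path)
    with open(path / "fit.json") as fh:
        meta = json.load(fh)
    views, independence, params, variance_models = [], [], [], []
    scores = pd.read_csv(path / "scores.tsv", sep="\t", index_col=0, float_precision="round_trip")
    for entry in meta["views"]:
        name = entry["name"]
        df = pd.read_csv(path / "views" / f"{name}.tsv", sep="\t", index_col=0)
        df.index = df.index.astype(str)
        view = ViewData.from_dataframe(df, family=entry["family"], name=name)
        view.log_transformed = bool(entry["log_transformed"])
        views.append(view)
        independence.append(IndependenceModel(
            offset=np.asarray(entry["offset"]),
            depths=np.asarray(entry["depths"]),
            pi_indep=None if entry["pi_indep"] is None else np.asarray(entry["pi_indep"]),
        ))
        load = pd.read_csv(path / f"loadings_{name}.tsv", sep="\t", index_col=0, float_precision="round_trip")
        coefs = design = None
        if (path / f"confounders_{name}.tsv").exists():
            coefs = pd.read_csv(path / f"confounders_{name}.tsv", sep="\t", index_col=0).to_numpy()
            design = pd.read_csv(path / f"confounder_design_{name}.tsv", sep="\t",
                                 index_col=0).to_numpy()
        params.append(ViewParams(
            loadings=load.to_numpy(), weights=np.asarray(entry["weights"]),
            confounder_coefs=coefs, confounder_design=design,
            confounder_blocks={k: list(vv) for k, vv in entry["confounder_blocks"].items()},
        ))
        vm = entry["variance_model"]
        if vm["kind"] == "trend":
            variance_models.append(_trend_from_dict(vm))
        else:
            variance_models.append(GaussianVariances(
                variances=np.asarray(vm["variances"]), prior_var=vm["prior_var"],
                prior_df=vm["prior_df"]))
    metadata = None
    if (path / "metadata.tsv").exists():
        metadata = read_metadata(path / "metadata.tsv")
    model = Combi.__new__(Combi)
    model.views = views
    model.sample_ids = list(scores.index.astype(str))
    model.metadata = metadata
    model.constraint_vars = None
    model.confounders = {}
    model.weights = {}
    gradient = None
    if "gradient" in meta:
        lam = pd.read_csv(path / "gradient.tsv", sep="\t", index_col=0)
        design = pd.read_csv(path / "gradient_design.tsv", sep="\t", index_col=0)
        gradient = EnvironmentalGradient(
            Lambda=lam.to_numpy(), design=design,
            blocks={k: list(vv) for k, vv in meta["gradient"]["blocks"].items()},
            scale=np.asarray(meta["gradient"]["scale"]))
        model.constraint_vars = list(meta["gradient"]["blocks"]) or None

    from .estimation import FitOptions
    opts = FitOptions(**meta["options"])
    return CombiResults(
        model=model, independence=independence, params=params,
        variance_models=variance_models, Z=scores.to_numpy(dtype=float),
        psi=np.asarray(meta["psi"]), gradient=gradient, M=int(meta["M"]),
        convergence=meta["convergence"], options=opts)
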