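"""Model interrogation and projection.

Fitted models are interrogated through their parameter estimates (directly
comparable because all DVs live on [0, 1]), through single-effect and
marginal-effect response curves, and by projecting predictions onto new
tabular or raster EV data.  Every projection is accompanied by a per-EV
report of the projection data range on the training-scaled axis (training
range = [0, 1]), so speculative extrapolation is visible at a glance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import MaxentModel, fit_model
from .io_tabular import AsciiGrid
from .transform import DVCatalog

__all__ = [
    "ProjectionResult",
    "project_model",
    "response_single",
    "response_marginal",
    "report_coefficients",
]


@dataclass
class ProjectionResult:
    """Predictions plus a per-EV extrapolation-range report.

    ``predictions`` is a Series (tabular input) or AsciiGrid (raster
    input); PRO scale for maximum-entropy models, probabilities for
    logistic regression.  ``ranges`` has one row per EV with the min/max of
    the projection values on the axis where the training range is [0, 1]
    (categorical EVs are flagged "inside"/"outside" instead).
    """

    predictions: object
    ranges: pd.DataFrame


def _ev_ranges(catalog: DVCatalog, ev_data: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for ev, fns in catalog.entries.items():
        fn = fns[0][1]
        if fn.type_tag == "B":
            train_levels = {str(f.params["level"]) for _, f in fns}
            seen = set(pd.unique(ev_data[ev].astype(str)))
            status = "inside" if seen <= train_levels else "outside"
            rows.append({"EV": ev, "min": np.nan, "max": np.nan, "status": status})
        else:
            tmin, tmax = fn.params["train_min"], fn.params["train_max"]
            x = np.asarray(ev_data[ev], dtype=float)
            x = x[np.isfinite(x)]
            scaled = (x - tmin) / (tmax - tmin)
            inside = scaled.min() >= 0.0 and scaled.max() <= 1.0
            rows.append(
                {
                    "EV": ev,
                    "min": float(scaled.min()),
                    "max": float(scaled.max()),
                    "status": "inside" if inside else "outside",
                }
            )
    return pd.DataFrame(rows)


def project_model(
    model: MaxentModel,
    catalog: DVCatalog,
    ev_data,
    clamp: bool = False,
) -> ProjectionResult:
    """Predict over new EV data (DataFrame or dict of EV-name -> AsciiGrid).

    ``clamp=True`` truncates continuous EV values to the training range
    before transformation, making predictions invariant to how far outside
    the training interval an input lies.  Raster nodata cells propagate to
    nodata predictions.
    """
    model_catalog = catalog.subset(_model_groups(model, catalog))
    if isinstance(ev_data, dict) and all(isinstance(v, AsciiGrid) for v in ev_data.values()):
        grids = ev_data
        first = next(iter(grids.values()))
        for g in grids.values():
            if not first.same_header(g):
                raise ValueError("projection rasters do not share an identical header")
        flat = {}
        valid = np.ones(first.nrows * first.ncols, dtype=bool)
        for name, g in grids.items():
            v = g.values.ravel()
            bad = v == g.nodata_value
            valid &= ~bad
            flat[name] = v
        df = pd.DataFrame(flat)
        tab = project_model(model, catalog, df[valid], clamp=clamp)
        out = np.full(first.nrows * first.ncols, first.nodata_value, dtype=float)
        out[valid] = np.asarray(tab.predictions, dtype=float)
        grid = AsciiGrid(
            ncols=first.ncols,
            nrows=first.nrows,
            xllcorner=first.xllcorner,
            yllcorner=first.yllcorner,
            cellsize=first.cellsize,
            nodata_value=first.nodata_value,
            values=out.reshape(first.nrows, first.ncols),
        )
        ranges = _ev_ranges(model_catalog, df[valid])
        return ProjectionResult(grid, ranges)

    ev_data = pd.DataFrame(ev_data)
    missing = [ev for ev in model_catalog.ev_names if ev not in ev_data.columns]
    if missing:
        raise KeyError(f"EVs missing from projection data: {missing}")
    dv = model_catalog.transform(ev_data, clamp=clamp)
    preds = pd.Series(model.predict(dv[model.dv_names_]), index=ev_data.index, name="prediction")
    return ProjectionResult(preds, _ev_ranges(model_catalog, ev_data))


def _model_groups(model: MaxentModel, catalog: DVCatalog) -> dict[str, list[str]]:
    groups = {}
    for ev, names in catalog.groups.items():
        mine = [n for n in names if n in model.dv_names_]
        if mine:
            groups[ev] = mine
    covered = {n for names in groups.values() for n in names}
    extra = [n for n in model.dv_names_ if n not in covered]
    if extra:
        raise KeyError(f"model DVs not found in catalog: {extra}")
    return groups


def _ev_grid(catalog: DVCatalog, ev: str, grid_n: int):
    fns = catalog.entries[ev]
    if fns[0][1].type_tag == "B":
        return np.array([f.params["level"] for _, f in fns], dtype=object)
    tmin = fns[0][1].params["train_min"]
    tmax = fns[0][1].params["train_max"]
    return np.linspace(tmin, tmax, grid_n)


def response_single(
    model: MaxentModel,
    catalog: DVCatalog,
    ev_dv_df: pd.DataFrame,
    rv,
    ev_name: str,
    grid_n: int = 100,
) -> pd.DataFrame:
    """Single-effect response curve for one EV.

    Refits a model containing only the named EV's DVs from ``model`` (same
    algorithm and rows) and evaluates it across the EV's training range
    (levels for a categorical EV).  Returns (ev_value, response) pairs on
    the PRO (maxent) or probability (LR) scale.
    """
    groups = _model_groups(model, catalog)
    if ev_name not in groups:
        raise ValueError(f"EV {ev_name!r} is not in the model")
    cols = groups[ev_name]
    sub = fit_model(
        ev_dv_df[cols], rv, algorithm=model.algorithm, bg_weight=model.bg_weight
    )
    grid = _ev_grid(catalog, ev_name, grid_n)
    sub_cat = catalog.subset({ev_name: cols})
    dv = sub_cat.transform(pd.DataFrame({ev_name: grid}))
    resp = sub.predict(dv[sub.dv_names_])
    return pd.DataFrame({ev_name: grid, "response": resp})


def response_marginal(
    model: MaxentModel,
    catalog: DVCatalog,
    ev_train: pd.DataFrame,
    ev_name: str,
    grid_n: int = 100,
    categorical=(),
) -> pd.DataFrame:
    """Marginal-effect response curve for one EV.

    Varies the named EV across its training range while holding every other
    continuous EV at its training mean and every categorical EV at its
    modal level.  Maximum-entropy responses are reported in exponential
    output q/N = exp(alpha + sum beta x); LR responses as probabilities.
    """
    groups = _model_groups(model, catalog)
    if ev_name not in groups:
        raise ValueError(f"EV {ev_name!r} is not in the model")
    grid = _ev_grid(catalog, ev_name, grid_n)
    frame = {}
    for ev in groups:
        if ev == ev_name:
            frame[ev] = grid
        elif ev in categorical or catalog.entries[ev][0][1].type_tag == "B":
            frame[ev] = np.repeat(ev_train[ev].astype(str).mode().iloc[0], len(grid))
        else:
            frame[ev] = np.full(len(grid), float(np.asarray(ev_train[ev], float).mean()))
    sub_cat = catalog.subset(groups)
    dv = sub_cat.transform(pd.DataFrame(frame))
    lin = dv[model.dv_names_].to_numpy() @ model.beta_
    if model.algorithm == "maxent":
        resp = np.exp(model.alpha_ + lin)
    else:
        from scipy.special import expit

        resp = expit(model.intercept_ + lin)
    return pd.DataFrame({ev_name: grid, "response": resp})


def report_coefficients(model: MaxentModel, catalog: DVCatalog | None = None) -> pd.DataFrame:
    """Coefficient table sorted by |beta| descending.

    DVs are scaled to [0, 1], so coefficient magnitudes are directly
    comparable.  The normalizer alpha and background count N (maxent) or
    the intercept (LR) are appended as extra rows.
    """
    rows = []
    ev_of = {}
    tag_of = {}
    if catalog is not None:
        for ev, fns in catalog.entries.items():
            for name, fn in fns:
                ev_of[name] = ev
                tag_of[name] = fn.type_tag
    for name, beta in zip(model.dv_names_, model.beta_):
        rows.append(
            {
                "dv": name,
                "ev": ev_of.get(name, name.rsplit("_", 1)[0]),
                "type": tag_of.get(name, name.rsplit("_", 1)[-1].rstrip("0123456789")),
                "beta": float(beta),
            }
        )
    rows.sort(key=lambda r: -abs(r["beta"]))
    if model.algorithm == "maxent":
        rows.append({"dv": "(alpha)", "ev": "", "type": "", "beta": model.alpha_})
        rows.append({"dv": "(N)", "ev": "", "type": "", "beta": float(model.n_background_)})
    else:
        rows.append({"dv": "(intercept)", "ev": "", "type": "", "beta": model.intercept_})
    return pd.DataFrame(rows, columns=["dv", "ev", "type", "beta"])
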