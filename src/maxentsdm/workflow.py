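"""End-to-end modelling workflow and the pipeline estimator.

``DistributionModel`` wraps the whole statistical approach — derived-
variable transformation, two-stage forward subset selection, and
maximum-entropy (or logistic-regression) fitting — behind the familiar
fit/predict estimator contract, so it composes with sklearn model
selection.  ``run_workflow`` drives the same pipeline from a plain-text
config, writing every artifact (training table, DV catalogue, selection
trails, model file, response curves, projection, evaluation report) to an
output directory; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import interrogate, selection
from .explore import compute_fop, plot_fop
from .evaluate import test_auc
from .fitting import MaxentModel
from .io_tabular import OccurrenceTable
from .transform import ALL_TYPES, DVCatalog, DerivedVariables

__all__ = ["DistributionModel", "RunConfig", "run_workflow"]

logger = logging.getLogger(__name__)


class DistributionModel(BaseEstimator):
    """Transform -> select -> fit pipeline as a single estimator.

    Parameters mirror the workflow defaults: all transformation types on,
    alpha = 0.01 at both selection stages, maximum-entropy fitting.

    After ``fit(X, y)`` (X: EV DataFrame; y: 1/0/NaN response):

    - ``transformer_`` / ``catalog_``: the fitted DV transformations
    - ``dv_selection_``: per-EV stage-one SelectionResult
    - ``selection_``: stage-two SelectionResult (trail in audit format)
    - ``model_``: the selected MaxentModel
    - ``predict(X)``: PRO values (maxent) or probabilities (LR)
    """

    def __init__(
        self,
        types=ALL_TYPES,
        alpha_dv: float = 0.01,
        alpha_ev: float = 0.01,
        algorithm: str = "maxent",
        bg_weight: float = 100.0,
        n_knots: int = 20,
        interaction: bool = False,
        formula_start=None,
        categorical=None,
    ):
        self.types = types
        self.alpha_dv = alpha_dv
        self.alpha_ev = alpha_ev
        self.algorithm = algorithm
        self.bg_weight = bg_weight
        self.n_knots = n_knots
        self.interaction = interaction
        self.formula_start = formula_start
        self.categorical = categorical

    def fit(self, X: pd.DataFrame, y):
        rv = np.asarray(y, dtype=float)
        self.transformer_ = DerivedVariables(
            types=self.types,
            n_knots=self.n_knots,
            algorithm=self.algorithm,
            bg_weight=self.bg_weight,
            categorical=self.categorical,
        ).fit(X, rv)
        self.catalog_ = self.transformer_.catalog_
        dv = self.transformer_.transform(X)
        self.dv_selection_ = selection.select_dv_for_ev(
            self.catalog_, dv, rv,
            alpha=self.alpha_dv, algorithm=self.algorithm, bg_weight=self.bg_weight,
        )
        sets = {ev: r.selected[ev] for ev, r in self.dv_selection_.items() if r.selected}
        if not sets:
            warnings.warn("no EV passed DV selection; model is the null model", UserWarning)
            from .fitting import fit_model

            self.selection_ = selection.SelectionResult(
                {}, pd.DataFrame(columns=selection.TRAIL_COLUMNS),
                fit_model(dv[[]], rv, algorithm=self.algorithm, bg_weight=self.bg_weight),
            )
        else:
            self.selection_ = selection.select_ev(
                sets, dv, rv,
                alpha=self.alpha_ev, interaction=self.interaction,
                formula_start=self.formula_start, algorithm=self.algorithm,
                bg_weight=self.bg_weight,
            )
        self.model_ = self.selection_.final_model
        return self

    @property
    def selected_evs_(self):
        return [ev for ev in self.selection_.selected if ":" not in ev]

    def predict(self, X: pd.DataFrame, clamp: bool = False):
        dv = self.transformer_.transform(X, clamp=clamp)
        cols = self.model_.dv_names_
        for c in cols:
            if c not in dv.columns:  # interaction products
                a, rest = c.split(":", 1)
                raise KeyError(f"DV {c!r} not reproducible from EV data")
        return self.model_.predict(dv[cols])


# ----------------------------------------------------------------------


@dataclass
class RunConfig:
    """Plain-text workflow configuration (see docs/methods.md)."""

    train_csv: str
    out_dir: str
    rv_col: str = "RV"
    categorical: list = field(default_factory=list)
    algorithm: str = "maxent"
    types: list = field(default_factory=lambda: list(ALL_TYPES))
    alpha_dv: float = 0.01
    alpha_ev: float = 0.01
    bg_weight: float = 100.0
    n_knots: int = 20
    interaction: bool = False
    formula_start: list | None = None
    clamp: bool = False
    seed: int = 0
    fop_evs: list = field(default_factory=list)
    test_csv: str | None = None

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_workflow(config: RunConfig) -> Path:
    """Run import -> FOP -> derive -> selectDV -> selectEV -> project ->
    evaluate, writing all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    t0 = _stage("import")
    table = OccurrenceTable.from_csv(
        config.train_csv, rv_col=config.rv_col,
        categorical=set(config.categorical) if config.categorical else None,
    )
    table.to_csv(out / "train.csv")
    logger.info(
        "rows=%d presences=%d (%.2fs)", len(table.df), table.n_presence, time.time() - t0
    )

    t0 = _stage("fop")
    for ev in config.fop_evs or table.ev_names[:1]:
        s = compute_fop(table, ev)
        s.bins.to_csv(out / f"fop_{ev}.csv", index=False)
        plot_fop(s, out / f"fop_{ev}.png")

    t0 = _stage("derive+select+fit")
    est = DistributionModel(
        types=tuple(config.types),
        alpha_dv=config.alpha_dv,
        alpha_ev=config.alpha_ev,
        algorithm=config.algorithm,
        bg_weight=config.bg_weight,
        n_knots=config.n_knots,
        interaction=config.interaction,
        formula_start=config.formula_start,
        categorical=table.categorical,
    )
    est.fit(table.ev, table.response)
    est.catalog_.to_json(out / "dv_catalog.json")
    for ev, res in est.dv_selection_.items():
        selection.write_trail(res.trail, out / f"trail_dv_{ev}.csv")
    selection.write_trail(est.selection_.trail, out / "trail_ev.csv")
    est.model_.to_json(out / "model.json")
    interrogate.report_coefficients(est.model_, est.catalog_).to_csv(
        out / "coefficients.csv", index=False
    )
    logger.info(
        "selected %d EVs, m=%d, Dsq=%.4f (%.2fs)",
        len(est.selected_evs_), est.model_.m_, est.model_.dsq_, time.time() - t0,
    )

    t0 = _stage("respond+project")
    dv = est.transformer_.transform(table.ev)
    for ev in est.selected_evs_:
        curve = interrogate.response_single(
            est.model_, est.catalog_, dv, table.response, ev
        )
        curve.to_csv(out / f"response_{ev}.csv", index=False)
    proj = interrogate.project_model(est.model_, est.catalog_, table.ev, clamp=config.clamp)
    pd.DataFrame({"prediction": proj.predictions}).to_csv(out / "projection.csv", index=False)
    proj.ranges.to_csv(out / "projection_ranges.csv", index=False)

    t0 = _stage("evaluate")
    if config.test_csv:
        test = OccurrenceTable.from_csv(
            config.test_csv, rv_col=config.rv_col,
            categorical=set(config.categorical) if config.categorical else None,
        )
        preds = est.predict(test.ev, clamp=config.clamp)
        roc = test_auc(preds, test.response)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roc = test_auc(np.asarray(proj.predictions), table.response)
    report = {
        "algorithm": config.algorithm,
        "n_rows": len(table.df),
        "n_presence": table.n_presence,
        "selected_evs": est.selected_evs_,
        "m": est.model_.m_,
        "Dsq": est.model_.dsq_,
        "auc": roc.auc,
        "auc_presence_only": roc.presence_only,
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return out
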