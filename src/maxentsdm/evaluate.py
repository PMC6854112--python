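"""Model evaluation: ROC/AUC and spatially stratified block cross-validation.

Discrimination ability is quantified as the area under the receiver
operating characteristic.  With presence-only data the "negatives" are
uninformed background locations, which biases AUC downward relative to the
presence-absence quantity, so presence-only AUC is always flagged with a
warning.  For cross-validation without independent evaluation data,
records are split into four spatial blocks by lines of longitude and
latitude chosen so the blocks hold (as near as possible) equal numbers of
presence records; background locations fall into the same four rectangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .fitting import fit_model, is_background
from .selection import select_dv_for_ev, select_ev
from .transform import DerivedVariables

__all__ = ["ROCResult", "test_auc", "block_partition", "cv_complexity_grid"]


@dataclass
class ROCResult:
    auc: float
    curve: pd.DataFrame  # columns fpr, tpr, threshold
    n_pos: int
    n_neg: int
    presence_only: bool

    def plot(self, path=None, ax=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        own = ax is None
        if own:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.curve["fpr"], self.curve["tpr"], "-", color="0.2")
        ax.plot([0, 1], [0, 1], ":", color="0.6")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {self.auc:.3f}")
        if path is not None:
            ax.figure.savefig(path, dpi=100)
            plt.close(ax.figure)
            return path
        return ax


def test_auc(predictions, labels) -> ROCResult:
    """AUC and ROC curve for predictions against occurrence labels.

    ``labels`` uses 1 for presence, 0 for absence and NaN for background;
    with no absences, background rows serve as negatives and a
    presence-only warning is emitted.  Ties follow the rank (Mann-Whitney)
    convention: the trapezoidal area of the curve over all distinct
    thresholds equals U / (n1 * n0).
    """
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos = y == 1.0
    neg = y == 0.0
    presence_only = not neg.any()
    if presence_only:
        neg = is_background(y)
        if not neg.any():
            raise ValueError("no absences and no background rows to evaluate against")
        warnings.warn(
            "AUC computed with presence-only data: background locations are "
            "used as negatives, which is not comparable to presence-absence AUC",
            UserWarning,
        )
    if not pos.any():
        raise ValueError("no presence rows to evaluate")
    keep = pos | neg
    yy = pos[keep].astype(int)
    pp = preds[keep]
    if np.all(pp == pp[0]):
        warnings.warn("constant predictions; AUC is 0.5 by the tie convention", UserWarning)
        curve = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "threshold": [np.inf, pp[0]]})
        return ROCResult(0.5, curve, int(pos.sum()), int(neg.sum()), presence_only)
    fpr, tpr, thr = roc_curve(yy, pp, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return ROCResult(auc, curve, int(pos.sum()), int(neg.sum()), presence_only)


def block_partition(xy, rv=None, k: int = 4, lon_first: bool = True):
    """Four spatial blocks with equal presence counts.

    Splits the presence records at the median longitude into two halves
    differing by at most one record, then splits each half at its own
    median latitude the same way.  If ``rv`` is given, the split lines are
    computed from presence rows only and every row (background included) is
    assigned to the same four geographic rectangles.  Returns an integer
    label array in {0, 1, 2, 3}; the partition is invariant to row order.
    """
    if k != 4:
        raise ValueError("block partitioning is defined for k = 4")
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (n, 2) array of coordinates")
    if rv is not None:
        pres_mask = np.asarray(rv, dtype=float) == 1.0
    else:
        pres_mask = np.ones(len(xy), dtype=bool)
    pres = xy[pres_mask]
    if len(pres) < k:
        raise ValueError("need at least k presence records")
    a, b = (0, 1) if lon_first else (1, 0)

    def split_bound(vals):
        """Boundary so that #(v <= bound) = ceil(n/2), up to ties."""
        order = np.sort(vals)
        n = len(order)
        hi_idx = (n + 1) // 2 - 1  # last index of the lower half
        bound = order[hi_idx]
        if hi_idx + 1 < n and order[hi_idx + 1] == bound:
            warnings.warn(
                "duplicate coordinates straddle a block boundary; "
                "achieving the nearest possible equal split",
                UserWarning,
            )
        return bound

    b1 = split_bound(pres[:, a])
    left = pres[:, a] <= b1
    b2_left = split_bound(pres[left, b])
    b2_right = split_bound(pres[~left, b])

    labels = np.empty(len(xy), dtype=int)
    all_left = xy[:, a] <= b1
    labels[all_left & (xy[:, b] <= b2_left)] = 0
    labels[all_left & (xy[:, b] > b2_left)] = 1
    labels[~all_left & (xy[:, b] <= b2_right)] = 2
    labels[~all_left & (xy[:, b] > b2_right)] = 3
    return labels


def cv_complexity_grid(
    table,
    alphas,
    k: int = 4,
    transform_types=("L", "M", "D", "HF", "HR", "T", "B"),
    algorithm: str = "maxent",
    bg_weight: float = 100.0,
    n_knots: int = 20,
):
    """AUC under varying selection strictness by block cross-validation.

    For every alpha and every spatial fold the full pipeline (derive ->
    DV selection -> EV selection) is rerun on the training folds and AUC is
    measured on the held-out fold (its presences against its background).
    Returns (grid DataFrame with columns alpha/fold/auc, best alpha by mean
    AUC).
    """
    if table.coords is None:
        raise ValueError("coordinates are required for block cross-validation")
    if len(list(alphas)) == 0:
        raise ValueError("alphas must be nonempty")
    rv = np.asarray(table.response, dtype=float)
    folds = block_partition(table.coords.to_numpy(), rv=rv, k=k)
    rows = []
    for alpha in alphas:
        for fold in range(k):
            test = folds == fold
            train = ~test
            if (rv[test] == 1).sum() < 1 or (rv[train] == 1).sum() < 1:
                warnings.warn(f"fold {fold} has no presences; skipped", UserWarning)
                continue
            dver = DerivedVariables(
                types=transform_types,
                algorithm=algorithm,
                bg_weight=bg_weight,
                n_knots=n_knots,
                categorical=table.categorical,
            )
            X_train = table.ev[train]
            dver.fit(X_train, rv[train])
            dv_train = dver.transform(X_train)
            stage1 = select_dv_for_ev(
                dver.catalog_, dv_train, rv[train], alpha=alpha,
                algorithm=algorithm, bg_weight=bg_weight,
            )
            sets = {ev: r.selected[ev] for ev, r in stage1.items() if r.selected}
            if not sets:
                auc = 0.5
            else:
                result = select_ev(
                    sets, dv_train, rv[train], alpha=alpha,
                    algorithm=algorithm, bg_weight=bg_weight,
                )
                dv_test = dver.transform(table.ev[test])
                preds = result.final_model.predict(dv_test[result.final_model.dv_names_])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    auc = test_auc(preds, rv[test]).auc
            rows.append({"alpha": alpha, "fold": fold, "auc": auc})
    grid = pd.DataFrame(rows, columns=["alpha", "fold", "auc"])
    best = grid.groupby("alpha")["auc"].mean().idxmax()
    return grid, best
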