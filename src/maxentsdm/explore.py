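"""Exploration of occurrence-environment relationships.

Frequency of observed presence (FOP) is the share of presence records among
all records within an interval (continuous EV) or level (categorical EV).
Plotted together with the data density it shows where along an
environmental gradient the modelled target is observed, and how well each
part of the gradient is sampled.  The smoothed FOP curve also supplies the
estimated optimum used by the deviation transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FOPSummary", "compute_fop", "plot_fop"]


@dataclass
class FOPSummary:
    ev_name: str
    continuous: bool
    bins: pd.DataFrame  # columns: bin (center or level), n_total, n_presence, fop, density[, smooth_fop]
    optimum: object  # EV value (continuous) or level (categorical) of peak smoothed FOP
    smoother_span: float | None = None
    n_bins: int | None = None


def _local_quadratic(x, y, w, span):
    """Weighted local polynomial (degree 2) smoother on a small grid.

    For each grid point, fits a quadratic by weighted least squares to the
    points inside a window spanning ``span`` of the grid width, with tricube
    distance weights multiplied by the supplied weights.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    out = np.empty_like(y)
    half = max(span * (x.max() - x.min()) / 2.0, 1e-12)
    for i, xi in enumerate(x):
        d = np.abs(x - xi)
        inside = d <= half
        # widen until at least 3 points are available for a quadratic
        if inside.sum() < 3:
            order = np.argsort(d)
            inside = np.zeros_like(inside)
            inside[order[:3]] = True
            half_i = max(d[order[:3]].max(), 1e-12)
        else:
            half_i = half
        tric = (1 - np.minimum(d[inside] / half_i, 1.0) ** 3) ** 3
        ww = tric * w[inside] + 1e-12
        deg = 2 if inside.sum() >= 3 else inside.sum() - 1
        coeffs = np.polynomial.polynomial.polyfit(x[inside] - xi, y[inside], deg, w=np.sqrt(ww))
        out[i] = coeffs[0]
    return out


def default_n_bins(n_rows: int) -> int:
    return max(5, min(100, n_rows // 10))


def compute_fop(
    table,
    ev_name: str,
    n_bins: int | None = None,
    smoother_span: float = 0.5,
) -> FOPSummary:
    """Binned frequency of observed presence for one EV.

    ``table`` is an OccurrenceTable (or anything exposing ``.response`` and
    ``.ev``).  Background rows count toward bin totals but not presences, so
    FOP is presence share per bin.  Continuous EVs get equal-width bins over
    the observed range, a local quadratic fit (weighted by bin totals) and
    the smoothed-curve argmax as the optimum; categorical EVs get one bin
    per level with the highest-FOP level as optimum.
    """
    rv = np.asarray(table.response, dtype=float)
    x = table.ev[ev_name]
    pres = rv == 1.0
    if pres.sum() < 1:
        raise ValueError("FOP requires at least one presence row")
    if pres.all():
        warnings.warn(
            "all rows are presences; FOP is identically 1 and carries no contrast",
            UserWarning,
        )

    continuous = ev_name not in table.categorical
    if continuous:
        xv = np.asarray(x, dtype=float)
        if n_bins is None:
            n_bins = default_n_bins(len(xv))
        edges = np.linspace(np.min(xv), np.max(xv), n_bins + 1)
        # right-inclusive last edge so the max value lands in the last bin
        idx = np.clip(np.digitize(xv, edges[1:-1]), 0, n_bins - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        n_total = np.bincount(idx, minlength=n_bins)
        n_pres = np.bincount(idx, weights=pres.astype(float), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            fop = np.where(n_total > 0, n_pres / np.maximum(n_total, 1), np.nan)
        density = n_total / n_total.sum()
        keep = n_total > 0
        smooth = np.full(n_bins, np.nan)
        if keep.sum() >= 2:
            smooth[keep] = _local_quadratic(
                centers[keep], fop[keep], n_total[keep], smoother_span
            )
        else:
            smooth[keep] = fop[keep]
        # The optimum drives the deviation transformation, so it must not be
        # an edge-extrapolation artifact of the local fit at near-empty tail
        # bins: restrict the argmax to bins with at least half the mean
        # occupancy of nonempty bins (and never fewer than 2 rows).
        support = n_total >= max(2.0, 0.5 * n_total[keep].mean())
        if not support.any():
            support = keep
        opt = float(centers[support][np.nanargmax(smooth[support])])
        df = pd.DataFrame(
            {
                "bin": centers,
                "n_total": n_total,
                "n_presence": n_pres.astype(int),
                "fop": fop,
                "smooth_fop": smooth,
                "density": density,
            }
        )
        return FOPSummary(ev_name, True, df, opt, smoother_span, n_bins)

    levels, idx = np.unique(np.asarray(x, dtype=object).astype(str), return_inverse=True)
    n_total = np.bincount(idx, minlength=len(levels))
    n_pres = np.bincount(idx, weights=pres.astype(float), minlength=len(levels))
    fop = n_pres / n_total
    df = pd.DataFrame(
        {
            "bin": levels,
            "n_total": n_total,
            "n_presence": n_pres.astype(int),
            "fop": fop,
            "density": n_total / n_total.sum(),
        }
    )
    opt = str(levels[int(np.argmax(fop))])
    return FOPSummary(ev_name, False, df, opt)


def plot_fop(summary: FOPSummary, path=None, ax=None):
    """Render a FOP summary: binned FOP, smoothed curve, density band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 4))
    df = summary.bins
    if summary.continuous:
        ax2 = ax.twinx()
        width = (df["bin"].iloc[-1] - df["bin"].iloc[0]) / max(len(df) - 1, 1)
        ax2.bar(df["bin"], df["density"], width=width, color="0.85", zorder=0)
        ax2.set_ylabel("data density")
        ax2.set_ylim(0, df["density"].max() * 3 if df["density"].max() > 0 else 1)
        ax.plot(df["bin"], df["fop"], "ko", ms=3, zorder=3, label="FOP")
        ax.plot(df["bin"], df["smooth_fop"], "r-", zorder=4, label="smoothed")
        ax.axvline(summary.optimum, color="r", ls=":", lw=0.8)
        ax.set_zorder(ax2.get_zorder() + 1)
        ax.patch.set_visible(False)
        ax.legend(loc="best", fontsize=8)
    else:
        ax.bar(df["bin"], df["fop"], color="0.4")
    ax.set_xlabel(summary.ev_name)
    ax.set_ylabel("frequency of observed presence")
    if path is not None:
        ax.figure.savefig(path, dpi=100)
        plt.close(ax.figure)
        return path
    return ax
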