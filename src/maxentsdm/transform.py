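"""Derived-variable transformation of explanatory variables.

Each explanatory variable (EV) is expanded into candidate derived variables
(DVs) by up to seven transformation types, each of which permits a unimodal
— or truncated-unimodal — response to the original gradient:

=====  =======================  ==========================================
tag    name                     raw form (before [0,1] rescaling)
=====  =======================  ==========================================
L      linear                   x
M      monotonous               zero-skewness transform of x
D      deviation                |x - optimum|^gamma, gamma in {0.5, 1, 2}
HF     forward hinge            max(0, x - k)
HR     reverse hinge            max(0, k - x)
T      threshold                1[x > k]
B      binary                   1[x == level]   (categorical EVs)
=====  =======================  ==========================================

All DVs are linearly rescaled so that the training column spans [0, 1]
(threshold/binary DVs take values in {0, 1}).  Because of this common scale
the magnitudes of fitted coefficients are directly comparable.  Every DV
carries its parameterized transformation function, so a model is
self-contained and can be re-applied to arbitrary new EV values; values
outside the training range map outside [0, 1] unless clamping is requested
at projection time.

Hinge and threshold candidates are generated on a grid of knots and
*preselected*: each candidate is fitted alone against the response and only
knots at local maxima of the D-squared-versus-knot sequence are retained.
DV names embed the EV name and transformation metadata, e.g. ``slope_D2``
(squared deviation from the FOP optimum of ``slope``) or ``slope_HF4``
(forward hinge at the 4th candidate knot).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin

from . import fitting
from .explore import compute_fop

__all__ = [
    "TransformFn",
    "DVCatalog",
    "DerivedVariables",
    "DegenerateEVError",
    "linear_dv",
    "zero_skewness_dv",
    "deviation_dv",
    "spline_dvs",
    "binary_dvs",
    "derive_vars",
    "local_maxima",
]

DEVIATION_EXPONENTS = ((0.5, "05"), (1.0, "1"), (2.0, "2"))


class DegenerateEVError(ValueError):
    """Raised when an EV carries no usable variation."""


def _skewness(x):
    x = np.asarray(x, float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    return m3 / m2**1.5


@dataclass
class TransformFn:
    """A serializable, parameterized map from one EV to one DV in [0, 1]."""

    ev_name: str
    type_tag: str  # L, M, D, HF, HR, T, B
    params: dict = field(default_factory=dict)
    out_min_raw: float = 0.0
    out_max_raw: float = 1.0

    def raw(self, x):
        t = self.type_tag
        p = self.params
        if t == "B":
            return (np.asarray(x, dtype=object).astype(str) == str(p["level"])).astype(float)
        x = np.asarray(x, dtype=float)
        if t == "L":
            return x
        if t == "M":
            fam = p["family"]
            if fam == "log":
                return np.log(p["c"] + x)
            if fam == "exp":
                # exp(c*(x - shift)); the shift only rescales, never reorders
                return np.exp(p["c"] * (x - p["shift"]))
            return x  # identity fallback
        if t == "D":
            return np.abs(x - p["optimum"]) ** p["exponent"]
        if t == "HF":
            return np.maximum(0.0, x - p["knot"])
        if t == "HR":
            return np.maximum(0.0, p["knot"] - x)
        if t == "T":
            return (x > p["knot"]).astype(float)
        raise ValueError(f"unknown transformation tag {t!r}")

    def __call__(self, x):
        r = self.raw(x)
        span = self.out_max_raw - self.out_min_raw
        if span == 0:
            raise DegenerateEVError(f"degenerate rescaling for {self.ev_name}_{self.type_tag}")
        return (r - self.out_min_raw) / span

    def fit_rescale(self, train_values):
        r = self.raw(train_values)
        self.out_min_raw = float(np.min(r))
        self.out_max_raw = float(np.max(r))
        return self

    def to_dict(self):
        return {
            "ev_name": self.ev_name,
            "type_tag": self.type_tag,
            "params": self.params,
            "out_min_raw": self.out_min_raw,
            "out_max_raw": self.out_max_raw,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


# ----------------------------------------------------------------------
# individual transformation builders


def _check_continuous(ev_values, ev_name):
    x = np.asarray(ev_values, dtype=float)
    if np.min(x) == np.max(x):
        raise DegenerateEVError(f"EV {ev_name!r} is constant")
    return x


def linear_dv(ev_values, ev_name="ev") -> TransformFn:
    """Linear transformation: rescale of the identity to [0, 1]."""
    x = _check_continuous(ev_values, ev_name)
    fn = TransformFn(ev_name, "L", {"train_min": float(x.min()), "train_max": float(x.max())})
    return fn.fit_rescale(x)


def zero_skewness_dv(ev_values, ev_name="ev", tol=1e-9) -> TransformFn:
    """Monotonous transformation driving sample skewness to zero.

    Right-skewed EVs use log(c + x) with c > -min(x); left-skewed EVs use
    exp(c * (x - max(x))) with c > 0 (the shift prevents overflow and does
    not affect skewness).  The constant c is found by root bracketing and
    Brent's method on the skewness of the transformed sample; if no root is
    bracketed the transformation falls back to linear with a warning.
    """
    x = _check_continuous(ev_values, ev_name)
    if len(np.unique(x)) < 3:
        raise DegenerateEVError(f"EV {ev_name!r} has fewer than 3 distinct values")
    g = _skewness(x)
    params = {"train_min": float(x.min()), "train_max": float(x.max())}
    if abs(g) <= tol:
        fn = TransformFn(ev_name, "M", {**params, "family": "identity", "c": 0.0})
        return fn.fit_rescale(x)
    try:
        if g > 0:
            rng = x.max() - x.min()
            lo = -x.min() + 1e-9 * max(rng, abs(x.min()), 1.0)
            hi = max(1.0, -x.min() + rng)
            f = lambda c: _skewness(np.log(c + x))
            for _ in range(60):
                if f(hi) > 0:
                    break
                hi *= 4.0
            else:
                raise ValueError("no sign change")
            if f(lo) > 0:
                raise ValueError("no sign change")
            c = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=500)
            fn = TransformFn(ev_name, "M", {**params, "family": "log", "c": float(c)})
        else:
            shift = float(x.max())
            scale = float(np.std(x)) or 1.0
            f = lambda c: _skewness(np.exp(c * (x - shift)))
            lo, hi = 1e-12 / scale, 1.0 / scale
            for _ in range(60):
                if f(hi) > 0:
                    break
                hi *= 4.0
            else:
                raise ValueError("no sign change")
            c = brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16, maxiter=500)
            fn = TransformFn(ev_name, "M", {**params, "family": "exp", "c": float(c), "shift": shift})
    except ValueError:
        warnings.warn(
            f"zero-skewness root not bracketed for EV {ev_name!r}; falling back to linear",
            UserWarning,
        )
        fn = TransformFn(ev_name, "M", {**params, "family": "identity", "c": 0.0})
    return fn.fit_rescale(x)


def deviation_dv(ev_values, fop_optimum, ev_name="ev") -> list[tuple[str, TransformFn]]:
    """Deviation transformations |x - optimum|^gamma for gamma 0.5, 1, 2."""
    x = _check_continuous(ev_values, ev_name)
    if fop_optimum is None or not np.isfinite(fop_optimum):
        warnings.warn(
            f"FOP optimum undefined for EV {ev_name!r}; using the EV median", UserWarning
        )
        fop_optimum = float(np.median(x))
    out = []
    for gamma, suffix in DEVIATION_EXPONENTS:
        fn = TransformFn(
            ev_name,
            "D",
            {
                "train_min": float(x.min()),
                "train_max": float(x.max()),
                "optimum": float(fop_optimum),
                "exponent": gamma,
            },
        ).fit_rescale(x)
        out.append((f"{ev_name}_D{suffix}", fn))
    return out


def local_maxima(values) -> np.ndarray:
    """Indices of local maxima of a sequence (endpoints count if greater
    than their single neighbour)."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return np.array([], dtype=int)
    if len(v) == 1:
        return np.array([0])
    keep = []
    for i in range(len(v)):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < len(v) - 1 else -np.inf
        if v[i] > left and v[i] > right:
            keep.append(i)
        elif v[i] == left and v[i] > right and i > 0:
            # plateau: keep the first index of a plateau that is a maximum
            pass
    return np.array(keep, dtype=int)


def spline_dvs(
    ev_values,
    rv,
    kind: str,
    ev_name="ev",
    n_knots: int = 20,
    algorithm: str = "maxent",
    bg_weight: float = 100.0,
) -> list[tuple[str, TransformFn]]:
    """Hinge/threshold candidates on a knot grid, preselected by D-squared.

    ``n_knots`` candidate knots are evenly spaced strictly inside the
    training range.  Each candidate DV is fitted alone against the response
    and only knots at local maxima of the D-squared sequence are retained;
    names index knots by their rank on the grid (1-based).
    """
    if kind not in ("HF", "HR", "T"):
        raise ValueError(f"spline kind must be HF, HR or T, got {kind!r}")
    x = _check_continuous(ev_values, ev_name)
    if len(np.unique(x)) < 3:
        warnings.warn(
            f"EV {ev_name!r} has fewer than 3 distinct values; no {kind} DVs", UserWarning
        )
        return []
    lo, hi = float(x.min()), float(x.max())
    knots = lo + (hi - lo) * np.arange(1, n_knots + 1) / (n_knots + 1)
    cands = []
    dsqs = []
    base = {"train_min": lo, "train_max": hi}
    for rank, k in enumerate(knots, start=1):
        fn = TransformFn(ev_name, kind, {**base, "knot": float(k)})
        raw = fn.raw(x)
        if raw.min() == raw.max():  # no variation at this knot
            continue
        fn.fit_rescale(x)
        col = fn(x)
        model = fitting.fit_model(
            pd.DataFrame({f"{ev_name}_{kind}{rank}": col}),
            rv,
            algorithm=algorithm,
            bg_weight=bg_weight,
        )
        cands.append((rank, fn))
        dsqs.append(model.dsq_)
    keep = set(local_maxima(dsqs))
    return [
        (f"{ev_name}_{kind}{rank}", fn)
        for i, (rank, fn) in enumerate(cands)
        if i in keep
    ]


def binary_dvs(ev_values, ev_name="ev") -> list[tuple[str, TransformFn]]:
    """One indicator DV per level of a categorical EV."""
    levels = sorted(pd.unique(np.asarray(ev_values, dtype=object).astype(str)))
    if len(levels) < 2:
        warnings.warn(f"categorical EV {ev_name!r} has a single level; no DVs", UserWarning)
        return []
    out = []
    for i, lev in enumerate(levels, start=1):
        fn = TransformFn(ev_name, "B", {"level": lev}, 0.0, 1.0)
        out.append((f"{ev_name}_B{i}", fn))
    return out


# ----------------------------------------------------------------------


class DVCatalog:
    """Ordered catalogue of (dv_name, TransformFn) per EV."""

    def __init__(self, entries: dict[str, list[tuple[str, TransformFn]]]):
        self.entries = entries
        names = [n for fns in entries.values() for n, _ in fns]
        if len(names) != len(set(names)):
            raise ValueError("duplicate DV names in catalog")

    @property
    def ev_names(self):
        return list(self.entries)

    @property
    def groups(self) -> dict[str, list[str]]:
        return {ev: [n for n, _ in fns] for ev, fns in self.entries.items()}

    @property
    def dv_names(self):
        return [n for fns in self.entries.values() for n, _ in fns]

    def subset(self, selected: dict[str, list[str]]) -> "DVCatalog":
        out = {}
        for ev, names in selected.items():
            fns = dict(self.entries[ev])
            out[ev] = [(n, fns[n]) for n in names]
        return DVCatalog(out)

    def transform(self, ev_data: pd.DataFrame, clamp: bool = False) -> pd.DataFrame:
        """Apply every stored transformation to new EV columns."""
        cols = {}
        for ev, fns in self.entries.items():
            if ev not in ev_data.columns:
                raise KeyError(f"EV {ev!r} missing from input data")
            x = ev_data[ev]
            if clamp and fns and fns[0][1].type_tag != "B":
                tmin = fns[0][1].params.get("train_min")
                tmax = fns[0][1].params.get("train_max")
                x = np.clip(np.asarray(x, dtype=float), tmin, tmax)
            for name, fn in fns:
                cols[name] = fn(x)
        return pd.DataFrame(cols, index=ev_data.index)

    def to_dict(self):
        return {
            ev: [[name, fn.to_dict()] for name, fn in fns]
            for ev, fns in self.entries.items()
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            {
                ev: [(name, TransformFn.from_dict(fd)) for name, fd in fns]
                for ev, fns in d.items()
            }
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


ALL_TYPES = ("L", "M", "D", "HF", "HR", "T", "B")


class DerivedVariables(TransformerMixin, BaseEstimator):
    """Transformer deriving candidate DVs from EV columns.

    Follows the fit/transform contract: ``fit(X, y)`` learns the
    parameterized transformations from training EVs ``X`` (a DataFrame;
    object/category columns are treated as categorical) and the response
    ``y`` (1 presence / 0 absence / NaN background, needed for the
    deviation optimum and the spline preselection); ``transform(X)``
    produces the DV design for any EV data.
    """

    def __init__(
        self,
        types=ALL_TYPES,
        n_knots: int = 20,
        algorithm: str = "maxent",
        bg_weight: float = 100.0,
        categorical=None,
    ):
        self.types = types
        self.n_knots = n_knots
        self.algorithm = algorithm
        self.bg_weight = bg_weight
        self.categorical = categorical

    def _split_kinds(self, X: pd.DataFrame):
        if self.categorical is not None:
            cat = set(self.categorical)
        else:
            cat = {
                c
                for c in X.columns
                if X[c].dtype == object or isinstance(X[c].dtype, pd.CategoricalDtype)
            }
        return cat

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("the response is required to derive variables")
        types = set(self.types)
        unknown = types - set(ALL_TYPES)
        if unknown:
            raise ValueError(f"unknown transformation types: {sorted(unknown)}")
        if not types:
            raise ValueError("empty transformation type set")
        rv = np.asarray(y, dtype=float)
        cat = self._split_kinds(X)
        entries: dict[str, list[tuple[str, TransformFn]]] = {}
        for ev in X.columns:
            fns: list[tuple[str, TransformFn]] = []
            try:
                if ev in cat:
                    if "B" in types:
                        fns.extend(binary_dvs(X[ev], ev))
                else:
                    xv = np.asarray(X[ev], dtype=float)
                    if "L" in types:
                        fns.append((f"{ev}_L", linear_dv(xv, ev)))
                    if "M" in types:
                        fns.append((f"{ev}_M", zero_skewness_dv(xv, ev)))
                    if "D" in types:
                        opt = self._fop_optimum(xv, rv, ev)
                        fns.extend(deviation_dv(xv, opt, ev))
                    for kind in ("HF", "HR", "T"):
                        if kind in types:
                            fns.extend(
                                spline_dvs(
                                    xv,
                                    rv,
                                    kind,
                                    ev,
                                    n_knots=self.n_knots,
                                    algorithm=self.algorithm,
                                    bg_weight=self.bg_weight,
                                )
                            )
            except DegenerateEVError as err:
                warnings.warn(f"skipping degenerate EV {ev!r}: {err}", UserWarning)
                continue
            if fns:
                entries[ev] = fns
        if not entries:
            raise DegenerateEVError("no usable EVs: all degenerate or no DVs derived")
        self.catalog_ = DVCatalog(entries)
        self.categorical_ = cat
        return self

    @staticmethod
    def _fop_optimum(xv, rv, ev):
        from .io_tabular import OccurrenceTable

        try:
            table = OccurrenceTable(
                pd.DataFrame({"RV": rv, ev: xv}), rv_col="RV", categorical=set()
            )
            return compute_fop(table, ev).optimum
        except ValueError:
            return None

    def transform(self, X: pd.DataFrame, clamp: bool = False) -> pd.DataFrame:
        return self.catalog_.transform(X, clamp=clamp)


def derive_vars(
    table,
    types=ALL_TYPES,
    algorithm: str = "maxent",
    n_knots: int = 20,
    bg_weight: float = 100.0,
):
    """Derive DVs from an OccurrenceTable; returns (catalog, dv_frame)."""
    est = DerivedVariables(
        types=types,
        n_knots=n_knots,
        algorithm=algorithm,
        bg_weight=bg_weight,
        categorical=table.categorical,
    )
    est.fit(table.ev, table.response)
    return est.catalog_, est.transform(table.ev)
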