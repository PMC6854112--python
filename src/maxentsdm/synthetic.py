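"""Seeded synthetic presence-background data with known ground truth.

The generator emulates the shape of real presence-background datasets: a
landscape sample of uninformed background locations with continuous and
categorical environmental variables, and presence locations whose sampling
intensity follows a log-linear model of the environment,

    eta(z) = sum_j f_j(z_j),

with per-variable response shapes that are ecologically standard: linear,
unimodal (Gaussian bump on the log-intensity scale), threshold, or hinge.
Presences are obtained by conditional thinning of candidate locations
drawn from the background distribution, with acceptance probability
proportional to exp(eta) — the discrete presence-background sampling
scheme that maximum-entropy fitting targets.  Sampling bias and detection
error are deliberately not simulated.

Every draw is a pure function of the spec and its seed, so tables are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_tabular import OccurrenceTable

__all__ = [
    "EVSpec",
    "Effect",
    "SyntheticSpec",
    "generate",
    "grassland_shaped_fixture",
    "bradypus_shaped_fixture",
]


@dataclass
class EVSpec:
    """One environmental variable: name, kind and sampling distribution.

    Continuous distributions: ("normal", mean, sd), ("uniform", lo, hi),
    ("lognormal", mu, sigma).  Categorical: dist = ("levels", [labels],
    [probs]).
    """

    name: str
    kind: str = "continuous"  # or "categorical"
    dist: tuple = ("uniform", 0.0, 1.0)

    def draw(self, rng: np.random.Generator, n: int):
        d = self.dist
        if self.kind == "categorical":
            _, labels, probs = d
            return rng.choice(np.asarray(labels, dtype=object), size=n, p=probs)
        if d[0] == "normal":
            return rng.normal(d[1], d[2], n)
        if d[0] == "uniform":
            return rng.uniform(d[1], d[2], n)
        if d[0] == "lognormal":
            return rng.lognormal(d[1], d[2], n)
        raise ValueError(f"unknown distribution {d[0]!r}")


@dataclass
class Effect:
    """Contribution of one EV to the log-intensity eta.

    shapes: "linear"    beta * (x - center) / scale (fixed constants)
            "unimodal"  beta * exp(-((x - optimum) / width)^2)
            "threshold" beta * 1[x > knot]
            "hinge"     beta * max(0, (x - knot) / scale)
            "levels"    per-level offsets (categorical), params["offsets"]
    ``beta`` is the effect size on the log-intensity scale.
    """

    ev: str
    shape: str
    beta: float = 1.0
    params: dict = field(default_factory=dict)

    def eta(self, x):
        p = self.params
        if self.shape == "levels":
            offsets = p["offsets"]
            return np.array([offsets.get(str(v), 0.0) for v in x], dtype=float)
        x = np.asarray(x, dtype=float)
        if self.shape == "linear":
            # fixed constants so the intensity is a pure function of x
            return self.beta * (x - p.get("center", 0.0)) / p.get("scale", 1.0)
        if self.shape == "unimodal":
            return self.beta * np.exp(-(((x - p["optimum"]) / p["width"]) ** 2))
        if self.shape == "threshold":
            return self.beta * (x > p["knot"]).astype(float)
        if self.shape == "hinge":
            return self.beta * np.maximum(0.0, (x - p["knot"]) / p.get("scale", 1.0))
        raise ValueError(f"unknown effect shape {self.shape!r}")


@dataclass
class SyntheticSpec:
    n_background: int = 2000
    n_presence: int = 200
    evs: list = field(default_factory=lambda: [EVSpec("ev1")])
    true_model: list = field(default_factory=list)  # list of Effect
    seed: int = 0
    with_coords: bool = True
    presence_absence: bool = False
    pa_intercept: float = -1.0  # baseline log-odds in presence-absence mode

    def validate(self):
        names = {e.name for e in self.evs}
        for eff in self.true_model:
            if eff.ev not in names:
                raise ValueError(f"true-model EV {eff.ev!r} not among the EVs")
            if not np.isfinite(eff.beta):
                raise ValueError("effect sizes must be finite")
        if self.n_background < 1 or self.n_presence < 1:
            raise ValueError("n_background and n_presence must be positive")


def _eta(spec: SyntheticSpec, frame: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(frame))
    for eff in spec.true_model:
        eta += eff.eta(frame[eff.ev])
    return eta


def generate(spec: SyntheticSpec):
    """Draw an OccurrenceTable and its ground truth from a SyntheticSpec.

    Returns (table, truth) where ``truth`` records the per-row
    log-intensity eta, the true EV set, and the spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = pd.DataFrame({e.name: e.draw(rng, spec.n_background) for e in spec.evs})

    if spec.presence_absence:
        eta = _eta(spec, bg)
        from scipy.special import expit

        p = expit(spec.pa_intercept + eta)
        rv = rng.binomial(1, p).astype(float)
        if rv.sum() < 1:
            raise ValueError("spec produced zero presences; raise intensity or n")
        df = bg.copy()
        df.insert(0, "RV", rv)
        if spec.with_coords:
            df["x"] = rng.uniform(0, 1, len(df))
            df["y"] = rng.uniform(0, 1, len(df))
        table = OccurrenceTable(df, categorical={e.name for e in spec.evs if e.kind == "categorical"})
        return table, {"eta": eta, "true_evs": sorted({e.ev for e in spec.true_model}), "spec": spec}

    # presence-background: thin candidates drawn from the background law
    pres_rows = []
    etas = []
    cap = 200  # batches
    for _ in range(cap):
        need = spec.n_presence - sum(len(p) for p in pres_rows)
        if need <= 0:
            break
        batch = max(4 * need, 64)
        cand = pd.DataFrame({e.name: e.draw(rng, batch) for e in spec.evs})
        eta = _eta(spec, cand)
        accept = rng.uniform(size=batch) < np.exp(eta - eta.max()) if np.any(eta != 0) else np.ones(batch, bool)
        if not np.isfinite(eta).all():
            raise ValueError("non-finite log-intensity; check effect sizes")
        taken = cand[accept].head(need)
        pres_rows.append(taken)
        etas.append(eta[accept][: len(taken)])
    pres = pd.concat(pres_rows, ignore_index=True)
    if len(pres) < spec.n_presence:
        raise ValueError("effective intensity too low to draw the requested presences")

    df = pd.concat([pres, bg], ignore_index=True)
    rv = np.concatenate([np.ones(len(pres)), np.full(len(bg), np.nan)])
    df.insert(0, "RV", rv)
    if spec.with_coords:
        df["x"] = rng.uniform(0, 1, len(df))
        df["y"] = rng.uniform(0, 1, len(df))
    table = OccurrenceTable(df, categorical={e.name for e in spec.evs if e.kind == "categorical"})
    truth = {
        "eta": np.concatenate([np.concatenate(etas), _eta(spec, bg)]),
        "true_evs": sorted({e.ev for e in spec.true_model}),
        "spec": spec,
    }
    return table, truth


def grassland_shaped_fixture(seed: int = 42) -> OccurrenceTable:
    """A table with the shape of a seminatural-grassland training set:
    1,059 presences, 16,420 background locations, 13 EVs (11 continuous,
    2 categorical).  Values are synthetic."""
    evs = [EVSpec(f"cont{i:02d}", "continuous", ("normal", 0.0, 1.0)) for i in range(1, 10)]
    evs += [
        EVSpec("slope", "continuous", ("lognormal", 1.5, 0.6)),
        EVSpec("elev", "continuous", ("uniform", 0.0, 500.0)),
        EVSpec(
            "geology",
            "categorical",
            ("levels", ["g1", "g2", "g3", "g4"], [0.4, 0.3, 0.2, 0.1]),
        ),
        EVSpec("landcover", "categorical", ("levels", ["a", "b", "c"], [0.5, 0.3, 0.2])),
    ]
    effects = [
        Effect("slope", "unimodal", 2.0, {"optimum": 6.0, "width": 4.0}),
        Effect("cont01", "linear", 1.0),
        Effect("geology", "levels", params={"offsets": {"g1": 0.6, "g2": 0.0, "g3": -0.4, "g4": -0.8}}),
    ]
    spec = SyntheticSpec(
        n_background=16420, n_presence=1059, evs=evs, true_model=effects, seed=seed
    )
    table, _ = generate(spec)
    return table


def bradypus_shaped_fixture(seed: int = 7, n_background: int = 2000) -> OccurrenceTable:
    """A table with the shape of the sloth example: 114 presences and 14
    EVs (13 continuous climate-like, 1 categorical vegetation), with
    coordinates for spatial blocking.  Values are synthetic."""
    evs = [EVSpec(f"clim{i:02d}", "continuous", ("normal", 0.0, 1.0)) for i in range(1, 14)]
    evs.append(
        EVSpec("veg", "categorical", ("levels", ["v1", "v2", "v3", "v4", "v5"], [0.3, 0.25, 0.2, 0.15, 0.1]))
    )
    effects = [
        Effect("clim01", "unimodal", 2.5, {"optimum": 0.5, "width": 1.0}),
        Effect("clim02", "linear", 1.5),
    ]
    spec = SyntheticSpec(
        n_background=n_background, n_presence=114, evs=evs, true_model=effects, seed=seed
    )
    table, _ = generate(spec)
    return table
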