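import numpy as np
import pandas as pd
import pytest

from maxentsdm.io_tabular import AsciiGrid, OccurrenceTable
from maxentsdm.synthetic import Effect, EVSpec, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def pb_table():
    """Small presence-background table with one informative continuous EV,
    one noise EV and one categorical EV."""
    spec = SyntheticSpec(
        n_background=600,
        n_presence=120,
        evs=[
            EVSpec("temp", "continuous", ("normal", 0.0, 1.0)),
            EVSpec("noise", "continuous", ("uniform", 0.0, 10.0)),
            EVSpec("soil", "categorical", ("levels", ["a", "b", "c"], [0.5, 0.3, 0.2])),
        ],
        true_model=[Effect("temp", "linear", 2.0)],
        seed=11,
    )
    table, _ = generate(spec)
    return table


@pytest.fixture
def pa_table():
    """Presence-absence table (0/1 response) for the LR path."""
    spec = SyntheticSpec(
        n_background=700,
        n_presence=1,
        evs=[
            EVSpec("temp", "continuous", ("normal", 0.0, 1.0)),
            EVSpec("noise", "continuous", ("uniform", 0.0, 10.0)),
        ],
        true_model=[Effect("temp", "linear", 1.5)],
        seed=5,
        presence_absence=True,
        pa_intercept=-1.0,
    )
    table, _ = generate(spec)
    return table


@pytest.fixture
def toy_grids():
    """Two 4x4 EV rasters sharing a header, with one nodata cell."""
    base = dict(ncols=4, nrows=4, xllcorner=0.0, yllcorner=0.0, cellsize=1.0, nodata_value=-9999.0)
    v1 = np.arange(16, dtype=float).reshape(4, 4)
    v2 = np.arange(16, dtype=float).reshape(4, 4) ** 2 / 10.0
    v2[0, 0] = -9999.0
    return {"ev_a": AsciiGrid(values=v1, **base), "ev_b": AsciiGrid(values=v2, **base)}
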