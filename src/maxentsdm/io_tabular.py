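"""Import and export of occurrence-environment data.

Two entry routes are supported: a single CSV table already holding the
response column plus EV columns, or spatial inputs — occurrence coordinates
as CSV plus one ESRI ASCII grid raster per EV, all sharing one coordinate
reference system.  The response is coded 1 for presence, 0 for absence and
NaN for uninformed background, so presence-background tables are
distinguishable from presence-absence tables (which matters downstream,
e.g. for the presence-only AUC warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceTable",
    "AsciiGrid",
    "AsciiGridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_data",
]

logger = logging.getLogger(__name__)

RV_COL = "RV"


class AsciiGridFormatError(ValueError):
    pass


@dataclass
class AsciiGrid:
    """An ESRI ASCII grid: header plus an nrows-by-ncols value matrix.

    Values are stored as written, with nodata cells equal to
    ``nodata_value``; ``mask`` exposes them as booleans.  The first matrix
    row is the *northernmost* row, per the format.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise AsciiGridFormatError(
                f"value matrix {self.values.shape} does not match header "
                f"({self.nrows}, {self.ncols})"
            )
        if self.ncols <= 0 or self.nrows <= 0 or self.cellsize <= 0:
            raise AsciiGridFormatError("ncols, nrows and cellsize must be positive")

    @property
    def mask(self) -> np.ndarray:
        return self.values == self.nodata_value

    def same_header(self, other: "AsciiGrid") -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and self.xllcorner == other.xllcorner
            and self.yllcorner == other.yllcorner
            and self.cellsize == other.cellsize
        )

    def cell_index(self, x, y):
        """(row, col) of the cell containing each point.

        Cell membership is half-open and lower-left anchored: a point
        belongs to the cell whose extent is [x0, x0+cellsize) x
        [y0, y0+cellsize).  Points outside the grid get row = -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xllcorner) / self.cellsize).astype(int)
        row_from_bottom = np.floor((y - self.yllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_center(self, row, col):
        x = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - 1 - np.asarray(row) + 0.5) * self.cellsize
        return x, y


def read_ascii_grid(path) -> AsciiGrid:
    """Read an ESRI ASCII grid (.asc); accepts the xllcenter dialect."""
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 7:
        raise AsciiGridFormatError(f"{path}: fewer than 6 header lines plus data")
    for line in lines[:6]:
        parts = line.split()
        if len(parts) != 2:
            raise AsciiGridFormatError(f"{path}: malformed header line {line!r}")
        header[parts[0].lower()] = parts[1]
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise AsciiGridFormatError(f"{path}: missing header key {key!r}")
    cellsize = float(header["cellsize"])
    if "xllcorner" in header and "yllcorner" in header:
        xll, yll = float(header["xllcorner"]), float(header["yllcorner"])
    elif "xllcenter" in header and "yllcenter" in header:
        # center dialect: corner = center - cellsize/2
        xll = float(header["xllcenter"]) - cellsize / 2.0
        yll = float(header["yllcenter"]) - cellsize / 2.0
    else:
        raise AsciiGridFormatError(f"{path}: missing xll/yll header keys")
    if "nodata_value" not in header:
        raise AsciiGridFormatError(f"{path}: missing header key 'NODATA_value'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for line in lines[6:]:
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != ncols:
            raise AsciiGridFormatError(
                f"{path}: data row with {len(vals)} values, expected {ncols}"
            )
        rows.append([float(v) for v in vals])
    if len(rows) != nrows:
        raise AsciiGridFormatError(f"{path}: {len(rows)} data rows, expected {nrows}")
    return AsciiGrid(
        ncols=ncols,
        nrows=nrows,
        xllcorner=xll,
        yllcorner=yll,
        cellsize=cellsize,
        nodata_value=float(header["nodata_value"]),
        values=np.array(rows, dtype=float),
    )


def _fmt(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def write_ascii_grid(grid: AsciiGrid, path):
    """Write an ESRI ASCII grid; read(write(g)) is value-identical."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {_fmt(grid.xllcorner)}\n")
        fh.write(f"yllcorner {_fmt(grid.yllcorner)}\n")
        fh.write(f"cellsize {_fmt(grid.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(grid.nodata_value)}\n")
        for row in grid.values:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")
    return path


# ----------------------------------------------------------------------


class OccurrenceTable:
    """Response + EV columns, with EV kind metadata and optional coordinates.

    Parameters
    ----------
    df : DataFrame with the response column and one column per EV
         (continuous: numeric; categorical: labels), optionally ``x``/``y``.
    rv_col : name of the response column (1 / 0 / NaN-for-background).
    categorical : EV names to treat as categorical; defaults to
         object/category-dtype columns.
    """

    def __init__(self, df: pd.DataFrame, rv_col: str = RV_COL, categorical=None):
        if rv_col not in df.columns:
            raise ValueError(f"response column {rv_col!r} not in table")
        if len(df) < 2:
            raise ValueError("occurrence table needs at least 2 rows")
        rv = pd.to_numeric(df[rv_col], errors="coerce")
        if not ((rv.dropna() == 1) | (rv.dropna() == 0)).all():
            raise ValueError("response values must be 1 (presence), 0 (absence) or missing (background)")
        if (rv == 1).sum() < 1:
            raise ValueError("occurrence table needs at least one presence row")
        self.df = df.reset_index(drop=True)
        self.rv_col = rv_col
        ev_cols = [c for c in df.columns if c not in (rv_col, "x", "y")]
        if not ev_cols:
            raise ValueError("no EV columns found")
        for c in ev_cols:
            if df[c].isna().all():
                raise ValueError(f"EV column {c!r} is entirely missing")
        self.ev_names = ev_cols
        if categorical is None:
            categorical = {
                c
                for c in ev_cols
                if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype)
            }
        self.categorical = set(categorical)

    @property
    def response(self) -> pd.Series:
        return pd.to_numeric(self.df[self.rv_col], errors="coerce")

    @property
    def ev(self) -> pd.DataFrame:
        return self.df[self.ev_names]

    @property
    def coords(self):
        if "x" in self.df.columns and "y" in self.df.columns:
            return self.df[["x", "y"]]
        return None

    @property
    def n_presence(self) -> int:
        return int((self.response == 1).sum())

    @property
    def n_absence(self) -> int:
        return int((self.response == 0).sum())

    @property
    def n_background(self) -> int:
        return int(self.response.isna().sum())

    @property
    def presence_only(self) -> bool:
        return self.n_absence == 0

    def to_csv(self, path):
        self.df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, rv_col: str = RV_COL, categorical=None):
        return cls(pd.read_csv(path), rv_col=rv_col, categorical=categorical)


def _extract(grids: dict[str, AsciiGrid], x, y):
    """EV values at point coordinates; NaN where outside or nodata."""
    first = next(iter(grids.values()))
    row, col = first.cell_index(x, y)
    outside = row < 0
    out = {}
    for name, g in grids.items():
        vals = np.full(len(row), np.nan)
        ok = ~outside
        vals[ok] = g.values[row[ok], col[ok]]
        vals[ok & (vals == g.nodata_value)] = np.nan
        # also nodata where the sentinel matched before the mask comparison
        nod = np.zeros(len(row), bool)
        nod[ok] = g.values[row[ok], col[ok]] == g.nodata_value
        vals[nod] = np.nan
        out[name] = vals
    return pd.DataFrame(out), outside


def read_data(
    presence_csv,
    ev_rasters: dict[str, AsciiGrid] | list,
    background_csv_or_n,
    pa_mode: bool = False,
    seed: int = 0,
    categorical=None,
) -> OccurrenceTable:
    """Assemble an OccurrenceTable from coordinates plus EV rasters.

    ``presence_csv`` is a CSV with x,y columns (or a DataFrame).
    ``ev_rasters`` maps EV name to AsciiGrid, or is a list of .asc paths
    (EV names taken from file stems).  ``background_csv_or_n`` is either a
    CSV/DataFrame of background (or absence, with ``pa_mode=True``)
    coordinates, or an integer n of background cells to sample uniformly
    without replacement from cells valid in every raster (seeded).

    Points outside the raster extent or on a nodata cell in any EV are
    dropped with a warning; losing every presence is fatal.
    """
    from pathlib import Path

    if not isinstance(ev_rasters, dict):
        ev_rasters = {Path(p).stem: read_ascii_grid(p) for p in ev_rasters}
    grids = list(ev_rasters.values())
    first = grids[0]
    for g in grids[1:]:
        if not first.same_header(g):
            raise AsciiGridFormatError("EV rasters do not share an identical header")

    pres = presence_csv if isinstance(presence_csv, pd.DataFrame) else pd.read_csv(presence_csv)
    if not {"x", "y"} <= set(pres.columns):
        raise ValueError("presence CSV must have x and y columns")

    def build(points, rv_value):
        ev_df, outside = _extract(ev_rasters, points["x"].to_numpy(), points["y"].to_numpy())
        if outside.any():
            warnings.warn(f"{int(outside.sum())} point(s) outside raster extent dropped", UserWarning)
        nodata = ev_df.isna().any(axis=1).to_numpy()
        n_drop = int((nodata & ~outside).sum())
        if n_drop:
            logger.info("dropped %d point(s) on nodata cells", n_drop)
        keep = ~(outside | nodata)
        out = ev_df[keep].copy()
        out.insert(0, RV_COL, rv_value)
        out["x"] = points["x"].to_numpy()[keep]
        out["y"] = points["y"].to_numpy()[keep]
        return out

    pres_rows = build(pres, 1.0)
    if len(pres_rows) == 0:
        raise ValueError("no valid presence rows after raster extraction")

    if isinstance(background_csv_or_n, (int, np.integer)):
        valid = ~np.any([g.mask for g in grids], axis=0)
        rows, cols = np.nonzero(valid)
        n = int(background_csv_or_n)
        if n > len(rows):
            raise ValueError(f"requested {n} background cells but only {len(rows)} valid cells")
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(rows), size=n, replace=False)
        bx, by = first.cell_center(rows[pick], cols[pick])
        bg = pd.DataFrame({"x": bx, "y": by})
    else:
        bg = (
            background_csv_or_n
            if isinstance(background_csv_or_n, pd.DataFrame)
            else pd.read_csv(background_csv_or_n)
        )
    bg_rows = build(bg, 0.0 if pa_mode else np.nan)
    table = pd.concat([pres_rows, bg_rows], ignore_index=True)
    return OccurrenceTable(table, rv_col=RV_COL, categorical=categorical)
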