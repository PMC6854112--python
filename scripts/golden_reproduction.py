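#!/usr/bin/env python
"""Rerun the published example workflows on their original datasets.

The two reference datasets are not redistributed here; they ship with the
MIAmaxent (v1.1.0) and maxnet (v0.1.2) R packages on CRAN.  Export each as
a CSV with the response column `RV` (1 = presence, empty = uninformed
background) plus one column per EV, e.g. in R:

    # grassland training data (MIAmaxent)
    library(MIAmaxent)
    grasslandPO <- readData(...)        # per the package vignette
    write.csv(grasslandPO, "grassland.csv", row.names = FALSE, na = "")

    # Bradypus variegatus (maxnet)
    library(maxnet)
    data(bradypus)
    bv <- data.frame(RV = ifelse(bradypus$presence == 1, 1, NA),
                     bradypus[, -1])
    write.csv(bv, "bradypus.csv", row.names = FALSE, na = "")

Then:

    python scripts/golden_reproduction.py --grassland grassland.csv \
        [--bradypus bradypus.csv] [--categorical geoberg,geolmja1,...]

The script runs the full pipeline (all transformation types, alpha = 0.01
for the grassland workflow; threshold transforms and interactions off,
alpha = 0.05 for the Bradypus comparison) and prints the selection trail
plus the headline quantities of each selected model for comparison with
the published tables.
"""

from __future__ import annotations

import argparse
import warnings

import numpy as np

from maxentsdm.io_tabular import OccurrenceTable
from maxentsdm.selection import TRAIL_COLUMNS
from maxentsdm.workflow import DistributionModel


def run(csv, categorical, types, alpha, label):
    table = OccurrenceTable.from_csv(csv, categorical=categorical or None)
    print(f"\n=== {label}: {table.n_presence} presences, "
          f"{table.n_background} background, {len(table.ev_names)} EVs ===")
    est = DistributionModel(
        types=types, alpha_dv=alpha, alpha_ev=alpha,
        categorical=table.categorical,
    )
    est.fit(table.ev, table.response)
    trail = est.selection_.trail
    with np.printoptions(precision=3):
        print(trail[TRAIL_COLUMNS].to_string(index=False,
              float_format=lambda v: f"{v:.3f}"))
    print(f"selected model: m = {est.model_.m_} DVs, "
          f"{len(est.selected_evs_)} EVs ({', '.join(est.selected_evs_)}), "
          f"Dsq = {est.model_.dsq_:.3f}")
    return est


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--grassland", help="CSV exported from the MIAmaxent training data")
    ap.add_argument("--bradypus", help="CSV exported from the maxnet Bradypus data")
    ap.add_argument("--categorical", default="", help="comma-separated categorical EV names")
    args = ap.parse_args()
    warnings.filterwarnings("ignore")
    cat = set(args.categorical.split(",")) if args.categorical else set()

    if not (args.grassland or args.bradypus):
        ap.error("provide --grassland and/or --bradypus")

    if args.grassland:
        run(args.grassland, cat, ("L", "M", "D", "HF", "HR", "T", "B"), 0.01, "grassland workflow")
    if args.bradypus:
        run(args.bradypus, cat, ("L", "M", "D", "HF", "HR", "B"), 0.05, "Bradypus comparison")


if __name__ == "__main__":
    main()
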