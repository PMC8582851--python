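#!/usr/bin/env python
"""Classify the spatial pattern of ESV change with natural breaks.

Takes the first- and last-epoch ESV rasters from 02_value_esv.py,
computes the per-cell change in yuan, cuts it into seven Jenks
natural-breaks classes (pooled over the full period) and writes the
classified map and the per-class cell counts under results/change/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import esvpipe as ep

ROOT = Path(__file__).resolve().parents[1] / "results"
VALUATION = ROOT / "valuation"
OUT = ROOT / "change"
K = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    years = sorted(p.stem.split("_")[1] for p in VALUATION.glob("esv_*.tif"))
    first, spec, _ = ep.read_raster(VALUATION / f"esv_{years[0]}.tif")
    last, spec2, _ = ep.read_raster(VALUATION / f"esv_{years[-1]}.tif")
    from esvpipe.grids import check_aligned

    check_aligned(spec, spec2, years[0], years[-1])
    delta = last.sum(axis=0).astype(float) - first.sum(axis=0).astype(float)

    cm = ep.classify_change(delta, k=K, year_start=years[0], year_end=years[-1])
    ep.write_raster(OUT / "esv_change.tif",
                    np.stack([cm.delta, cm.labels.astype(float)]), spec,
                    band_names=["delta_yuan", "jenks_class"])
    table = pd.DataFrame({
        "interval_yuan": cm.intervals(),
        "n_cells": cm.class_counts(),
        "share_pct": 100.0 * cm.class_counts() / delta.size,
    })
    table.to_csv(OUT / "change_classes.csv", index=False)

    print(f"ESV change {years[0]} -> {years[-1]}: "
          f"mean {delta.mean():+.0f} yuan/cell, "
          f"{(delta > 0).mean() * 100:.1f}% of cells gained value")
    print(f"{K} natural-breaks classes (within-class SS optimal):")
    print(table.to_string(index=False))
    print(f"wrote map and table to {OUT}")


if __name__ == "__main__":
    main()
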