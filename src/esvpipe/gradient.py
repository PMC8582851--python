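"""Gradient differentiation of ESV along its driving factors.

Each driver is cut into a small ordered set of field-standard classes
(terrain classes from the Chinese national land-survey regulations,
equidistant NDVI cover classes, natural-breaks-derived classes for
precipitation, population/economic density and settlement distance)
and the ESV total and share falling in each class is tabulated.
Bins are lower-open, upper-closed (a, b]; the outermost bins are
unbounded, so assignment is exhaustive. A scheme may declare hard
lower/upper limits, in which case out-of-range cells are reported in
an explicit overflow bin rather than silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DomainError, SchemaError


@dataclass(frozen=True)
class GradientScheme:
    """Ordered binning of one driver.

    ``edges`` are the interior boundaries (strictly increasing); bin c
    is (edges[c-1], edges[c]] with open ends outside. ``labels`` has
    one entry per bin (len(edges) + 1). Optional ``lower``/``upper``
    declare the valid data range; values outside go to an overflow bin.
    """

    factor: str
    edges: tuple[float, ...]
    labels: tuple[str, ...]
    unit: str = ""
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if not np.all(np.diff(e) > 0):
            raise SchemaError(f"edges must be strictly increasing: {self.edges}")
        if len(self.labels) != len(self.edges) + 1:
            raise SchemaError(
                f"{len(self.labels)} labels for {len(self.edges) + 1} bins"
            )

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; −1 marks out-of-range (overflow) values."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(np.asarray(self.edges), v, side="left").astype(np.int64)
        if self.lower is not None:
            idx[v < self.lower] = -1
        if self.upper is not None:
            idx[v > self.upper] = -1
        return idx

    def label_of(self, value: float) -> str:
        i = int(self.assign(np.asarray([value]))[0])
        if i < 0:
            return "out_of_range"
        return self.labels[i]


def builtin_schemes() -> dict[str, GradientScheme]:
    """The seven printed gradient schemes, keyed by factor name."""
    return {
        "slope": GradientScheme(
            factor="slope",
            edges=(2.0, 6.0, 15.0, 25.0),
            labels=("flat", "gentle slope", "slope", "steep slope", "dangerous slope"),
            unit="degree",
        ),
        "elevation": GradientScheme(
            factor="elevation",
            edges=(200.0, 500.0),
            labels=("plains", "hills", "mountains"),
            unit="m",
        ),
        "ndvi": GradientScheme(
            factor="ndvi",
            edges=(0.2, 0.4, 0.6, 0.8),
            labels=(
                "low coverage",
                "medium and low coverage",
                "medium coverage",
                "medium to high coverage",
                "high coverage",
            ),
        ),
        "precipitation": GradientScheme(
            factor="precipitation",
            edges=(500.0, 800.0, 1000.0),
            labels=("<=500 mm", "500-800 mm", "800-1000 mm", ">1000 mm"),
            unit="mm",
        ),
        "pop_density": GradientScheme(
            factor="pop_density",
            edges=(5.0, 100.0, 1000.0, 10000.0),
            labels=(
                "<=5 persons/km2",
                "5-100 persons/km2",
                "100-1000 persons/km2",
                "1000-10000 persons/km2",
                ">10000 persons/km2",
            ),
            unit="persons/km2",
        ),
        "econ_density": GradientScheme(
            factor="econ_density",
            edges=(50.0, 100.0, 1000.0, 10000.0),
            labels=(
                "<=50 yuan/km2",
                "50-100 yuan/km2",
                "100-1000 yuan/km2",
                "1000-10000 yuan/km2",
                ">10000 yuan/km2",
            ),
            unit="yuan/km2",
        ),
        "dist_settlement": GradientScheme(
            factor="dist_settlement",
            edges=(10.0, 500.0, 1000.0, 5000.0),
            labels=("<=10 m", "10-500 m", "500-1000 m", "1000-5000 m", ">5000 m"),
            unit="m",
        ),
    }


def esv_by_gradient(
    esv_per_cell: np.ndarray,
    factor: np.ndarray,
    scheme: GradientScheme,
    year: str = "",
) -> pd.DataFrame:
    """Total and share of ESV in each gradient class of one driver.

    ``esv_per_cell`` is the per-cell total ESV (yuan); ``factor`` the
    aligned driver raster. Shares sum to 100% and totals to the grand
    total, with any out-of-range cells reported in an 'out_of_range'
    row.
    """
    esv_per_cell = np.asarray(esv_per_cell, dtype=float)
    factor = np.asarray(factor, dtype=float)
    if esv_per_cell.shape != factor.shape:
        raise SchemaError(
            f"ESV shape {esv_per_cell.shape} != factor shape {factor.shape}"
        )
    idx = scheme.assign(factor).ravel()
    esv = esv_per_cell.ravel()
    grand = esv.sum()
    if grand == 0:
        raise DegenerateInputError("grand-total ESV is zero; shares undefined")

    rows = []
    for c, label in enumerate(scheme.labels):
        sel = idx == c
        total = float(esv[sel].sum())
        rows.append(
            {
                "factor": scheme.factor,
                "bin": label,
                "year": year,
                "n_cells": int(sel.sum()),
                "esv_yuan": total,
                "share_pct": 100.0 * total / grand,
            }
        )
    if (idx == -1).any():
        sel = idx == -1
        total = float(esv[sel].sum())
        rows.append(
            {
                "factor": scheme.factor,
                "bin": "out_of_range",
                "year": year,
                "n_cells": int(sel.sum()),
                "esv_yuan": total,
                "share_pct": 100.0 * total / grand,
            }
        )
    return pd.DataFrame(rows)


def factor_correlation(factor: np.ndarray, esv_per_cell: np.ndarray) -> float:
    """Pearson product-moment correlation between a driver and per-cell ESV."""
    f = np.asarray(factor, dtype=float).ravel()
    e = np.asarray(esv_per_cell, dtype=float).ravel()
    if f.size != e.size:
        raise SchemaError("factor and ESV rasters differ in size")
    if f.size < 3:
        raise DegenerateInputError("need at least 3 cells")
    if f.std() == 0 or e.std() == 0:
        raise DomainError("correlation undefined for zero-variance input")
    r, _ = stats.pearsonr(f, e)
    return float(r)
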