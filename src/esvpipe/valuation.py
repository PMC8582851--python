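"""Equivalent-factor valuation of ecosystem services.

The equivalent-factor method (Costanza lineage, Chinese terrestrial
table by Xie et al.) prices nine ecosystem services for five valued
land types through a table of dimensionless equivalents. One standard
equivalent factor equals 1/7 of the market value of the annual grain
yield of one hectare of average farmland, so the monetary anchor is

    E_ij = alpha * (1/7) * (P * Q / A) * E0_ij

with P the grain price (yuan/kg), Q the grain yield (kg), A the sown
area (hm²) and alpha a provincial correction coefficient (1.39 for
Henan). Values from different years are made comparable by CPI
deflation, VC_ij = E_ij * CPI' / CPI0, and the per-cell value is

    ESV(cell, service j) = sum_i  area_i(cell) * VC_ij

summed over land types i. Construction land carries coefficient 0 by
default (its ecological value is conventionally not counted in this
method); that choice is overridable by supplying a custom table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, SchemaError
from .grids import GridSpec, check_raster

#: Canonical land-class order used by every composition raster.
LAND_CLASSES = ["cropland", "forestland", "grassland", "water", "construction", "unused"]

#: The five land types carrying non-zero equivalents.
VALUED_LAND_TYPES = ["cropland", "forestland", "grassland", "water", "unused"]

#: The nine second-category services, in table order.
SERVICES = [
    "food_production",
    "raw_material_production",
    "gas_regulation",
    "climate_regulation",
    "hydrological_regulation",
    "waste_treatment",
    "soil_conservation",
    "biodiversity_maintenance",
    "aesthetic_landscape",
]

#: First-category grouping of the nine services.
CATEGORY_MAP = {
    "food_production": "provisioning",
    "raw_material_production": "provisioning",
    "gas_regulation": "regulating",
    "climate_regulation": "regulating",
    "hydrological_regulation": "regulating",
    "waste_treatment": "regulating",
    "soil_conservation": "supporting",
    "biodiversity_maintenance": "supporting",
    "aesthetic_landscape": "cultural",
}

FIRST_CATEGORIES = ["provisioning", "regulating", "supporting", "cultural"]


@dataclass(frozen=True)
class GrainStats:
    """Regional grain statistics anchoring the standard equivalent factor.

    P: average grain price (yuan/kg); Q: grain yield (kg); A: sown
    area (hm²); alpha: provincial correction coefficient (1.39 by
    convention for Henan).
    """

    P: float
    Q: float
    A: float
    alpha: float = 1.39

    def __post_init__(self) -> None:
        if self.A == 0:
            raise ZeroDivisionError("sown area A must be non-zero")
        if self.P <= 0 or self.Q <= 0 or self.A < 0 or self.alpha <= 0:
            raise DomainError("grain statistics must be positive")


@dataclass(frozen=True)
class CpiSeries:
    """Fixed-base and current consumer price indices for deflation."""

    cpi_prime: float
    cpi0: float

    def __post_init__(self) -> None:
        if self.cpi0 == 0:
            raise ZeroDivisionError("current CPI index must be non-zero")
        if self.cpi_prime <= 0 or self.cpi0 < 0:
            raise DomainError("CPI indices must be positive")


class CoefficientTable:
    """5 (+construction) land types × 9 services value coefficients.

    Wraps a DataFrame indexed by service with one column per land
    class (yuan·hm⁻²·yr⁻¹). Construction is fixed at 0 unless the
    caller supplies a value column for it.
    """

    def __init__(self, values: pd.DataFrame):
        missing_services = set(SERVICES) - set(values.index)
        if missing_services:
            raise SchemaError(f"coefficient table missing services: {sorted(missing_services)}")
        missing_types = set(VALUED_LAND_TYPES) - set(values.columns)
        if missing_types:
            raise SchemaError(f"coefficient table missing land types: {sorted(missing_types)}")
        table = values.reindex(SERVICES).copy()
        if "construction" not in table.columns:
            table["construction"] = 0.0
        table = table[LAND_CLASSES].astype(float)
        if (table.values < 0).any():
            raise DomainError("value coefficients must be non-negative")
        self.values = table

    @property
    def matrix(self) -> np.ndarray:
        """(n_services, n_land_classes) coefficient matrix in canonical order."""
        return self.values.to_numpy()

    @classmethod
    def from_csv(cls, path) -> "CoefficientTable":
        df = pd.read_csv(path)
        if "service" not in df.columns:
            raise SchemaError("coefficient CSV needs a 'service' column")
        df = df.set_index("service").drop(columns=["category"], errors="ignore")
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.values[VALUED_LAND_TYPES].copy()
        out.insert(0, "category", [CATEGORY_MAP[s] for s in out.index])
        out.to_csv(path, index_label="service")

    def scaled(self, factor: float) -> "CoefficientTable":
        return CoefficientTable(self.values[VALUED_LAND_TYPES] * factor)


def load_coefficients() -> CoefficientTable:
    """Packaged 2015 value-coefficient table for the study region (yuan·hm⁻²·yr⁻¹)."""
    with resources.files("esvpipe.data").joinpath("esv_coefficients_2015.csv").open() as fh:
        return CoefficientTable.from_csv(fh)


def correct_equivalents(e0, grain: GrainStats):
    """Regionally correct national equivalents to yuan·hm⁻²·yr⁻¹.

    E_ij = alpha * (1/7) * (P*Q/A) * E0_ij; linear in every input.
    Accepts an array or DataFrame and returns the same shape.
    """
    e0_arr = np.asarray(e0, dtype=float) if not isinstance(e0, pd.DataFrame) else e0
    if np.any(np.asarray(e0_arr) < 0):
        raise DomainError("equivalents must be non-negative")
    factor = grain.alpha * (1.0 / 7.0) * (grain.P * grain.Q / grain.A)
    return e0_arr * factor


def deflate_cpi(e, cpi: CpiSeries):
    """Rebase monetary coefficients to the fixed-base price level.

    VC_ij = E_ij * (1 + (CPI' − CPI0)/CPI0) = E_ij * CPI'/CPI0.
    """
    ratio = 1.0 + (cpi.cpi_prime - cpi.cpi0) / cpi.cpi0
    e_arr = np.asarray(e, dtype=float) if not isinstance(e, pd.DataFrame) else e
    return e_arr * ratio


@dataclass
class LandComposition:
    """Per-cell area fractions of the six land classes for one year.

    fractions has shape (6, rows, cols) in :data:`LAND_CLASSES` order
    and sums to 1 over classes at every cell.
    """

    fractions: np.ndarray
    spec: GridSpec
    year: str

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(LAND_CLASSES), *self.spec.shape):
            raise AlignmentError(
                f"composition shape {self.fractions.shape} does not match "
                f"(6, {self.spec.n_rows}, {self.spec.n_cols})"
            )
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DomainError("land-class fractions must sum to 1 at every cell")
        if (self.fractions < -1e-12).any():
            raise DomainError("land-class fractions must be non-negative")


@dataclass
class EsvGrid:
    """Per-cell, per-service ecosystem service value (yuan) for one year."""

    values: np.ndarray  # (n_services, rows, cols)
    spec: GridSpec
    year: str
    cell_area_hm2: float

    def total(self) -> float:
        """Grand total over cells and services, in yuan."""
        return float(self.values.sum())

    def per_cell_total(self) -> np.ndarray:
        """(rows, cols) total ESV per cell over all services."""
        return self.values.sum(axis=0)


def compute_esv(
    land: LandComposition,
    coeffs: CoefficientTable,
    cell_area_hm2: float | None = None,
) -> EsvGrid:
    """Value a land composition: ESV(c, j) = Σ_i A_i(c) · VC_ij.

    A_i(c) is the area of land type i in cell c (fraction × cell
    area in hm²); VC_ij are the table coefficients (yuan·hm⁻²·yr⁻¹).
    """
    if cell_area_hm2 is None:
        cell_area_hm2 = land.spec.cell_area_hm2
    if cell_area_hm2 <= 0:
        raise DomainError("cell area must be positive")
    vc = coeffs.matrix  # (9, 6)
    # einsum over land classes: (service, class) x (class, r, c)
    values = np.einsum("jc,crk->jrk", vc, land.fractions) * cell_area_hm2
    return EsvGrid(values=values, spec=land.spec, year=land.year, cell_area_hm2=cell_area_hm2)


def aggregate(
    esv: EsvGrid,
    regions: np.ndarray | None = None,
    level: str = "second",
) -> pd.DataFrame:
    """Aggregate an ESV grid to a tidy (group × region) table in yuan.

    level "second" keeps the nine services; "first" sums them into the
    four first categories. With ``regions`` (an integer label raster)
    totals are reported per region; otherwise one study-wide column.
    Group totals always sum exactly to the grand total.
    """
    if level not in ("first", "second"):
        raise SchemaError(f"unknown aggregation level {level!r}")
    if regions is not None:
        check_raster(regions, esv.spec, "regions")
        region_labels = np.unique(regions)
    else:
        regions = np.zeros(esv.spec.shape, dtype=np.int32)
        region_labels = np.array([0])

    rows = []
    for j, service in enumerate(SERVICES):
        layer = esv.values[j]
        for lab in region_labels:
            rows.append(
                {
                    "category": CATEGORY_MAP[service],
                    "service": service,
                    "region": int(lab),
                    "year": esv.year,
                    "esv_yuan": float(layer[regions == lab].sum()),
                }
            )
    table = pd.DataFrame(rows)
    if level == "first":
        table = (
            table.groupby(["category", "region", "year"], as_index=False, sort=False)
            .agg(esv_yuan=("esv_yuan", "sum"))
        )
    return table
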