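"""Regular-grid geometry and GeoTIFF raster I/O.

Every raster in the pipeline lives on a :class:`GridSpec` — a north-up
regular grid of square cells (default 1 km). Layers are written as
float32 GeoTIFFs with ModelPixelScale / ModelTiepoint georeferencing
tags and the band names stored as JSON in the image description, so
they round-trip losslessly through this module and open in standard
GIS tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import AlignmentError, InvalidGridError

#: GeoTIFF tag codes for pixel scale and tiepoint.
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; at least 4 each.
    cell_size : float
        Cell edge length in metres (default 1000 m, i.e. a 1 km cell).
    origin : tuple of float
        (x, y) of the top-left corner in metres.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise InvalidGridError(
                f"grid must be at least 4x4, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise InvalidGridError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_hm2(self) -> float:
        """Cell area in hectares (1 km cell -> 100 hm²)."""
        return self.cell_size**2 / 1e4


def check_aligned(spec_a: GridSpec, spec_b: GridSpec, name_a: str = "a", name_b: str = "b") -> None:
    """Raise :class:`AlignmentError` unless the two grids are identical."""
    if spec_a != spec_b:
        raise AlignmentError(
            f"rasters {name_a!r} and {name_b!r} are not on the same grid: "
            f"{spec_a} vs {spec_b}"
        )


def check_raster(array: np.ndarray, spec: GridSpec, name: str = "raster") -> None:
    """Raise :class:`AlignmentError` unless ``array`` matches ``spec``'s shape."""
    if array.shape[-2:] != spec.shape:
        raise AlignmentError(
            f"{name!r} has shape {array.shape}, expected trailing {spec.shape}"
        )


def write_raster(
    path,
    array: np.ndarray,
    spec: GridSpec,
    band_names: list[str] | None = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as a float32 GeoTIFF."""
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    check_raster(arr, spec)
    if band_names is not None and len(band_names) != arr.shape[0]:
        raise AlignmentError(
            f"{len(band_names)} band names for {arr.shape[0]} bands"
        )
    meta = {
        "cell_size": spec.cell_size,
        "origin": list(spec.origin),
        "band_names": band_names,
    }
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin[0], spec.origin[1], 0.0)),
    ]
    tifffile.imwrite(
        path,
        arr,
        description=json.dumps(meta),
        extratags=extratags,
        photometric="minisblack",
    )


def read_raster(path) -> tuple[np.ndarray, GridSpec, list[str] | None]:
    """Read a GeoTIFF written by :func:`write_raster`.

    Returns (array of shape (bands, rows, cols), GridSpec, band names or None).
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if arr.ndim == 2:
        arr = arr[None]
    spec = GridSpec(
        n_rows=arr.shape[-2],
        n_cols=arr.shape[-1],
        cell_size=float(meta.get("cell_size", 1000.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )
    return arr, spec, meta.get("band_names")


def block_regions(spec: GridSpec, n_blocks_rows: int = 3, n_blocks_cols: int = 3) -> np.ndarray:
    """Partition the grid into a checkerboard of rectangular regions.

    Emulates county subdivisions of a study area; labels run 1..R in
    row-major block order.
    """
    row_edges = np.linspace(0, spec.n_rows, n_blocks_rows + 1).astype(int)
    col_edges = np.linspace(0, spec.n_cols, n_blocks_cols + 1).astype(int)
    labels = np.zeros(spec.shape, dtype=np.int32)
    lab = 1
    for i in range(n_blocks_rows):
        for j in range(n_blocks_cols):
            labels[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = lab
            lab += 1
    return labels
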