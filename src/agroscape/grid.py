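"""Raster data model and I/O shared by every other module.

A :class:`Grid` is a plain 2-D numpy array with cell-size metadata.
Indexing is 0-based ``(row, col)`` with row 0 the northernmost row; all
geographic bookkeeping (corner coordinates, pixel scale tags) is confined
to the readers and writers.  Grids are bounded (no wrap-around) and a cell
covers ``resolution × resolution`` square meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "CellSet",
    "read_raster",
    "write_raster",
    "connected_components",
    "neighbors",
]

#: A set of in-bounds (row, col) pairs.
CellSet = set

DEFAULT_RESOLUTION = 10.0

# TIFF tags used to carry geo metadata without a full GeoTIFF stack.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_GDAL_NODATA = 42113


@dataclass
class Grid:
    """A single-band raster.

    Parameters
    ----------
    values
        2-D array, row-major, row 0 = north.
    resolution
        Cell edge length in meters (> 0). Default 10 m, so a 200×200 grid
        spans 2 km × 2 km.
    nodata
        Sentinel marking cells outside the landscape, or ``None``.
    """

    values: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("Grid values must be a non-empty 2-D array")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_m2(self) -> float:
        return self.resolution**2

    def valid_mask(self) -> np.ndarray:
        """Boolean array: True where the cell belongs to the landscape."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.nrow and 0 <= c < self.ncol

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.resolution, self.nodata)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.resolution == other.resolution
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and (lightweight) GeoTIFF
# ---------------------------------------------------------------------------

RasterFormat = Literal["geotiff", "ascii_grid"]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    if path.suffix.lower() in {".tif", ".tiff"}:
        return "geotiff"
    return "ascii_grid"


def read_raster(path: str | Path, format: RasterFormat | None = None) -> Grid:
    """Read a raster from an ESRI ASCII grid or a GeoTIFF.

    The cell size is taken from the file metadata; files with non-square
    cells are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_raster(grid: Grid, path: str | Path, format: RasterFormat | None = None) -> None:
    """Write a raster as an ESRI ASCII grid or a GeoTIFF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "dx", "dy", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise IOError(f"{path}: missing ncols/nrows header")
    if "dx" in header or "dy" in header:
        dx, dy = header.get("dx"), header.get("dy")
        if dx != dy:
            raise ValueError(f"{path}: non-square cells (dx={dx}, dy={dy})")
        cellsize = float(dx)
    else:
        cellsize = float(header.get("cellsize", DEFAULT_RESOLUTION))
    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    if values.size != nrow * ncol:
        raise IOError(f"{path}: expected {nrow * ncol} values, got {values.size}")
    values = values.reshape(nrow, ncol)
    if np.all(values == np.floor(values)):
        ints = values.astype(np.int64)
        if np.array_equal(ints, values):
            values = ints
    nodata = header.get("nodata_value")
    return Grid(values, resolution=cellsize, nodata=nodata)


def _format_value(v) -> str:
    f = float(v)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _write_ascii(grid: Grid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncol}\n")
        fh.write(f"nrows {grid.nrow}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {_format_value(grid.resolution)}\n")
        if grid.nodata is not None:
            fh.write(f"NODATA_value {_format_value(grid.nodata)}\n")
        for row in grid.values:
            fh.write(" ".join(_format_value(v) for v in row) + "\n")


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        resolution = DEFAULT_RESOLUTION
        tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        if tag is not None:
            sx, sy = float(tag.value[0]), float(tag.value[1])
            if abs(sx - sy) > 1e-9 * max(sx, sy):
                raise ValueError(f"{path}: non-square cells (sx={sx}, sy={sy})")
            resolution = sx
        nodata = None
        ntag = page.tags.get(_TAG_GDAL_NODATA)
        if ntag is not None:
            nodata = float(ntag.value)
    if values.ndim != 2:
        raise IOError(f"{path}: expected a single-band raster")
    return Grid(values, resolution=resolution, nodata=nodata)


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    values = grid.values
    if np.issubdtype(values.dtype, np.integer):
        data = values.astype(np.int32)
    else:
        data = values.astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(grid.resolution), float(grid.resolution), 0.0)),
    ]
    if grid.nodata is not None:
        nod = _format_value(grid.nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nod))
    tifffile.imwrite(str(path), data, extratags=extratags)


# ---------------------------------------------------------------------------
# Neighborhood / component utilities
# ---------------------------------------------------------------------------

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def connected_components(mask: Grid | np.ndarray, connectivity: int = 8) -> tuple[Grid, int]:
    """Label maximal connected components of a 0/1 mask.

    Returns a grid of labels 1..K (0 = background) and the count K.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    values = mask.values if isinstance(mask, Grid) else np.asarray(mask)
    resolution = mask.resolution if isinstance(mask, Grid) else DEFAULT_RESOLUTION
    if not np.isin(values, (0, 1)).all():
        raise ValueError("mask must be binary 0/1")
    labels, count = ndimage.label(values, structure=_STRUCTURES[connectivity])
    return Grid(labels.astype(np.int32), resolution), int(count)


_OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def neighbors(cell: tuple[int, int], grid: Grid, connectivity: int = 8) -> CellSet:
    """In-bounds neighbors of a cell (no wrap-around)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not grid.in_bounds(cell):
        raise ValueError(f"cell {cell} is out of bounds for {grid.shape} grid")
    r, c = cell
    return {
        (r + dr, c + dc)
        for dr, dc in _OFFSETS[connectivity]
        if grid.in_bounds((r + dr, c + dc))
    }


def cells_to_mask(cells: Iterable[tuple[int, int]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a cell set into a boolean array."""
    mask = np.zeros(shape, dtype=bool)
    for r, c in cells:
        mask[r, c] = True
    return mask
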