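"""Regular geographic raster grids and plain-text raster I/O.

A :class:`RasterGrid` is a single 2-D layer on an axis-aligned
longitude/latitude grid.  Row 0 is the northernmost row and column 0 the
westernmost column; cell centres carry the coordinates.  Missing data are
tracked with a boolean mask (``True`` = masked/no-data).

Rasters are stored on disk as ESRI ASCII grids (``.asc``), a widely supported
georeferenced text format.  Values are written with 9 significant digits,
which round-trips float32 exactly and keeps repeated runs byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
]

_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two rasters do not share shape, origin, or cell size."""


@dataclass
class RasterGrid:
    """One environmental or suitability layer on a regular lon/lat grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = north.
    origin_lon, origin_lat
        Coordinates of the north-west corner of the grid (outer edge of
        cell (0, 0)).
    cell_size
        Cell edge length in decimal degrees (square cells).
    mask
        Boolean array, ``True`` where the cell carries no data.
    name
        Optional layer name (predictor name, "suitability", ...).
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of cell (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; may be out of range."""
        col = int(math.floor((lon - self.origin_lon) / self.cell_size))
        row = int(math.floor((self.origin_lat - lat) / self.cell_size))
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        row, col = self.cell_of(lon, lat)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon, lat) of every cell centre, each of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat - (rows + 0.5) * self.cell_size
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(
            lat[:, None], self.shape
        ).copy()

    # -- data ---------------------------------------------------------------

    def valid_values(self) -> np.ndarray:
        """1-D array of values on unmasked cells."""
        return self.values[~self.mask]

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "RasterGrid":
        """Clone the grid geometry, optionally substituting values/name."""
        return RasterGrid(
            values=self.values.copy() if values is None else np.asarray(values, dtype=float),
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            mask=self.mask.copy(),
            name=self.name if name is None else name,
        )

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-9)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-9)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )

    def require_aligned(self, other: "RasterGrid", names: tuple[str, str] = ("a", "b")) -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"rasters {names[0]!r} and {names[1]!r} are not aligned: "
                f"{self.shape}@({self.origin_lon},{self.origin_lat},{self.cell_size}) vs "
                f"{other.shape}@({other.origin_lon},{other.origin_lat},{other.cell_size})"
            )


# -- ESRI ASCII grid I/O ----------------------------------------------------


def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a raster as an ESRI ASCII grid (rows north to south)."""
    path = Path(path)
    vals = grid.values.astype(np.float32)
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.origin_lon!r}",
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {_NODATA:g}",
    ]
    out = np.where(grid.mask, np.float32(_NODATA), vals)
    for r in range(grid.n_rows):
        lines.append(" ".join(np.format_float_positional(v, precision=9, trim="-",
                                                         fractional=False)
                              for v in out[r]))
    path.write_text("\n".join(lines) + "\n")


def read_raster(path: str | Path, name: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        body = np.loadtxt(fh, dtype=np.float32)
    body = body.reshape(nrows, ncols)
    nodata = np.float32(header.get("nodata_value", _NODATA))
    mask = body == nodata
    values = body.astype(float)
    values[mask] = np.nan
    cell = header["cellsize"]
    return RasterGrid(
        values=values,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        mask=mask,
        name=name or path.stem,
    )


def write_stack(directory: str | Path, stack: dict[str, RasterGrid]) -> list[Path]:
    """Write one .asc file per layer under *directory*; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for layer_name, grid in stack.items():
        p = directory / f"{layer_name}.asc"
        write_raster(p, grid)
        paths.append(p)
    return paths


def read_stack(directory: str | Path) -> dict[str, RasterGrid]:
    """Read every .asc layer under *directory*, checking mutual alignment."""
    directory = Path(directory)
    stack: dict[str, RasterGrid] = {}
    first: RasterGrid | None = None
    first_path = ""
    for p in sorted(directory.glob("*.asc")):
        g = read_raster(p, name=p.stem)
        if first is None:
            first, first_path = g, str(p)
        else:
            try:
                first.require_aligned(g)
            except AlignmentError as exc:
                raise AlignmentError(f"{first_path} vs {p}: {exc}") from None
        stack[p.stem] = g
    return stack
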