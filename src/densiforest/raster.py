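"""Georeferenced raster lattice shared by all spatial stages.

A :class:`RasterGrid` is a set of named single-band layers on one north-up
geographic (WGS84 lon/lat) lattice with a common nodata mask.  Pixel
convention, used everywhere in the package: origin at the top-left (west,
north) corner, cells are half-open intervals ``[edge, edge + cellsize)`` in
longitude and ``(edge - cellsize, edge]`` read top-down in latitude, i.e.
``col = floor((lon - west)/cs)``, ``row = floor((north - lat)/cs)``.

Layers are serialized as ESRI ASCII grids (``.asc``), a plain-text
single-band raster format: a short header (ncols, nrows, xllcorner,
yllcorner, cellsize, NODATA_value) followed by the rows, north first.
Round-trips are bit-exact for finite values because floats are written
with ``repr`` precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

NODATA = -9999.0


@dataclass
class RasterGrid:
    """Named float layers on a shared lon/lat lattice with one mask.

    Parameters
    ----------
    west, north : float
        Coordinates of the outer top-left corner, decimal degrees.
    cellsize : float
        Cell edge length in degrees (square cells).
    layers : dict of str -> 2-D ndarray
        All arrays congruent; values at masked pixels are ignored.
    mask : 2-D bool ndarray
        True where a pixel carries no data.
    """

    west: float
    north: float
    cellsize: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers not congruent: {shapes}")
        if self.mask is None and self.layers:
            self.mask = np.zeros(next(iter(self.layers.values())).shape, dtype=bool)

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cellsize

    def index_of(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the half-open cell containing each point."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((self.north - lat) / self.cellsize).astype(int)
        col = np.floor((lon - self.west) / self.cellsize).astype(int)
        return row, col

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        row, col = self.index_of(lat, lon)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def sample(self, name: str, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Layer values at point locations (NaN off-grid or masked)."""
        row, col = self.index_of(lat, lon)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full(np.shape(row), np.nan)
        r, c = row[ok], col[ok]
        vals = self.layers[name][r, c].astype(float)
        vals[self.mask[r, c]] = np.nan
        out[ok] = vals
        return out

    # -- layer access -------------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if self.layers and values.shape != self.shape:
            raise ValueError(f"layer {name!r} shape {values.shape} != grid {self.shape}")
        self.layers[name] = values
        if self.mask is None:
            self.mask = np.zeros(values.shape, dtype=bool)

    def masked(self, name: str) -> np.ndarray:
        """Layer with masked pixels set to NaN."""
        out = self.layers[name].astype(float).copy()
        out[self.mask] = np.nan
        return out

    def pixel_area_ha(self, radius_km: float = 6371.007) -> np.ndarray:
        """Per-pixel spherical surface area in hectares (authalic sphere).

        Area of a lon/lat cell = R^2 * dlon * (sin(lat_top) - sin(lat_bot)).
        """
        r_m = radius_km * 1e3
        dlon = np.deg2rad(self.cellsize)
        lat_top = np.deg2rad(self.north - np.arange(self.n_rows) * self.cellsize)
        lat_bot = lat_top - np.deg2rad(self.cellsize)
        band_m2 = r_m**2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
        return np.repeat(band_m2[:, None], self.n_cols, axis=1) / 1e4

    # -- I/O ----------------------------------------------------------
    def write_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, arr in self.layers.items():
            p = directory / f"{name}.asc"
            write_ascii_grid(p, self, name)
            written.append(p)
        return written

    @classmethod
    def read_dir(cls, directory: str | Path) -> "RasterGrid":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers under {directory}")
        grid = None
        for p in paths:
            layer = read_ascii_grid(p)
            if grid is None:
                grid = layer
                grid.layers = {p.stem: layer.layers[p.stem]}
            else:
                if (layer.west, layer.north, layer.cellsize) != (
                    grid.west,
                    grid.north,
                    grid.cellsize,
                ):
                    raise ValueError(f"layer {p.stem} not on the shared lattice")
                grid.add_layer(p.stem, layer.layers[p.stem])
                grid.mask |= layer.mask
        return grid


def write_ascii_grid(path: str | Path, grid: RasterGrid, name: str) -> None:
    """Write one layer as an ESRI ASCII grid (text, repr-precision floats)."""
    arr = grid.layers[name]
    path = Path(path)
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.west!r}",
        f"yllcorner {(grid.north - grid.n_rows * grid.cellsize)!r}",
        f"cellsize {grid.cellsize!r}",
        f"NODATA_value {NODATA!r}",
    ]
    body = arr.astype(float).copy()
    body[grid.mask] = NODATA
    for row in body:
        lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read a single-layer ESRI ASCII grid; layer named after the file stem."""
    path = Path(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.asarray(rows, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: body shape {arr.shape} != header ({n_rows},{n_cols})")
    nodata = header.get("nodata_value", NODATA)
    mask = arr == nodata
    cs = header["cellsize"]
    grid = RasterGrid(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * cs,
        cellsize=cs,
        layers={path.stem: arr},
        mask=mask,
    )
    return grid
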