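"""Geographic raster grids, ESRI ASCII I/O, spherical cell areas, terrain derivatives.

All layers in a study share a single :class:`GridSpec`: a north-up grid of
square cells in geographic coordinates (EPSG:4326 semantics), origin at the
upper-left corner, row index increasing southward.  Coordinates always refer
to cell centers.  Values are held as float64 internally; the ASCII dialect
round-trips them losslessly via repr-precision formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "Layer",
    "EnvStack",
    "read_raster",
    "write_raster",
    "cell_area_km2",
    "cell_areas_map",
    "slope_aspect",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic raster with square cells.

    Parameters
    ----------
    origin_lon, origin_lat
        Decimal degrees of the grid's upper-left *corner*.
    cell_size
        Cell edge length in degrees (cells are square).
    n_rows, n_cols
        Grid dimensions.
    nodata
        Sentinel value marking missing cells.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        east = self.origin_lon + self.n_cols * self.cell_size
        south = self.origin_lat - self.n_rows * self.cell_size
        if not (-180.0 - 1e-9 <= self.origin_lon and east <= 180.0 + 1e-9):
            raise ValueError("grid exceeds [-180, 180] longitude bounds")
        if not (-90.0 - 1e-9 <= south and self.origin_lat <= 90.0 + 1e-9):
            raise ValueError("grid exceeds [-90, 90] latitude bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon[n_cols], lat[n_rows]) of cell-center coordinates."""
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return lon, lat

    def locate(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell index containing a point, or None when off-grid.

        Cell ownership is half-open: a point on a shared edge belongs to the
        cell to its lower-right in index space (larger col / larger row); the
        outer east and south grid edges remain inclusive so boundary points
        on the grid's own rim are not lost.
        """
        col_f = (lon - self.origin_lon) / self.cell_size
        row_f = (self.origin_lat - lat) / self.cell_size
        col = int(math.floor(col_f))
        row = int(math.floor(row_f))
        if col == self.n_cols and abs(col_f - self.n_cols) < 1e-9:
            col -= 1
        if row == self.n_rows and abs(row_f - self.n_rows) < 1e-9:
            row -= 1
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None


@dataclass
class Layer:
    """A named single-band raster bound to a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        v = self.values
        return ~(np.isnan(v) | (v == self.grid.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Layer":
        return Layer(self.grid, values, self.name if name is None else name)


@dataclass
class EnvStack:
    """Ordered collection of co-registered predictor layers.

    After :meth:`harmonize_mask` every layer carries the identical nodata
    mask, so a cell is either valid for all predictors or for none.
    """

    grid: GridSpec
    layers: dict[str, Layer] = field(default_factory=dict)

    def add(self, layer: Layer) -> None:
        if layer.grid != self.grid:
            raise ValueError(f"layer {layer.name!r} is on a different grid")
        if layer.name in self.layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self.layers[layer.name] = layer

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def mask(self) -> np.ndarray:
        """Joint validity mask: True where every layer is valid."""
        m = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            m &= layer.mask
        return m

    def harmonize_mask(self) -> "EnvStack":
        """Return a stack where all layers share the joint nodata mask."""
        joint = self.mask
        out = EnvStack(self.grid)
        for name, layer in self.layers.items():
            v = layer.values.copy()
            v[~joint] = self.grid.nodata
            out.add(Layer(self.grid, v, name))
        return out

    def table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Extract an (n_points, n_layers) value table at cell indices."""
        return np.column_stack(
            [self.layers[n].values[rows, cols] for n in self.names]
        )

    def subset(self, names: list[str]) -> "EnvStack":
        out = EnvStack(self.grid)
        for n in names:
            out.add(self.layers[n])
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_ASC_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def read_raster(path, name: str = "") -> Layer:
    """Read a single-band ESRI ASCII grid (.asc) into a :class:`Layer`.

    Rejects rasters with rectangular cells (the header carries a single
    CELLSIZE, but DX/DY-style headers are refused) and anything that is not
    the ASCII dialect.
    """
    path = str(path)
    with open(path) as fh:
        head = fh.read(4)
    if head[:2] in ("II", "MM") or head[:4] == "\x89PNG":
        raise ValueError(
            f"{path}: binary raster formats are not supported; "
            "convert to ESRI ASCII grid (.asc)"
        )
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASC_KEYS | {"dx", "dy"}:
                if key in ("dx", "dy"):
                    raise ValueError(
                        f"{path}: DX/DY header implies non-square cells; only "
                        "square-cell grids are supported"
                    )
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"} - set(header)
    if missing:
        raise ValueError(f"{path}: not an ESRI ASCII grid (missing {sorted(missing)})")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        nodata=nodata,
    )
    if not name:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    return Layer(grid, values, name)


def write_raster(layer: Layer, path) -> None:
    """Write a layer as an ESRI ASCII grid; read(write(L)) is bit-identical."""
    g = layer.grid
    with open(str(path), "w") as fh:
        fh.write(f"NCOLS {g.n_cols}\n")
        fh.write(f"NROWS {g.n_rows}\n")
        fh.write(f"XLLCORNER {g.origin_lon!r}\n")
        fh.write(f"YLLCORNER {g.origin_lat - g.n_rows * g.cell_size!r}\n")
        fh.write(f"CELLSIZE {g.cell_size!r}\n")
        fh.write(f"NODATA_VALUE {g.nodata!r}\n")
        for row in layer.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Spherical cell areas
# ---------------------------------------------------------------------------


def cell_area_km2(grid: GridSpec, row: int) -> float:
    """Area in km² of any cell in the given row, on a sphere of R = 6371 km.

    A = R² · Δλ · (sin φ_top − sin φ_bottom): constant along a row and
    decreasing toward the poles.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} outside grid with {grid.n_rows} rows")
    lat_top = math.radians(grid.origin_lat - row * grid.cell_size)
    lat_bot = math.radians(grid.origin_lat - (row + 1) * grid.cell_size)
    dlam = math.radians(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (math.sin(lat_top) - math.sin(lat_bot))


def cell_areas_map(grid: GridSpec) -> np.ndarray:
    """(n_rows, n_cols) array of per-cell areas in km²."""
    rows = np.arange(grid.n_rows)
    lat_top = np.radians(grid.origin_lat - rows * grid.cell_size)
    lat_bot = np.radians(grid.origin_lat - (rows + 1) * grid.cell_size)
    dlam = math.radians(grid.cell_size)
    band = EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    return np.repeat(band[:, None], grid.n_cols, axis=1)


# ---------------------------------------------------------------------------
# Terrain: Horn slope and aspect
# ---------------------------------------------------------------------------

_FLAT_EPS = 1e-8
FLAT_ASPECT = -1.0  # aspect code for flat cells


def slope_aspect(dem: Layer) -> tuple[Layer, Layer]:
    """Slope (degrees) and aspect (compass degrees) from a DEM.

    Gradients use Horn's 3×3 weighted finite differences with horizontal
    distances in metres derived from the latitude-dependent metric size of a
    degree cell.  Aspect is the downslope compass direction, clockwise from
    north in [0, 360); flat cells (gradient magnitude < 1e-8) carry the
    sentinel ``FLAT_ASPECT``.  Border cells and cells adjacent to nodata are
    set to nodata.
    """
    g = dem.grid
    z = dem.values
    valid = dem.mask
    if not valid.any():
        raise ValueError("DEM contains no valid cells")
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("DEM must be at least 3x3")

    _, lat = g.cell_centers()
    deg_km = EARTH_RADIUS_KM * math.pi / 180.0
    dx_m = deg_km * 1000.0 * g.cell_size * np.cos(np.radians(lat))  # per row
    dy_m = deg_km * 1000.0 * g.cell_size

    slope = np.full(g.shape, g.nodata)
    aspect = np.full(g.shape, g.nodata)

    # interior cells whose full 3x3 neighbourhood is valid
    ok = valid.copy()
    neigh_ok = np.ones((g.n_rows - 2, g.n_cols - 2), dtype=bool)
    for di in (0, 1, 2):
        for dj in (0, 1, 2):
            neigh_ok &= ok[di : di + g.n_rows - 2, dj : dj + g.n_cols - 2]

    def w(di: int, dj: int) -> np.ndarray:
        return z[di : di + g.n_rows - 2, dj : dj + g.n_cols - 2]

    # Horn kernel: dz/dx positive eastward, dz/dy positive northward
    dz_dx = ((w(0, 2) + 2 * w(1, 2) + w(2, 2)) - (w(0, 0) + 2 * w(1, 0) + w(2, 0))) / (
        8.0 * dx_m[1:-1, None]
    )
    dz_dy = ((w(0, 0) + 2 * w(0, 1) + w(0, 2)) - (w(2, 0) + 2 * w(2, 1) + w(2, 2))) / (
        8.0 * dy_m
    )

    grad = np.hypot(dz_dx, dz_dy)
    s = np.degrees(np.arctan(grad))
    # downslope bearing: direction of -gradient, clockwise from north
    a = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    a[grad < _FLAT_EPS] = FLAT_ASPECT
    s[~neigh_ok] = g.nodata
    a[~neigh_ok] = g.nodata

    slope[1:-1, 1:-1] = s
    aspect[1:-1, 1:-1] = a
    return (
        Layer(g, slope, "slope"),
        Layer(g, aspect, "aspect"),
    )
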