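"""Regular geographic grids: data model, ASCII-grid I/O, resampling, geometry.

All layers live on a shared lon/lat grid addressed by (row, col), with row 0
at the northern edge. Cell-center coordinates are used for interpolation and
point-in-cell assignment; extents are half-open ``[origin, origin + n*res)``.
Areas are computed on a sphere of radius 6371 km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

EARTH_RADIUS_KM = 6371.0

#: Layer-name registry: which named layers form the climate and land-cover
#: predictor sets, and the name of the sampling-effort covariate.
CLIMATE_LAYERS = ("tmin", "tmax", "pan", "pcv")
LANDCOVER_LAYERS = ("needleleaf", "broadleaf", "grassland", "shrub", "crop", "urban")
BIAS_LAYER = "bias"


def lon_centers(origin_lon: float, res_arcmin: float, n_cols: int) -> np.ndarray:
    """Longitudes of cell centers, west to east."""
    res = res_arcmin / 60.0
    return origin_lon + (np.arange(n_cols) + 0.5) * res


def lat_centers(origin_lat: float, res_arcmin: float, n_rows: int) -> np.ndarray:
    """Latitudes of cell centers, north to south (row 0 is northernmost)."""
    res = res_arcmin / 60.0
    return origin_lat - (np.arange(n_rows) + 0.5) * res


@dataclass
class EnvGrid:
    """A stack of named raster layers on one regular lon/lat grid.

    Parameters
    ----------
    origin_lon, origin_lat
        Degrees of the grid's upper-left (north-west) corner.
    res_arcmin
        Cell size in arcminutes; cells are square in degrees.
    layers
        Mapping layer name -> (n_rows, n_cols) float array.
    mask
        Boolean array, True where a cell is outside the study region.
        Masked cells are excluded from sums, quantiles and centroids.
    """

    origin_lon: float
    origin_lat: float
    res_arcmin: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None
    crs_label: str = "WGS84 lon/lat"

    def __post_init__(self) -> None:
        if self.res_arcmin <= 0:
            raise ValueError("res_arcmin must be positive")
        shapes = {name: a.shape for name, a in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        if self.mask is None:
            if not self.layers:
                raise ValueError("empty grid: need at least one layer or a mask")
            self.mask = np.zeros(next(iter(self.layers.values())).shape, bool)
        self.mask = np.asarray(self.mask, bool)
        for name, a in self.layers.items():
            if a.shape != self.mask.shape:
                raise ValueError(f"layer {name!r} shape {a.shape} != mask {self.mask.shape}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def res_deg(self) -> float:
        return self.res_arcmin / 60.0

    @property
    def lon_centers(self) -> np.ndarray:
        return lon_centers(self.origin_lon, self.res_arcmin, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        return lat_centers(self.origin_lat, self.res_arcmin, self.n_rows)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing a point, or None if outside.

        Half-open convention: a point on the west/north edge of a cell
        belongs to it; on the east/south edge it belongs to the neighbour.
        """
        col = math.floor((lon - self.origin_lon) / self.res_deg)
        row = math.floor((self.origin_lat - lat) / self.res_deg)
        # points exactly on the northern/western outer boundary fall in row/col 0
        if lat == self.origin_lat:
            row = 0
        if lon == self.origin_lon:
            col = 0
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def copy(self) -> "EnvGrid":
        return EnvGrid(
            self.origin_lon,
            self.origin_lat,
            self.res_arcmin,
            {k: v.copy() for k, v in self.layers.items()},
            self.mask.copy(),
            self.crs_label,
        )

    def subset(self, names) -> "EnvGrid":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing layers: {missing}")
        return EnvGrid(
            self.origin_lon, self.origin_lat, self.res_arcmin,
            {n: self.layers[n].copy() for n in names}, self.mask.copy(), self.crs_label,
        )


@dataclass
class ScenarioSpec:
    """A named future layer set aligned with the current-period grid."""

    name: str
    gcm_label: str
    layer_source: EnvGrid


# -- I/O (ESRI ASCII grid: plain-text, single band, explicit nodata) --------

def write_layer(grid: EnvGrid, name: str, path: str | Path, nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (.asc)."""
    a = np.array(grid.layers[name], float)
    a[grid.mask] = nodata
    yll = grid.origin_lat - grid.n_rows * grid.res_deg
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.res_deg!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, a, fmt="%.10g")


def read_layer(path: str | Path, name: str) -> EnvGrid:
    """Read a single-band ESRI ASCII grid into an EnvGrid with one layer.

    Nodata cells become masked. The grid is assumed geographic (lon/lat);
    a cellsize implying a non-geographic coordinate range raises.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"data shape {data.shape} != header ({n_rows}, {n_cols})")
    res_deg = header["cellsize"]
    origin_lat = header["yllcorner"] + n_rows * res_deg
    if abs(header["xllcorner"]) > 360 or abs(origin_lat) > 90:
        raise ValueError(
            f"non-geographic georeference (xll={header['xllcorner']}, "
            f"top lat={origin_lat}); only lon/lat grids are supported"
        )
    mask = data == header["nodata_value"]
    vals = data.astype(float)
    vals[mask] = np.nan
    return EnvGrid(header["xllcorner"], origin_lat, res_deg * 60.0, {name: vals}, mask)


# -- operations -------------------------------------------------------------

def bilinear_resample(grid: EnvGrid, target_res_arcmin: float) -> EnvGrid:
    """Resample every layer to a new resolution by bilinear interpolation.

    The output covers the same extent. Each output cell-center value is the
    bilinear interpolation of the four surrounding input cell centers;
    outside the outer ring of input centers, the nearest edge value is used.
    Any output cell whose interpolation touches a masked input is masked.
    """
    if target_res_arcmin <= 0:
        raise ValueError("target_res_arcmin must be positive")
    if not grid.layers:
        raise ValueError("empty grid: no layers to resample")
    n_rows = max(1, round(grid.n_rows * grid.res_arcmin / target_res_arcmin))
    n_cols = max(1, round(grid.n_cols * grid.res_arcmin / target_res_arcmin))
    ratio = target_res_arcmin / grid.res_arcmin
    # fractional input index of each output cell center
    fi = (np.arange(n_rows) + 0.5) * ratio - 0.5
    fj = (np.arange(n_cols) + 0.5) * ratio - 0.5
    jj, ii = np.meshgrid(fj, fi)
    coords = np.stack([ii, jj])

    mask_w = map_coordinates(grid.mask.astype(float), coords, order=1, mode="nearest")
    out_mask = mask_w > 1e-12
    out_layers = {}
    for name, a in grid.layers.items():
        filled = np.where(grid.mask, 0.0, a)
        vals = map_coordinates(filled, coords, order=1, mode="nearest")
        vals[out_mask] = np.nan
        out_layers[name] = vals
    return EnvGrid(grid.origin_lon, grid.origin_lat, target_res_arcmin,
                   out_layers, out_mask, grid.crs_label)


def cell_areas_km2(grid: EnvGrid) -> np.ndarray:
    """Cell area in km^2 for each row (constant within a row).

    Spherical formula: A = R^2 * d_lambda * (sin(phi_top) - sin(phi_bot)).
    """
    res = grid.res_deg
    lat_top = grid.origin_lat - np.arange(grid.n_rows) * res
    lat_bot = lat_top - res
    if lat_top.max() > 90 + 1e-9 or lat_bot.min() < -90 - 1e-9:
        raise ValueError("grid rows extend outside [-90, 90] latitude")
    dlam = math.radians(res)
    return (EARTH_RADIUS_KM ** 2) * dlam * (
        np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot))
    )


def align_or_fail(grids: list[EnvGrid]) -> None:
    """Raise unless all grids share origin, resolution and shape (1e-9 deg)."""
    if not grids:
        raise ValueError("no grids given")
    ref = grids[0]
    for g in grids[1:]:
        for prop in ("origin_lon", "origin_lat", "res_arcmin"):
            if abs(getattr(g, prop) - getattr(ref, prop)) > 1e-9:
                raise ValueError(
                    f"grids misaligned: {prop} differs "
                    f"({getattr(ref, prop)} vs {getattr(g, prop)})"
                )
        for prop in ("n_rows", "n_cols"):
            if getattr(g, prop) != getattr(ref, prop):
                raise ValueError(
                    f"grids misaligned: {prop} differs "
                    f"({getattr(ref, prop)} vs {getattr(g, prop)})"
                )


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on the R = 6371 km sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))
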