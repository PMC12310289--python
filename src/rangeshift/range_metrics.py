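"""Suitability maps, binary maps, areas of habitat and range centroids.

Implements the projection bookkeeping for decoupled change scenarios: a
future layer set can be combined with the current one so that only climate,
only land cover, or both take future values ("clim", "land", "both"), and
the resulting suitability surfaces are summarised as area of habitat (km^2),
suitability-weighted centroids, and great-circle shift distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import (
    CLIMATE_LAYERS,
    LANDCOVER_LAYERS,
    EnvGrid,
    ScenarioSpec,
    align_or_fail,
    haversine_km,
    lat_centers,
    lon_centers,
)

#: Prediction modes: which variable sets take future values.
MODES = ("both", "clim", "land")


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability in [0, 1] on the study grid."""

    origin_lon: float
    origin_lat: float
    res_arcmin: float
    values: np.ndarray
    mask: np.ndarray
    species_id: str = ""
    scenario: str = "current"
    mode: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        v = self.values[~self.mask]
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("suitability values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lon_centers(self) -> np.ndarray:
        return lon_centers(self.origin_lon, self.res_arcmin, self.shape[1])

    @property
    def lat_centers(self) -> np.ndarray:
        return lat_centers(self.origin_lat, self.res_arcmin, self.shape[0])


@dataclass
class BinaryMap:
    """Thresholded suitability with the threshold recorded."""

    origin_lon: float
    origin_lat: float
    res_arcmin: float
    values: np.ndarray  # boolean
    threshold: float
    species_id: str = ""
    scenario: str = "current"
    mode: str = "current"


@dataclass
class RangeSummary:
    """Range metrics for one species x scenario x prediction mode."""

    species_id: str
    scenario: str
    mode: str
    area_km2: float
    centroid_lon: float
    centroid_lat: float
    shift_km: float
    restricted_to_occupied: bool = False


def make_decoupled_inputs(current: EnvGrid, future: ScenarioSpec, mode: str) -> EnvGrid:
    """Combine current and future layers so that only one set changes.

    mode "both": future climate and land cover; "clim": future climate with
    land cover fixed at present; "land": future land cover with climate
    fixed at present. All other layers come from the current grid.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    src = future.layer_source
    align_or_fail([current, src])
    out = current.copy()
    take = []
    if mode in ("both", "clim"):
        take += list(CLIMATE_LAYERS)
    if mode in ("both", "land"):
        take += list(LANDCOVER_LAYERS)
    missing = [n for n in take if n not in src.layers]
    if missing:
        raise KeyError(f"future layer set lacks layers: {missing}")
    for name in take:
        out.layers[name] = src.layers[name].copy()
    return out


def binarize(suit: SuitabilityMap, threshold: float,
             region_mask: np.ndarray | None = None) -> BinaryMap:
    """True where suitability >= threshold, within the unmasked region."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    ok = ~suit.mask
    if region_mask is not None:
        ok &= np.asarray(region_mask, bool)
    vals = np.where(ok, suit.values >= threshold, False)
    return BinaryMap(suit.origin_lon, suit.origin_lat, suit.res_arcmin,
                     vals, threshold, suit.species_id, suit.scenario, suit.mode)


def area_of_habitat(binary: BinaryMap, row_areas_km2: np.ndarray) -> float:
    """Total km^2 of cells classified suitable."""
    row_areas_km2 = np.asarray(row_areas_km2, float)
    if row_areas_km2.shape[0] != binary.values.shape[0]:
        raise ValueError("row-area vector length != number of rows")
    return float((binary.values.sum(axis=1) * row_areas_km2).sum())


def weighted_centroid(suit: SuitabilityMap,
                      region_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Suitability-weighted mean cell-center (lon, lat).

    Weights are the continuous suitability values only — no cell-area
    multiplier — over unmasked cells of the region.
    """
    ok = ~suit.mask
    if region_mask is not None:
        ok &= np.asarray(region_mask, bool)
    w = np.where(ok, suit.values, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero suitability mass in region; centroid undefined")
    lon = float((w * suit.lon_centers[None, :]).sum() / total)
    lat = float((w * suit.lat_centers[:, None]).sum() / total)
    return lon, lat


def shift_km(c_current: tuple[float, float], c_future: tuple[float, float]) -> float:
    """Great-circle distance (km) between two centroids given as (lon, lat)."""
    return haversine_km(c_current[0], c_current[1], c_future[0], c_future[1])


def restrict_to_occupied(suit: SuitabilityMap, occupied_cells) -> SuitabilityMap:
    """Mask every cell not currently occupied by the species."""
    keep = np.zeros(suit.shape, bool)
    for r, c in occupied_cells:
        if 0 <= r < suit.shape[0] and 0 <= c < suit.shape[1]:
            keep[r, c] = True
    new_mask = suit.mask | ~keep
    if new_mask.all():
        raise ValueError("no unmasked occupied cells; restriction is empty")
    return replace(suit, values=suit.values.copy(), mask=new_mask)


def percent_change(area_future: float, area_current: float) -> float:
    """100 * (future - current) / current."""
    if area_current <= 0:
        raise ValueError("current area must be positive")
    return 100.0 * (area_future - area_current) / area_current


def summarise_range(suit: SuitabilityMap, threshold: float, row_areas_km2: np.ndarray,
                    current_centroid: tuple[float, float] | None = None,
                    region_mask: np.ndarray | None = None,
                    restricted: bool = False) -> RangeSummary:
    """Area of habitat, centroid and shift distance for one suitability map."""
    b = binarize(suit, threshold, region_mask)
    area = area_of_habitat(b, row_areas_km2)
    lon, lat = weighted_centroid(suit, region_mask)
    d = 0.0 if current_centroid is None else shift_km(current_centroid, (lon, lat))
    return RangeSummary(suit.species_id, suit.scenario, suit.mode,
                        area, lon, lat, d, restricted)
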