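"""Gridding occurrences, sampling-bias surfaces, pseudo-absences, training tables.

A species is present in a cell if at least one record falls inside it.
Sampling effort is approximated by a Gaussian kernel density of records from
related taxa, rescaled to [0, 1]. Pseudo-absences are drawn uniformly (max
10,000 by default) from the biomes the species occupies, excluding presence
cells, and the two classes are weighted to a neutral 0.5 prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BIAS_LAYER, CLIMATE_LAYERS, LANDCOVER_LAYERS, EnvGrid
from .synth import OccurrenceSet

log = logging.getLogger(__name__)


@dataclass
class TrainingTable:
    """Presence/pseudo-absence rows with predictors, bias and case weights.

    ``data`` holds columns ``response`` (0/1), ``weight`` (> 0), ``bias``
    and one column per predictor. Presence and pseudo-absence weights sum to
    the same total, so the weighted prevalence is exactly 0.5.
    """

    data: pd.DataFrame
    predictors: list[str]
    species_id: str = ""

    def __post_init__(self) -> None:
        need = {"response", "weight", "bias", *self.predictors}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"training table lacks columns: {sorted(missing)}")
        y = self.data["response"].to_numpy()
        w = self.data["weight"].to_numpy()
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        if not ((y == 0) | (y == 1)).all():
            raise ValueError("response must be 0/1")
        if y.min() == y.max():
            raise ValueError("need at least one presence and one pseudo-absence")
        if self.data[self.predictors + ["bias"]].isna().any().any():
            raise ValueError("missing predictor values in training table")
        wp = w[y == 1].sum()
        wa = w[y == 0].sum()
        if not np.isclose(wp, wa, rtol=1e-9):
            raise ValueError(f"class weight sums differ: {wp} vs {wa}")


def read_occurrences_csv(path: str | Path, species: str | None = None) -> OccurrenceSet:
    """Read an occurrences CSV with columns species, lon, lat."""
    df = pd.read_csv(path)
    need = {"species", "lon", "lat"}
    if not need <= set(df.columns):
        raise ValueError(f"occurrence CSV needs columns {sorted(need)}")
    if species is not None:
        df = df[df["species"] == species]
    elif df["species"].nunique() > 1:
        raise ValueError("multiple species in file; pass species=")
    sp = species if species is not None else str(df["species"].iloc[0])
    pts = list(zip(df["lon"].astype(float), df["lat"].astype(float)))
    return OccurrenceSet(sp, pts, source_label=str(path))


def write_occurrences_csv(occ: OccurrenceSet, path: str | Path) -> None:
    pd.DataFrame(
        {"species": occ.species_id,
         "lon": [p[0] for p in occ.points],
         "lat": [p[1] for p in occ.points]}
    ).to_csv(path, index=False)


def grid_presences(occ: OccurrenceSet, grid: EnvGrid) -> set[tuple[int, int]]:
    """Unique (row, col) cells containing at least one record.

    Points outside the grid extent are dropped with a logged count; cell
    assignment follows the half-open cell convention.
    """
    cells: set[tuple[int, int]] = set()
    dropped = 0
    for lon, lat in occ.points:
        cell = grid.cell_of(lon, lat)
        if cell is None or grid.mask[cell]:
            dropped += 1
        else:
            cells.add(cell)
    if dropped:
        level = logging.WARNING if dropped > 0.01 * len(occ.points) else logging.INFO
        log.log(level, "%s: dropped %d/%d points outside grid/region",
                occ.species_id, dropped, len(occ.points))
    if not cells:
        raise ValueError("no occurrence points fall inside the grid extent")
    return cells


def kernel_bias(family_points: list[tuple[float, float]], grid: EnvGrid,
                bandwidth_cells: float = 10.0) -> np.ndarray:
    """Gaussian kernel density of effort points, rescaled to [0, 1].

    Distances are measured in cell units at cell centers; the surface is
    divided by its maximum over unmasked cells so the busiest cell gets 1.
    """
    if not family_points:
        raise ValueError("need at least one effort point")
    if bandwidth_cells <= 0:
        raise ValueError("bandwidth_cells must be positive")
    pts = np.asarray(family_points, float)
    px = (pts[:, 0] - grid.origin_lon) / grid.res_deg
    py = (grid.origin_lat - pts[:, 1]) / grid.res_deg
    inside = (px >= 0) & (px <= grid.n_cols) & (py >= 0) & (py <= grid.n_rows)
    if not inside.any():
        raise ValueError("all effort points fall outside the grid extent")
    cx = np.arange(grid.n_cols) + 0.5
    cy = np.arange(grid.n_rows) + 0.5
    h2 = 2.0 * bandwidth_cells ** 2
    dens = np.zeros(grid.shape)
    # chunk over points to bound memory on large point sets
    for start in range(0, len(px), 512):
        sx = px[start:start + 512]
        sy = py[start:start + 512]
        dx2 = (cx[None, :] - sx[:, None]) ** 2          # (chunk, n_cols)
        dy2 = (cy[None, :] - sy[:, None]) ** 2          # (chunk, n_rows)
        dens += np.einsum("pr,pc->rc", np.exp(-dy2 / h2), np.exp(-dx2 / h2))
    peak = dens[~grid.mask].max()
    if peak == 0:
        raise ValueError("kernel density vanishes on the study region")
    out = dens / peak
    out[grid.mask] = np.nan
    return out


def draw_pseudoabsences(presences: set[tuple[int, int]], biome_map: np.ndarray,
                        n_max: int = 10_000, seed: int = 0,
                        mask: np.ndarray | None = None) -> set[tuple[int, int]]:
    """Uniform random cells from the biomes the species occupies.

    Cells are drawn without replacement from the union of biomes containing
    at least one presence, excluding presence cells and masked cells;
    ``min(n_max, available)`` cells are returned. Deterministic given seed.
    """
    biome_map = np.asarray(biome_map)
    if mask is None:
        mask = np.zeros(biome_map.shape, bool)
    occupied = {int(biome_map[r, c]) for r, c in presences}
    eligible = np.isin(biome_map, list(occupied)) & ~np.asarray(mask, bool)
    for r, c in presences:
        eligible[r, c] = False
    rows, cols = np.nonzero(eligible)
    if rows.size == 0:
        raise ValueError("no cells available for pseudo-absences")
    n = min(n_max, rows.size)
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    return {(int(rows[i]), int(cols[i])) for i in idx}


def assemble_training(presences: set[tuple[int, int]], pabs: set[tuple[int, int]],
                      env: EnvGrid, bias: np.ndarray,
                      species_id: str = "") -> TrainingTable:
    """Build the weighted presence/pseudo-absence table.

    Presence rows get weight 1; pseudo-absence rows get weight
    n_presences / n_pseudoabsences, which pins the weighted prevalence at
    0.5. Rows with any missing predictor value are dropped (logged).
    """
    if not presences or not pabs:
        raise ValueError("need non-empty presence and pseudo-absence sets")
    predictors = [n for n in (*CLIMATE_LAYERS, *LANDCOVER_LAYERS) if n in env.layers]
    if not predictors:
        raise ValueError("environment has no predictor layers")
    bias = np.asarray(bias, float)

    def rows_for(cells, response):
        recs = []
        for r, c in sorted(cells):
            if env.mask[r, c]:
                continue
            rec = {"response": response, "row": r, "col": c,
                   "bias": float(bias[r, c])}
            for name in predictors:
                rec[name] = float(env.layers[name][r, c])
            recs.append(rec)
        return recs

    df = pd.DataFrame(rows_for(presences, 1) + rows_for(pabs, 0))
    n0 = len(df)
    df = df.dropna(subset=predictors + ["bias"])
    if len(df) < n0:
        level = logging.WARNING if n0 - len(df) > 0.01 * n0 else logging.INFO
        log.log(level, "dropped %d/%d rows with missing predictor values",
                n0 - len(df), n0)
    n_p = int((df["response"] == 1).sum())
    n_a = int((df["response"] == 0).sum())
    if n_p == 0 or n_a == 0:
        raise ValueError("a class became empty after dropping incomplete rows")
    df["weight"] = np.where(df["response"] == 1, 1.0, n_p / n_a)
    df = df.reset_index(drop=True)
    return TrainingTable(df, predictors, species_id)
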