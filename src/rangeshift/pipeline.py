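"""End-to-end study orchestration: synthesize or ingest, fit, partition,
evaluate, project under decoupled scenarios, and compare across species.

All randomness flows from a single root seed through named substreams
(derived by hashing ``root_seed:stage:species``), so a re-run with the same
configuration reproduces byte-identical CSV outputs. One species' failure
never aborts the batch; failures are recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import occurrences as occ_mod
from .comparison import compare_grid
from .evaluation import evaluate, omission_threshold, variable_importance
from .grid import EnvGrid, cell_areas_km2, write_layer
from .models import fit_ensemble, predict_ensemble, predict_table
from .partitioning import partition_batch
from .range_metrics import MODES, make_decoupled_inputs, restrict_to_occupied, summarise_range
from .synth import (
    SCENARIO_PRESETS,
    FieldSpec,
    VirtualSpecies,
    generate_environment,
    generate_future,
    sample_occurrences,
    true_suitability,
)

log = logging.getLogger(__name__)


def substream(root_seed: int, *labels) -> int:
    """Derive a reproducible child seed (< 2^31) from a root seed and labels."""
    key = f"{root_seed}:" + ":".join(str(x) for x in labels)
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2**31)


#: Default virtual species: distinct niches over the synthetic layers.
def default_species() -> list[VirtualSpecies]:
    return [
        # cold-adapted montane species: loses ground under warming
        VirtualSpecies("sp_boreal", beta={"tmax": -1.8, "pan": 0.6, "needleleaf": 0.5},
                       beta_sq={"tmax": -0.4}, intercept=-0.5, detection_gamma=0.5),
        # mesic forest species with humped precipitation response
        VirtualSpecies("sp_forest", beta={"tmin": -1.0, "broadleaf": 0.8, "pan": 0.5},
                       beta_sq={"pan": -0.5}, intercept=-0.8, detection_gamma=0.5),
        # open-habitat species tied to grassland/shrub mosaics
        VirtualSpecies("sp_steppe", beta={"tmax": -0.8, "grassland": 0.9, "shrub": 0.4},
                       beta_sq={"pcv": -0.3}, intercept=-0.8, detection_gamma=0.5),
    ]


@dataclass
class StudyConfig:
    """Everything a full run needs; defaults mirror the study settings."""

    field_spec: FieldSpec = field(default_factory=FieldSpec)
    species: list[VirtualSpecies] = field(default_factory=default_species)
    scenarios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in SCENARIO_PRESETS.items()})
    modes: tuple[str, ...] = MODES
    n_target_presences: int = 300
    n_pseudoabsences: int = 10_000
    n_effort_hubs: int = 12
    bandwidth_cells: float = 10.0
    n_biomes: int = 4
    omission_q: float = 0.05
    boyce_windows: int = 101
    boyce_window_frac: float = 0.1
    n_trees: int = 500
    stepwise: bool = True
    importance_reps: int = 3
    write_maps: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modes"] = list(self.modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "field_spec" in d and isinstance(d["field_spec"], dict):
            d["field_spec"] = FieldSpec(**d["field_spec"])
        if "species" in d:
            d["species"] = [
                sp if isinstance(sp, VirtualSpecies) else VirtualSpecies(**sp)
                for sp in d["species"]
            ]
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def make_biomes(env: EnvGrid, n_biomes: int) -> np.ndarray:
    """Integer biome ids from quantile bands of minimum temperature."""
    t = env.layers["tmin"]
    qs = np.quantile(t[~env.mask], np.linspace(0, 1, n_biomes + 1)[1:-1])
    return np.digitize(t, qs)


def make_effort_bias(env: EnvGrid, n_hubs: int, bandwidth_cells: float,
                     seed: int) -> np.ndarray:
    """Observer-effort surface: kernel density around random observer hubs."""
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, env.n_rows, n_hubs)
    cols = rng.integers(0, env.n_cols, n_hubs)
    lons = env.lon_centers
    lats = env.lat_centers
    hubs = [(float(lons[c]), float(lats[r])) for r, c in zip(rows, cols)]
    return occ_mod.kernel_bias(hubs, env, bandwidth_cells)


def run_study(config: StudyConfig, outdir: str | Path) -> Path:
    """Run the full pipeline and write its tables under ``outdir``.

    Emits partitions.csv (+ partition_summary.csv), evaluation.csv,
    importance.csv, range_summaries.csv, comparisons.csv, zscores.csv,
    suitability/binary maps (ASCII grids, optional) and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = config.seed
    fs = FieldSpec(**{**asdict(config.field_spec), "seed": substream(root, "env")})
    env = generate_environment(fs)
    bias = make_effort_bias(env, config.n_effort_hubs, config.bandwidth_cells,
                            substream(root, "hubs"))
    biomes = make_biomes(env, config.n_biomes)
    areas = cell_areas_km2(env)
    scenarios = {
        name: generate_future(env, delta, name=name)
        for name, delta in config.scenarios.items()
    }

    tables, truth = [], {}
    failures: dict[str, str] = {}
    for sp in config.species:
        try:
            suit = true_suitability(env, sp)
            occ = sample_occurrences(suit, np.nan_to_num(bias),
                                     config.n_target_presences, sp,
                                     substream(root, "occ", sp.species_id))
            presences = occ_mod.grid_presences(occ, env)
            pabs = occ_mod.draw_pseudoabsences(
                presences, biomes, config.n_pseudoabsences,
                substream(root, "pabs", sp.species_id), env.mask)
            table = occ_mod.assemble_training(presences, pabs, env,
                                              np.nan_to_num(bias), sp.species_id)
            tables.append(table)
            truth[sp.species_id] = (sp, presences, table)
        except Exception as exc:
            log.warning("preparation failed for %s: %s", sp.species_id, exc)
            failures[sp.species_id] = f"prepare: {exc}"

    part_df, part_summary, part_failed = partition_batch(
        tables, substream(root, "partition"), config.stepwise)
    for sid in part_failed:
        failures[sid] = failures.get(sid, "partition failed")
    part_df.to_csv(outdir / "partitions.csv", index=False)
    part_summary.rename("value").to_csv(outdir / "partition_summary.csv")

    eval_rows, imp_frames, range_rows = [], [], []
    maps_dir = outdir / "maps"
    if config.write_maps:
        maps_dir.mkdir(exist_ok=True)
    for table in tables:
        sid = table.species_id
        try:
            sp, presences, _ = truth[sid]
            ens = fit_ensemble(table, substream(root, "fit", sid),
                               config.stepwise, config.n_trees)
            pred = predict_table(ens, table.data)
            y = table.data["response"].to_numpy()
            report = evaluate(pred[y == 1], pred[y == 0], config.omission_q,
                              config.boyce_windows, config.boyce_window_frac)
            eval_rows.append({"species_id": sid, **asdict(report)})
            imp = variable_importance(ens, table, config.importance_reps,
                                      substream(root, "imp", sid))
            imp.insert(0, "species_id", sid)
            imp_frames.append(imp)

            current = predict_ensemble(ens, env, "max", "current", "current")
            pres_idx = tuple(np.array(sorted(presences)).T)
            thr = omission_threshold(current.values[pres_idx], config.omission_q)
            cur_sum = summarise_range(current, thr, areas)
            range_rows.append(cur_sum)
            cur_restricted = summarise_range(
                restrict_to_occupied(current, presences), thr, areas,
                restricted=True)
            range_rows.append(cur_restricted)
            cur_cent = (cur_sum.centroid_lon, cur_sum.centroid_lat)
            cur_cent_r = (cur_restricted.centroid_lon, cur_restricted.centroid_lat)
            if config.write_maps:
                _write_map(maps_dir, current, env)
            for scen_name, scen in scenarios.items():
                for mode in config.modes:
                    proj_env = make_decoupled_inputs(env, scen, mode)
                    smap = predict_ensemble(ens, proj_env, "max", scen_name, mode)
                    range_rows.append(summarise_range(smap, thr, areas, cur_cent))
                    restricted = restrict_to_occupied(smap, presences)
                    range_rows.append(summarise_range(
                        restricted, thr, areas, cur_cent_r, restricted=True))
                    if config.write_maps:
                        _write_map(maps_dir, smap, env)
        except Exception as exc:
            log.warning("modelling failed for %s: %s", sid, exc)
            failures[sid] = f"model: {exc}"

    pd.DataFrame(eval_rows).to_csv(outdir / "evaluation.csv", index=False)
    if imp_frames:
        pd.concat(imp_frames).to_csv(outdir / "importance.csv", index=False)
    summaries = pd.DataFrame([asdict(r) for r in range_rows])
    summaries.to_csv(outdir / "range_summaries.csv", index=False)

    ok_species = summaries["species_id"].nunique()
    if ok_species >= 2:
        full = summaries[~summaries["restricted_to_occupied"]]
        results, zscores = compare_grid(full)
        results.to_csv(outdir / "comparisons.csv", index=False)
        zscores.to_csv(outdir / "zscores.csv", index=False)

    manifest = {
        "config_hash": config.content_hash(),
        "root_seed": root,
        "package_version": _pkg_version("rangeshift"),
        "n_species_requested": len(config.species),
        "n_species_completed": int(ok_species),
        "failures": failures,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _write_map(maps_dir: Path, smap, env: EnvGrid) -> None:
    g = EnvGrid(smap.origin_lon, smap.origin_lat, smap.res_arcmin,
                {"suit": smap.values}, smap.mask)
    name = f"{smap.species_id}_{smap.scenario}_{smap.mode}.asc"
    write_layer(g, "suit", maps_dir / name)
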