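"""Simulate the study system: environment, effort surface, virtual species.

Generates the gridded climate/land-cover environment, the observer-effort
(sampling bias) surface, a biome map, and for each virtual species a set of
bias-thinned occurrence records with its presence/pseudo-absence training
table. Writes layers to results/env/ and tables to results/tables/.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import CONFIG, RESULTS, table_path

import rangeshift as rs
from rangeshift.grid import EnvGrid, write_layer
from rangeshift.pipeline import make_biomes, make_effort_bias, substream


def main() -> None:
    root = CONFIG.seed
    env = rs.generate_environment(rs.FieldSpec(
        **{**asdict(CONFIG.field_spec), "seed": substream(root, "env")}))
    bias = np.nan_to_num(make_effort_bias(env, CONFIG.n_effort_hubs,
                                          CONFIG.bandwidth_cells,
                                          substream(root, "hubs")))
    biomes = make_biomes(env, CONFIG.n_biomes)

    env_dir = RESULTS / "env"
    env_dir.mkdir(parents=True, exist_ok=True)
    for name in env.layers:
        write_layer(env, name, env_dir / f"{name}.asc")
    aux = EnvGrid(env.origin_lon, env.origin_lat, env.res_arcmin,
                  {"bias": bias, "biome": biomes.astype(float)}, env.mask)
    write_layer(aux, "bias", env_dir / "bias.asc")
    write_layer(aux, "biome", env_dir / "biome.asc")
    print(f"environment: {env.n_rows}x{env.n_cols} cells at "
          f"{env.res_arcmin}' resolution, {len(env.layers)} layers")

    (RESULTS / "tables").mkdir(parents=True, exist_ok=True)
    for sp in CONFIG.species:
        suit = rs.true_suitability(env, sp)
        occ = rs.sample_occurrences(suit, bias, CONFIG.n_target_presences, sp,
                                    substream(root, "occ", sp.species_id))
        presences = rs.grid_presences(occ, env)
        pabs = rs.draw_pseudoabsences(presences, biomes, CONFIG.n_pseudoabsences,
                                      substream(root, "pabs", sp.species_id),
                                      env.mask)
        table = rs.assemble_training(presences, pabs, env, bias, sp.species_id)
        table.data.to_csv(table_path(sp.species_id), index=False)
        print(f"{sp.species_id}: {len(occ.points)} records -> "
              f"{len(presences)} presence cells, {len(pabs)} pseudo-absences")


if __name__ == "__main__":
    main()
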