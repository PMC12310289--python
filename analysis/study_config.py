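"""Shared configuration for the numbered analysis scripts.

The scripts run the packaged study stage by stage, exchanging state through
``results/``: layers as ASCII grids, tables/results as CSV, fitted model
bundles as pickles. Re-running any script with the same ROOT_SEED
reproduces its outputs exactly.
"""

from pathlib import Path

import pandas as pd

from rangeshift.grid import CLIMATE_LAYERS, LANDCOVER_LAYERS
from rangeshift.occurrences import TrainingTable
from rangeshift.pipeline import StudyConfig

ROOT_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = StudyConfig(seed=ROOT_SEED, write_maps=False)


def table_path(species_id: str) -> Path:
    return RESULTS / "tables" / f"{species_id}.csv"


def model_path(species_id: str) -> Path:
    return RESULTS / "models" / f"{species_id}.pkl"


def load_table(species_id: str) -> TrainingTable:
    df = pd.read_csv(table_path(species_id))
    preds = [c for c in df.columns if c in CLIMATE_LAYERS + LANDCOVER_LAYERS]
    return TrainingTable(df, preds, species_id)
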