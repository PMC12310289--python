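"""Deviance partitioning of presence/pseudo-absence GLMs into climate,
land-cover and joint fractions.

Four weighted binomial GLMs are fit on one training table: a bias-only null,
climate + bias, land cover + bias, and climate + land cover + bias, each
non-null model reduced by stepwise AIC. With explained-deviance fractions
D_M = (dev_null - dev_M) / dev_null, the two-set partition is

    a = D_CL - D_L   (independent climate)
    b = D_CL - D_C   (independent land cover)
    c = D_C + D_L - D_CL   (joint, confounded by collinearity)

so a + b + c = D_CL identically. Components are also reported as
percentages of D_CL. Negative components (suppression, or tiny stepwise
artifacts) are reported as-is, not truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .grid import CLIMATE_LAYERS, LANDCOVER_LAYERS
from .models import fit_glm, stepwise_aic
from .occurrences import TrainingTable

log = logging.getLogger(__name__)

#: Material violation of the nesting inequality D_CL >= max(D_C, D_L);
#: stepwise reduction can leave tiny violations, larger ones indicate a
#: broken fit.
_NESTING_TOL = 0.005


@dataclass
class PartitionResult:
    """Deviances and partition components for one species."""

    species_id: str
    dev_null: float
    dev_C: float
    dev_L: float
    dev_CL: float
    D_C: float
    D_L: float
    D_CL: float
    a: float
    b: float
    c: float
    pct_a: float
    pct_b: float
    pct_c: float


def partition_deviance(table: TrainingTable, seed: int = 0,
                       stepwise: bool = True,
                       climate: tuple[str, ...] = CLIMATE_LAYERS,
                       landcover: tuple[str, ...] = LANDCOVER_LAYERS) -> PartitionResult:
    """Partition the explained deviance of one species' training table.

    The null model contains only the sampling-bias covariate (plus the
    intercept); each non-null model is the stepwise-AIC reduction of the
    full linear+quadratic model on its variable set plus bias.
    """
    clim = [p for p in climate if p in table.predictors]
    land = [p for p in landcover if p in table.predictors]
    if not clim or not land:
        raise ValueError("table must contain both climate and land-cover predictors")

    null = fit_glm(table, seed, predictors=[])
    dev_null = null.deviance
    if dev_null <= 1e-12:
        raise ValueError("null deviance is zero: degenerate response")

    def reduced(preds):
        m = fit_glm(table, seed, predictors=list(preds))
        return stepwise_aic(m, table) if stepwise else m

    dev_C = reduced(clim).deviance
    dev_L = reduced(land).deviance
    dev_CL = reduced(clim + land).deviance

    D_C = (dev_null - dev_C) / dev_null
    D_L = (dev_null - dev_L) / dev_null
    D_CL = (dev_null - dev_CL) / dev_null
    if D_CL < max(D_C, D_L) - _NESTING_TOL:
        raise RuntimeError(
            f"partition nesting violated: D_CL={D_CL:.4f} < "
            f"max(D_C={D_C:.4f}, D_L={D_L:.4f})"
        )
    a = D_CL - D_L
    b = D_CL - D_C
    c = D_C + D_L - D_CL
    if D_CL <= 0:
        raise ValueError("model explains no deviance; percentages undefined")
    return PartitionResult(table.species_id, dev_null, dev_C, dev_L, dev_CL,
                           D_C, D_L, D_CL, a, b, c,
                           100 * a / D_CL, 100 * b / D_CL, 100 * c / D_CL)


def partition_batch(tables: list[TrainingTable], seed: int = 0,
                    stepwise: bool = True) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Partition every species, continuing past per-species failures.

    Returns (per-species rows, across-species mean/SD summary of D_CL and
    the percentage components, list of failed species ids). The SD is the
    sample SD (ddof=1) and is NaN for a single species.
    """
    rows, failures = [], []
    for t in tables:
        try:
            rows.append(asdict(partition_deviance(t, seed, stepwise)))
        except Exception as exc:
            log.warning("partitioning failed for %s: %s", t.species_id, exc)
            failures.append(t.species_id)
    if not rows:
        raise RuntimeError(f"all species failed: {failures}")
    df = pd.DataFrame(rows)
    cols = ["D_CL", "pct_a", "pct_b", "pct_c"]
    summary = pd.concat({"mean": df[cols].mean(), "sd": df[cols].std(ddof=1)})
    return df, summary, failures
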