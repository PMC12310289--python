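"""Shared fixtures: virtual study cases built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import rangeshift as rs
from rangeshift.occurrences import TrainingTable
from rangeshift.pipeline import make_biomes, make_effort_bias, substream


def build_case(seed: int, alpha_cov: float = 0.5, corr_len: float = 8.0,
               n_rows: int = 50, n_cols: int = 50, n_target: int = 300,
               beta: dict | None = None, beta_sq: dict | None = None,
               gamma: float = 0.0) -> dict:
    """One virtual species with its environment, bias, cells and table."""
    env = rs.generate_environment(rs.FieldSpec(
        n_rows=n_rows, n_cols=n_cols, correlation_length=corr_len,
        alpha_cov=alpha_cov, seed=substream(seed, "env")))
    sp = rs.VirtualSpecies(
        "virtual",
        beta=beta if beta is not None else {"tmax": -1.5, "tmin": 0.8, "pan": 0.6},
        beta_sq=beta_sq if beta_sq is not None else {"tmax": -0.4},
        intercept=-0.5, detection_gamma=gamma)
    suit = rs.true_suitability(env, sp)
    bias = np.nan_to_num(make_effort_bias(env, 12, 10.0, substream(seed, "hubs")))
    occ = rs.sample_occurrences(suit, bias, n_target, sp, substream(seed, "occ"))
    presences = rs.grid_presences(occ, env)
    biomes = make_biomes(env, 4)
    pabs = rs.draw_pseudoabsences(presences, biomes, 10_000,
                                  substream(seed, "pabs"), env.mask)
    table = rs.assemble_training(presences, pabs, env, bias, sp.species_id)
    return {"env": env, "species": sp, "suit": suit, "bias": bias,
            "occ": occ, "presences": presences, "pabs": pabs,
            "biomes": biomes, "table": table}


def sim_table(seed: int, n: int = 2000, betas=(1.0, -0.8, 0.0),
              names=("x1", "x2", "x3"), intercept: float = -0.3) -> TrainingTable:
    """Training table simulated directly from a known logistic model."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(names)))
    y = (rng.random(n) < expit(intercept + X @ np.asarray(betas))).astype(int)
    if y.sum() in (0, n):
        raise ValueError("degenerate simulation")
    df = pd.DataFrame(X, columns=list(names))
    df["bias"] = rng.random(n)
    df["response"] = y
    n1 = y.sum()
    df["weight"] = np.where(y == 1, 1.0, n1 / (n - n1))
    return TrainingTable(df, list(names), "sim")


@pytest.fixture(scope="session")
def case():
    return build_case(seed=11, gamma=0.5)


@pytest.fixture(scope="session")
def ensemble(case):
    return rs.fit_ensemble(case["table"], seed=3, n_trees=200)


@pytest.fixture(scope="session")
def env_small():
    return rs.generate_environment(rs.FieldSpec(n_rows=12, n_cols=10, seed=4))
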