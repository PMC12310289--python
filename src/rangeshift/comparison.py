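"""Paired cross-species comparisons of range metrics between prediction
modes and scenarios (Wilcoxon signed-rank tests)."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon

#: Metrics compared across species.
METRICS = ("area_km2", "centroid_lon", "centroid_lat", "shift_km")


@dataclass
class ComparisonResult:
    metric: str
    pair_kind: str  # "mode" or "scenario"
    level_a: str
    level_b: str
    context: str  # the scenario (for mode pairs) or mode (for scenario pairs)
    n: int
    statistic: float
    p_value: float
    direction: int  # sign of the median paired difference (a - b)
    all_zero: bool = False


def wilcoxon_paired(x, y, metric: str = "", pair=("a", "b"), pair_kind: str = "",
                    context: str = "", zero_method: str = "drop") -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped by default (Wilcoxon's convention; pass
    ``zero_method="pratt"`` to keep them in the ranking). With no nonzero
    differences the result is defined as p = 1 with the statistic at its
    null expectation and flagged ``all_zero``. The exact null distribution
    is used when the effective n is <= 25 with no tied magnitudes; otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-d vectors")
    if x.size < 2:
        raise ValueError("need at least 2 matched pairs")
    d = x - y
    direction = int(np.sign(np.median(d)))
    nz = d[d != 0]
    if nz.size == 0:
        return ComparisonResult(metric, pair_kind, pair[0], pair[1], context,
                                x.size, 0.0, 1.0, 0, all_zero=True)
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    zm = "wilcox" if zero_method == "drop" else "pratt"
    res = _scipy_wilcoxon(d, zero_method=zm, alternative="two-sided",
                          correction=False, method=method)
    return ComparisonResult(metric, pair_kind, pair[0], pair[1], context,
                            x.size, float(res.statistic),
                            float(min(res.pvalue, 1.0)), direction)


def compare_grid(summaries: pd.DataFrame,
                 metrics=METRICS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All mode-pairs within each scenario and scenario-pairs within each mode.

    ``summaries`` needs columns species_id, scenario, mode and the metric
    columns; the "current" prediction (scenario "current", mode "current")
    participates as a scenario level available to every mode. Returns
    (test rows, per-species z-standardized metric values for plotting).

    Raises on duplicated species x scenario x mode rows or on species
    missing from any compared cell.
    """
    df = summaries.copy()
    key = ["species_id", "scenario", "mode"]
    if df.duplicated(key).any():
        dupes = df[df.duplicated(key, keep=False)][key]
        raise ValueError(f"duplicated summary rows:\n{dupes}")
    species = sorted(df["species_id"].unique())
    current = df[df["mode"] == "current"]
    future = df[df["mode"] != "current"]
    scenarios = sorted(future["scenario"].unique())
    modes = sorted(future["mode"].unique())
    scenario_levels = (["current"] if len(current) else []) + scenarios

    def vector(scenario, mode, metric):
        if scenario == "current":
            sub = current.set_index("species_id")
        else:
            sub = future[(future["scenario"] == scenario)
                         & (future["mode"] == mode)].set_index("species_id")
        missing = [s for s in species if s not in sub.index]
        if missing:
            raise ValueError(
                f"missing cells for scenario={scenario!r} mode={mode!r}: {missing}")
        return sub.loc[species, metric].to_numpy(float)

    rows = []
    for metric in metrics:
        for scen in scenarios:  # mode pairs within a scenario
            for ma, mb in itertools.combinations(modes, 2):
                rows.append(wilcoxon_paired(
                    vector(scen, ma, metric), vector(scen, mb, metric),
                    metric, (ma, mb), "mode", scen))
        for mode in modes:  # scenario pairs (incl. current) within a mode
            for sa, sb in itertools.combinations(scenario_levels, 2):
                rows.append(wilcoxon_paired(
                    vector(sa, mode, metric), vector(sb, mode, metric),
                    metric, (sa, sb), "scenario", mode))
    results = pd.DataFrame([asdict(r) for r in rows])

    # per-species z-scores across the compared cells, for plotting
    z = df.copy()
    for metric in metrics:
        z[metric] = z.groupby("species_id")[metric].transform(
            lambda v: (v - v.mean()) / v.std(ddof=0) if v.std(ddof=0) > 0 else 0.0)
    return results, z
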