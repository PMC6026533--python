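"""Orchestration of parameter grids over (selection strength, recombination rate).

A grid runs one simulation cell per ``(s, rho)`` pair, each with its own
deterministic random stream derived from the master seed, and collects the
per-cell summaries into a tidy table.  On top of the grid table sit the two
headline analyses: the per-``N_e s`` regression of log(MTF) on log(rho)
expressed as percent MTF increase per halving of rho, and the cell-by-cell
comparison of the additive and multiplicative fitness schemes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .engine import InitMode, SimParams, run_batch
from .fitness import AdditiveScheme, FitnessScheme, MultiplicativeScheme
from .stats import (
    CellSummary,
    loglog_regression,
    percent_increase_per_halving,
    summarize_cell,
)

#: Default rho grid: 12 log-spaced values spanning 0.005..20, plus the two
#: extremes 0 (perfect linkage) and 4000 (free recombination, r = 0.5).
DEFAULT_RHO_GRID = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_RHO_EXTREMES = (0.0, 4000.0)

#: Columns of the grid summary table.
GRID_COLUMNS = (
    "s", "nes", "rho", "replicates", "n_fixed", "n_similar_two",
    "n_opposite_two", "n_three", "n_all", "retained_both", "retained_any", "mtf",
)


@dataclass(frozen=True)
class GridSpec:
    """Full parameter grid: every ``(s, rho)`` pair becomes one cell.

    ``s_values`` are per-locus heterozygote advantages; for the
    multiplicative scheme each is realised as ``s_hom = s / d_dom``.
    """

    s_values: Sequence[float] = (0.002, 0.003, 0.004, 0.005, 0.006, 0.008, 0.01)
    rho_values: Sequence[float] = DEFAULT_RHO_GRID + DEFAULT_RHO_EXTREMES
    N: int = 1000
    G: int = 100_000
    replicates: int = 1000
    scheme: str = "additive"
    init_mode: InitMode = "exact_quarters"
    d_dom: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("additive", "multiplicative"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not self.s_values or not self.rho_values:
            raise ValueError("s_values and rho_values must be non-empty")

    def make_scheme(self, s: float) -> FitnessScheme:
        if self.scheme == "additive":
            return AdditiveScheme(s=s)
        return MultiplicativeScheme.from_het_advantage(s, d_dom=self.d_dom)

    def cells(self) -> List[SimParams]:
        """One SimParams per (s, rho), in deterministic order, with derived seeds."""
        out = []
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(self.s_values) * len(self.rho_values))
        k = 0
        for s in self.s_values:
            for rho in self.rho_values:
                out.append(
                    SimParams(
                        scheme=self.make_scheme(s),
                        N=self.N,
                        rho=rho,
                        G=self.G,
                        init_mode=self.init_mode,
                        replicates=self.replicates,
                        seed=int(children[k].generate_state(1)[0] % (2**31)),
                    )
                )
                k += 1
        return out


def _summary_row(summary: CellSummary, s: float, nes: float) -> Dict:
    c = summary.outcome_counts
    return {
        "s": s,
        "nes": nes,
        "rho": summary.params.rho,
        "replicates": summary.replicates,
        "n_fixed": c["Fixed"],
        "n_similar_two": c["SimilarTwo"],
        "n_opposite_two": c["OppositeTwo"],
        "n_three": c["Three"],
        "n_all": c["All"],
        "retained_both": summary.retained_both,
        "retained_any": summary.retained_any,
        "mtf": summary.mtf if summary.mtf is not None else np.nan,
    }


def run_grid(grid: GridSpec, progress: bool = False) -> pd.DataFrame:
    """Run every cell of the grid; returns one summary row per ``(s, rho)``."""
    rows = []
    for params in grid.cells():
        t0 = time.perf_counter()
        batch = run_batch(params)
        summary = summarize_cell(batch)
        s = params.scheme.het_advantage
        rows.append(_summary_row(summary, s=s, nes=2 * params.N * s))
        if progress:
            import sys
            print(
                f"cell s={s} rho={params.rho}: retained_both="
                f"{summary.retained_both}/{summary.replicates}, mtf={summary.mtf}, "
                f"{time.perf_counter() - t0:.1f}s",
                file=sys.stderr,
            )
    return pd.DataFrame(rows, columns=list(GRID_COLUMNS))


def run_manifest(grid: GridSpec, wall_time: float) -> Dict:
    """JSON-serialisable record of a grid run (parameters, seed, timing)."""
    from . import __version__

    return {
        "version": __version__,
        "grid": {
            "s_values": list(grid.s_values),
            "rho_values": list(grid.rho_values),
            "N": grid.N,
            "G": grid.G,
            "replicates": grid.replicates,
            "scheme": grid.scheme,
            "init_mode": grid.init_mode,
            "d_dom": grid.d_dom,
            "seed": grid.seed,
        },
        "wall_time_s": wall_time,
    }


def reproduce_mtf_table(
    grid_df: pd.DataFrame,
    rho_min: float = 0.005,
    rho_max: float = 20.0,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-``N_e s`` effect of rho on MTF: percent increase per halving + p-value.

    For each selection strength, regresses log(MTF) on log(rho) over cells
    with rho inside ``[rho_min, rho_max]`` and a defined MTF (rho = 0 has no
    log; rho beyond the grid is saturated free recombination; cells where
    fewer than half the replicates fixed have no MTF).  Rows with fewer than
    ``min_cells`` usable cells are marked not quantifiable (NaN).
    """
    rows = []
    for nes, sub in grid_df.groupby("nes"):
        usable = sub[
            (sub["rho"] >= rho_min) & (sub["rho"] <= rho_max) & sub["mtf"].notna()
        ]
        if len(usable) < min_cells:
            rows.append({"nes": nes, "pct_increase_per_halving": np.nan,
                         "pvalue": np.nan, "n_cells": len(usable)})
            continue
        reg = loglog_regression(list(zip(usable["rho"], usable["mtf"])))
        rows.append({
            "nes": nes,
            "pct_increase_per_halving": percent_increase_per_halving(reg.slope),
            "pvalue": reg.pvalue,
            "n_cells": reg.n,
        })
    return pd.DataFrame(rows).sort_values("nes").reset_index(drop=True)


def compare_schemes(
    grid_additive: pd.DataFrame, grid_multiplicative: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell difference in retention between the two fitness schemes.

    Both tables must cover the same ``(nes, rho)`` cells.  Returns one row
    per cell with the absolute difference in the retained-both percentage;
    the maximum over cells is the headline agreement figure.
    """
    keys = ["nes", "rho"]
    a = grid_additive[keys + ["replicates", "retained_both"]].copy()
    m = grid_multiplicative[keys + ["replicates", "retained_both"]].copy()
    merged = a.merge(m, on=keys, suffixes=("_add", "_mult"))
    if len(merged) != len(a) or len(merged) != len(m):
        raise ValueError("grids do not cover the same (nes, rho) cells")
    merged["retained_both_pct_add"] = (
        100.0 * merged["retained_both_add"] / merged["replicates_add"]
    )
    merged["retained_both_pct_mult"] = (
        100.0 * merged["retained_both_mult"] / merged["replicates_mult"]
    )
    merged["abs_diff_pct"] = (
        merged["retained_both_pct_add"] - merged["retained_both_pct_mult"]
    ).abs()
    return merged


def max_scheme_difference(comparison: pd.DataFrame) -> float:
    """Maximum per-cell retained-both difference, in percentage points."""
    return float(comparison["abs_diff_pct"].max())
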