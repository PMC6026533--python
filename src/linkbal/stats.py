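"""Aggregate statistics over replicate simulations.

Covers the three quantities used to characterise how linkage affects the
retention of balanced polymorphism:

* retention proportions — how many replicates keep one or both loci
  polymorphic to the simulation horizon;
* the median time to fixation (MTF) at locus 1, treating replicates that
  never fixed as right-censored beyond the horizon;
* ordinary least-squares regressions of log(MTF) and log(retained count + 1)
  on log(rho), whose slope is translated into the percent change per halving
  of the recombination rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .engine import OUTCOMES, BatchResult, ReplicateResult, SimParams

#: Outcomes in which both loci are still polymorphic at the horizon.
BOTH_POLYMORPHIC = frozenset({"OppositeTwo", "Three", "All"})
#: Outcomes in which at least one locus is still polymorphic.
ANY_POLYMORPHIC = BOTH_POLYMORPHIC | {"SimilarTwo"}


@dataclass
class CellSummary:
    """Aggregate of one parameter cell."""

    params: SimParams
    outcome_counts: Dict[str, int]
    retained_both: int
    retained_any: int
    mtf: Optional[float]

    @property
    def replicates(self) -> int:
        return sum(self.outcome_counts.values())

    @property
    def retained_both_pct(self) -> float:
        return 100.0 * self.retained_both / self.replicates

    @property
    def retained_any_pct(self) -> float:
        return 100.0 * self.retained_any / self.replicates


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    pvalue: float
    stderr: float
    n: int


def median_time_to_fixation(
    fix_gens: Sequence[Optional[float]], G: int
) -> Optional[float]:
    """Median fixation generation with right-censoring at the horizon ``G``.

    ``None`` (or any value > G, or 0 from the batch encoding) marks a
    censored replicate, ranked after every observed fixation time.  The
    lower-median convention is used for even counts so the MTF is always an
    attained fixation generation.  Returns ``None`` when the median position
    falls among the censored replicates, i.e. when fewer than half of the
    replicates fixed.
    """
    arr = [np.inf if g is None or g == 0 or g > G else float(g) for g in fix_gens]
    if not arr:
        raise ValueError("fix_gens must be non-empty")
    n = len(arr)
    med = np.partition(np.asarray(arr), (n - 1) // 2)[(n - 1) // 2]
    return None if np.isinf(med) else float(med)


def loglog_regression(points: Sequence[tuple]) -> RegressionResult:
    """OLS of log(y) on log(rho) over ``(rho, y)`` pairs, both strictly positive.

    The two-sided p-value is the usual t-test on the slope.  Natural logs are
    used; the base cancels in the percent-per-halving transform.
    """
    pts = [(float(rho), float(y)) for rho, y in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points for regression, got {len(pts)}")
    if any(rho <= 0 or y <= 0 for rho, y in pts):
        raise ValueError("all rho and y values must be > 0")
    x = np.log([p[0] for p in pts])
    y = np.log([p[1] for p in pts])
    res = sps.linregress(x, y)
    return RegressionResult(res.slope, res.intercept, res.pvalue, res.stderr, len(pts))


def percent_increase_per_halving(slope: float) -> float:
    """Percent change in the response when rho is halved, from a log-log slope.

    Halving rho multiplies the response by ``2**(-slope)``, so the percent
    change is ``(2**(-slope) - 1) * 100``; a negative slope gives a positive
    increase.
    """
    if not np.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    return (2.0 ** (-slope) - 1.0) * 100.0


def retention_count_regression(points: Sequence[tuple]) -> RegressionResult:
    """OLS of log(retained count + 1) on log(rho).

    Adding one keeps the response defined when no replicate retained both
    polymorphisms (range log(1)..log(replicates + 1)).
    """
    pts = [(float(rho), float(c)) for rho, c in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points for regression, got {len(pts)}")
    if any(rho <= 0 or c < 0 for rho, c in pts):
        raise ValueError("rho must be > 0 and counts >= 0")
    x = np.log([p[0] for p in pts])
    y = np.log([p[1] + 1.0 for p in pts])
    res = sps.linregress(x, y)
    return RegressionResult(res.slope, res.intercept, res.pvalue, res.stderr, len(pts))


def summarize_cell(
    results: Union[BatchResult, Iterable[ReplicateResult]],
    params: Optional[SimParams] = None,
) -> CellSummary:
    """Tabulate outcome categories, retention counts and the locus-1 MTF."""
    if isinstance(results, BatchResult):
        params = results.params
        outcomes = list(results.outcomes)
        fix1: list = list(results.fix_gen_locus1)
    else:
        results = list(results)
        if not results:
            raise ValueError("results must be non-empty")
        if params is None:
            raise ValueError("params is required for a list of ReplicateResult")
        outcomes = [r.outcome for r in results]
        fix1 = [r.fix_gen_locus1 for r in results]
    counts = {cat: 0 for cat in OUTCOMES}
    for o in outcomes:
        counts[o] += 1
    retained_both = sum(counts[c] for c in BOTH_POLYMORPHIC)
    retained_any = sum(counts[c] for c in ANY_POLYMORPHIC)
    return CellSummary(
        params=params,
        outcome_counts=counts,
        retained_both=retained_both,
        retained_any=retained_any,
        mtf=median_time_to_fixation(fix1, params.G),
    )
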