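"""Forward-time Wright-Fisher dynamics of two linked loci under balancing selection.

The state of a population of ``N`` diploids is the vector of counts of the
four gamete haplotypes (AB, Ab, aB, ab) out of ``2N``.  Each generation the
deterministic selection-recombination recursion gives the expected gamete
frequencies in the next generation, and genetic drift is applied as a single
multinomial draw of ``2N`` gametes.  There is no mutation: once a locus fixes
(allele frequency 0 or 1) it stays fixed, and a replicate stops as soon as
both loci are fixed.

The recursion for expected gamete frequencies is the standard two-locus
selection + recombination update under random mating.  With haplotype
frequencies ``x``, fitness matrix ``f``, marginal fitnesses
``w_i = sum_j f(i,j) x_j``, mean fitness ``wbar = sum_i x_i w_i``, linkage
disequilibrium ``D = x1*x4 - x2*x3`` and double-heterozygote fitness
``w_dh = f(AB, ab)``::

    x1' = (x1*w1 - r*w_dh*D) / wbar      x2' = (x2*w2 + r*w_dh*D) / wbar
    x4' = (x4*w4 - r*w_dh*D) / wbar      x3' = (x3*w3 + r*w_dh*D) / wbar

Recombination only reshuffles alleles between loci, so the marginal allele
frequencies after the update do not depend on ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

from .fitness import HAPLOTYPES, FitnessScheme, fitness_matrix

OUTCOMES = ("Fixed", "SimilarTwo", "OppositeTwo", "Three", "All")

InitMode = Literal["exact_quarters", "random_half"]


def rho_to_r(rho: float, n_e: float) -> float:
    """Convert the population-scaled recombination rate ``rho = 4*N_e*r`` to ``r``.

    ``r`` is a probability of recombination between the two loci per meiosis
    and cannot exceed 0.5 (free recombination); larger implied values are
    clamped with a warning.
    """
    if rho < 0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    if n_e <= 0:
        raise ValueError(f"N_e must be > 0, got {n_e}")
    r = rho / (4.0 * n_e)
    if r > 0.5:
        warnings.warn(
            f"rho={rho} with N_e={n_e} implies r={r:.3g} > 0.5; clamping to 0.5 "
            "(free recombination)",
            stacklevel=2,
        )
        return 0.5
    return r


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation cell.

    Attributes
    ----------
    scheme:
        Fitness scheme (additive or multiplicative).
    N:
        Number of diploid individuals (2N gametes per generation).
    rho:
        Population-scaled recombination rate ``4 * N_e * r`` with
        ``N_e = 2N``.
    G:
        Maximum number of generations.
    init_mode:
        ``exact_quarters`` starts every replicate at counts
        ``(N/2, N/2, N/2, N/2)``; ``random_half`` assigns allele A to a
        uniformly chosen half of the 2N gametes and, independently, allele B
        to another uniformly chosen half.
    replicates:
        Number of independent replicates.
    seed:
        Seed for the cell's random stream (optional; a fresh generator is
        used when omitted and no explicit ``rng`` is supplied).
    """

    scheme: FitnessScheme
    N: int = 1000
    rho: float = 0.0
    G: int = 100_000
    init_mode: InitMode = "exact_quarters"
    replicates: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.G < 1:
            raise ValueError(f"G must be >= 1, got {self.G}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.init_mode not in ("exact_quarters", "random_half"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def n_e(self) -> int:
        """Effective population size ``2N`` (the number of gametes sampled)."""
        return 2 * self.N

    @property
    def r(self) -> float:
        """Per-generation recombination fraction implied by ``rho``."""
        return rho_to_r(self.rho, self.n_e)


@dataclass
class ReplicateResult:
    """Outcome of a single replicate.

    ``fix_gen_locus1`` / ``fix_gen_locus2`` are the first generation at which
    the locus fixed, or ``None`` if it was still polymorphic at generation
    ``G`` (censored).  ``final_presence`` lists the haplotypes with nonzero
    count at the end of the replicate.
    """

    fix_gen_locus1: Optional[int]
    fix_gen_locus2: Optional[int]
    final_presence: tuple
    outcome: str
    trajectory: Optional[np.ndarray] = None  # columns: generation, freq_A, freq_B


@dataclass
class BatchResult:
    """Vectorised outcome of all replicates of one parameter cell.

    ``fix_gen_locus1``/``fix_gen_locus2`` hold 0 for censored replicates
    (fixation generations are always >= 1).
    """

    params: SimParams
    fix_gen_locus1: np.ndarray  # (R,) int, 0 = censored at G
    fix_gen_locus2: np.ndarray
    final_counts: np.ndarray  # (R, 4) haplotype counts at termination
    outcomes: np.ndarray  # (R,) str

    @property
    def replicates(self) -> int:
        return len(self.fix_gen_locus1)

    def iter_results(self) -> Iterator[ReplicateResult]:
        for k in range(self.replicates):
            yield ReplicateResult(
                fix_gen_locus1=int(self.fix_gen_locus1[k]) or None,
                fix_gen_locus2=int(self.fix_gen_locus2[k]) or None,
                final_presence=tuple(
                    h for h, c in zip(HAPLOTYPES, self.final_counts[k]) if c > 0
                ),
                outcome=str(self.outcomes[k]),
            )


def expected_gamete_frequencies(
    state: np.ndarray, scheme: FitnessScheme, r: float
) -> np.ndarray:
    """Post-selection, post-recombination expected gamete frequencies.

    ``state`` is a length-4 vector of haplotype frequencies (must sum to 1
    within 1e-8).  Returns a length-4 probability vector.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"state must have shape (4,), got {x.shape}")
    if np.any(x < -1e-12):
        raise ValueError("haplotype frequencies must be non-negative")
    if abs(x.sum() - 1.0) > 1e-8:
        raise ValueError(f"haplotype frequencies must sum to 1, got {x.sum()}")
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"r must be in [0, 0.5], got {r}")
    f = fitness_matrix(scheme)
    return _step(x[None, :], f, float(f[0, 3]), r)[0]


def _step(x: np.ndarray, f: np.ndarray, w_dh: float, r: float) -> np.ndarray:
    """Vectorised recursion over rows of ``x`` (shape (R, 4)). No validation."""
    w = x @ f  # marginal fitnesses; f is symmetric
    xw = x * w
    wbar = xw.sum(axis=1, keepdims=True)
    if r > 0.0:
        d = x[:, 0] * x[:, 3] - x[:, 1] * x[:, 2]
        adj = r * w_dh * d
        xw[:, 0] -= adj
        xw[:, 3] -= adj
        xw[:, 1] += adj
        xw[:, 2] += adj
    out = xw / wbar
    # guard against tiny negative round-off
    np.clip(out, 0.0, None, out=out)
    out /= out.sum(axis=1, keepdims=True)
    return out


def sample_next_generation(
    expected: np.ndarray, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the next generation's haplotype counts: multinomial(2N, expected)."""
    expected = np.asarray(expected, dtype=float)
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if abs(expected.sum() - 1.0) > 1e-8:
        raise ValueError("expected frequencies must sum to 1")
    return rng.multinomial(2 * N, expected)


def initialize(init_mode: InitMode, N: int, rng: Optional[np.random.Generator] = None,
               replicates: int = 1) -> np.ndarray:
    """Initial haplotype counts, shape ``(replicates, 4)``, each row summing to 2N.

    ``exact_quarters`` requires ``2N`` divisible by 4 and puts each haplotype
    at exactly 25%.  ``random_half`` gives allele A to exactly N of the 2N
    gametes chosen uniformly at random and, independently, allele B to
    another uniform half; the AB-count is then hypergeometric, so both allele
    frequencies start at exactly 0.5 while the initial linkage disequilibrium
    is random with mean 0.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if init_mode == "exact_quarters":
        if (2 * N) % 4 != 0:
            raise ValueError(
                f"exact_quarters requires 2N divisible by 4, got N={N}"
            )
        return np.full((replicates, 4), N // 2, dtype=np.int64)
    if init_mode == "random_half":
        if rng is None:
            raise ValueError("random_half initialization requires an rng")
        # overlap between the A-half and the B-half of the 2N gametes
        k = rng.hypergeometric(N, N, N, size=replicates)
        return np.stack([k, N - k, N - k, k], axis=1).astype(np.int64)
    raise ValueError(f"unknown init_mode {init_mode!r}")


def classify_outcome(final_presence: Sequence[str]) -> str:
    """Map the set of surviving haplotypes to one of the five outcome categories.

    Fixed (one haplotype), SimilarTwo (two haplotypes sharing an allele at
    one locus), OppositeTwo ({AB, ab} or {Ab, aB}), Three, All.
    """
    present = frozenset(final_presence)
    if not present:
        raise ValueError("final_presence must be non-empty")
    if not present <= set(HAPLOTYPES):
        raise ValueError(f"unknown haplotypes in {sorted(present)}")
    n = len(present)
    if n == 1:
        return "Fixed"
    if n == 2:
        if present in (frozenset({"AB", "ab"}), frozenset({"Ab", "aB"})):
            return "OppositeTwo"
        return "SimilarTwo"
    if n == 3:
        return "Three"
    return "All"


def run_batch(params: SimParams, rng: Optional[np.random.Generator] = None) -> BatchResult:
    """Run all replicates of one parameter cell with a vectorised engine.

    All replicates advance in lockstep; a replicate leaves the active set as
    soon as both of its loci are fixed (the state is then absorbing).  All
    randomness comes from a single generator per cell, seeded from
    ``params.seed`` when ``rng`` is not given, so a cell is reproducible from
    ``(params, seed)`` alone.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    R = params.replicates
    two_n = 2 * params.N
    f = fitness_matrix(params.scheme)
    w_dh = float(f[0, 3])
    r = params.r

    counts = initialize(params.init_mode, params.N, rng, replicates=R)
    fix1 = np.zeros(R, dtype=np.int64)
    fix2 = np.zeros(R, dtype=np.int64)
    final_counts = counts.copy()

    idx = np.arange(R)  # active replicate ids
    cur = counts.astype(np.float64)
    cur_fix1 = np.zeros(R, dtype=bool)  # locus fixed but partner still segregating
    cur_fix2 = np.zeros(R, dtype=bool)

    inv = 1.0 / two_n
    for gen in range(1, params.G + 1):
        e = _step(cur * inv, f, w_dh, r)
        cur = rng.multinomial(two_n, e).astype(np.float64)
        a1 = cur[:, 0] + cur[:, 1]
        a2 = cur[:, 0] + cur[:, 2]
        f1 = (a1 == 0) | (a1 == two_n)
        f2 = (a2 == 0) | (a2 == two_n)
        new1 = f1 & ~cur_fix1
        if new1.any():
            fix1[idx[new1]] = gen
            cur_fix1 |= f1
        new2 = f2 & ~cur_fix2
        if new2.any():
            fix2[idx[new2]] = gen
            cur_fix2 |= f2
        done = f1 & f2
        if done.any():
            final_counts[idx[done]] = cur[done].astype(np.int64)
            keep = ~done
            idx = idx[keep]
            cur = cur[keep]
            cur_fix1 = cur_fix1[keep]
            cur_fix2 = cur_fix2[keep]
            if idx.size == 0:
                break

    if idx.size:
        final_counts[idx] = cur.astype(np.int64)

    outcomes = np.array(
        [classify_outcome([h for h, c in zip(HAPLOTYPES, row) if c > 0])
         for row in final_counts],
        dtype=object,
    )
    return BatchResult(
        params=params,
        fix_gen_locus1=fix1,
        fix_gen_locus2=fix2,
        final_counts=final_counts,
        outcomes=outcomes,
    )


def run_replicate(
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    record_trajectory: bool = False,
) -> ReplicateResult:
    """Run a single replicate; optionally records (generation, p, q) each generation."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    two_n = 2 * params.N
    f = fitness_matrix(params.scheme)
    w_dh = float(f[0, 3])
    r = params.r

    counts = initialize(params.init_mode, params.N, rng, replicates=1)[0].astype(float)
    fix1: Optional[int] = None
    fix2: Optional[int] = None
    traj = [] if record_trajectory else None
    inv = 1.0 / two_n

    for gen in range(1, params.G + 1):
        e = _step(counts[None, :] * inv, f, w_dh, r)[0]
        counts = rng.multinomial(two_n, e).astype(float)
        a1 = counts[0] + counts[1]
        a2 = counts[0] + counts[2]
        if traj is not None:
            traj.append((gen, a1 * inv, a2 * inv))
        if fix1 is None and a1 in (0, two_n):
            fix1 = gen
        if fix2 is None and a2 in (0, two_n):
            fix2 = gen
        if fix1 is not None and fix2 is not None:
            break

    presence = tuple(h for h, c in zip(HAPLOTYPES, counts) if c > 0)
    return ReplicateResult(
        fix_gen_locus1=fix1,
        fix_gen_locus2=fix2,
        final_presence=presence,
        outcome=classify_outcome(presence),
        trajectory=np.array(traj) if traj is not None else None,
    )


def linkage_disequilibrium(state: np.ndarray) -> float:
    """``D = x_AB * x_ab - x_Ab * x_aB`` for a frequency vector."""
    x = np.asarray(state, dtype=float)
    return float(x[0] * x[3] - x[1] * x[2])
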