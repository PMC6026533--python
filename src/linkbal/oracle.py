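"""Exact Markov-chain validation of the simulator at tiny population sizes.

For a handful of diploids the full chain on haplotype-count states is small
enough to build explicitly: states are the compositions of ``2N`` gametes
into four haplotype counts, and the transition from state ``u`` to ``v`` is
the multinomial probability of drawing counts ``v`` with the expected gamete
frequencies computed from ``u``.  Absorption probabilities and expected
hitting times then come from the standard linear solves, giving an exact
ground truth the stochastic engine can be checked against.

The oracle deliberately reuses the engine's expected-frequency recursion: it
validates the drift/absorption machinery (multinomial sampling, fixation
bookkeeping), while the recursion itself is validated separately against
closed-form and enumeration examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .engine import _step
from .fitness import HAPLOTYPES, FitnessScheme, fitness_matrix

_MAX_N = 4  # 165 states at N=4; beyond that the chain is pointlessly large


@dataclass(frozen=True)
class ChainSpec:
    """Specification of the finite chain: diploid count, fitness scheme, r."""

    N: int
    scheme: FitnessScheme
    r: float

    def __post_init__(self) -> None:
        if not 1 <= self.N <= _MAX_N:
            raise ValueError(f"oracle requires 1 <= N <= {_MAX_N}, got {self.N}")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"r must be in [0, 0.5], got {self.r}")


def enumerate_states(two_n: int) -> np.ndarray:
    """All compositions of ``two_n`` into 4 non-negative counts, shape (S, 4)."""
    states = [
        (i, j, k, two_n - i - j - k)
        for i, j, k in product(range(two_n + 1), repeat=3)
        if i + j + k <= two_n
    ]
    return np.array(states, dtype=np.int64)


def build_transition_matrix(spec: ChainSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition matrix over count states.

    Returns ``(states, P)`` where ``states`` has shape (S, 4) and ``P[u, v]``
    is the probability of moving from ``states[u]`` to ``states[v]`` in one
    generation.
    """
    two_n = 2 * spec.N
    states = enumerate_states(two_n)
    f = fitness_matrix(spec.scheme)
    probs = _step(states / two_n, f, float(f[0, 3]), spec.r)  # (S, 4)

    # multinomial log-pmf of every target state under every source's probs;
    # flooring at 1e-300 lets exp() underflow zero-probability moves to 0
    log_coef = gammaln(two_n + 1) - gammaln(states + 1).sum(axis=1)  # (S,)
    logp = np.log(np.maximum(probs, 1e-300))  # (S, 4)
    counts = states.astype(float)
    term = logp @ counts.T  # term[u, v] = sum_h states[v, h] * logp[u, h]
    P = np.exp(term + log_coef[None, :])
    return states, P


def _state_index(states: np.ndarray, state: Sequence[int]) -> int:
    match = np.flatnonzero((states == np.asarray(state)).all(axis=1))
    if match.size != 1:
        raise ValueError(f"state {tuple(state)} not in chain")
    return int(match[0])


@dataclass
class AbsorptionSummary:
    """Exact absorption quantities from a given start state."""

    fixation_probs: Dict[str, float]  # per fixed-haplotype absorbing state
    prob_locus1_fixes_A: float
    expected_time_locus1: float  # expected generations to locus-1 fixation
    expected_time_both: float  # expected generations to double fixation


def absorption_summary(spec: ChainSpec, start: Sequence[int]) -> AbsorptionSummary:
    """Solve the chain for absorption probabilities and expected hitting times.

    ``start`` is a haplotype-count 4-tuple summing to 2N.  The four
    monomorphic states (all gametes one haplotype) are the absorbing states;
    locus-level quantities lump the states where that locus has fixed.
    """
    two_n = 2 * spec.N
    if sum(start) != two_n:
        raise ValueError(f"start counts must sum to 2N={two_n}, got {tuple(start)}")
    states, P = build_transition_matrix(spec)
    s0 = _state_index(states, start)
    S = len(states)

    absorbing = np.flatnonzero((states == two_n).any(axis=1))
    transient = np.flatnonzero(~np.isin(np.arange(S), absorbing))
    Q = P[np.ix_(transient, transient)]
    R = P[np.ix_(transient, absorbing)]
    iq = np.eye(len(transient)) - Q

    fix_probs: Dict[str, float]
    if s0 in absorbing:
        fix_probs = {
            h: float(states[s0, k] == two_n) for k, h in enumerate(HAPLOTYPES)
        }
        time_both = 0.0
    else:
        t_pos = int(np.flatnonzero(transient == s0)[0])
        B = np.linalg.solve(iq, R)
        fix_probs = {}
        for col, a_idx in enumerate(absorbing):
            h = HAPLOTYPES[int(np.argmax(states[a_idx]))]
            fix_probs[h] = float(B[t_pos, col])
        time_both = float(np.linalg.solve(iq, np.ones(len(transient)))[t_pos])

    # locus-1 fixation: absorbing class = states with allele-A count 0 or 2N
    a_count = states[:, 0] + states[:, 1]
    def _hitting_time(fixed_mask: np.ndarray) -> float:
        trans = np.flatnonzero(~fixed_mask)
        if fixed_mask[s0]:
            return 0.0
        pos = int(np.flatnonzero(trans == s0)[0])
        Qm = P[np.ix_(trans, trans)]
        t = np.linalg.solve(np.eye(len(trans)) - Qm, np.ones(len(trans)))
        return float(t[pos])

    l1_fixed = (a_count == 0) | (a_count == two_n)
    time_l1 = _hitting_time(l1_fixed)

    # probability that locus 1 fixes on allele A (absorbing class a_count == 2N)
    if l1_fixed[s0]:
        p_a = float(a_count[s0] == two_n)
    else:
        trans = np.flatnonzero(~l1_fixed)
        pos = int(np.flatnonzero(trans == s0)[0])
        Qm = P[np.ix_(trans, trans)]
        r_vec = P[np.ix_(trans, np.flatnonzero(a_count == two_n))].sum(axis=1)
        p_a = float(np.linalg.solve(np.eye(len(trans)) - Qm, r_vec)[pos])

    return AbsorptionSummary(
        fixation_probs=fix_probs,
        prob_locus1_fixes_A=p_a,
        expected_time_locus1=time_l1,
        expected_time_both=time_both,
    )
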