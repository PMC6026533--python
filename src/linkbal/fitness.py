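"""Diploid genotype fitness for two linked loci under symmetric overdominance.

Two fitness schemes are provided:

* :class:`AdditiveScheme` — fitness is 1 plus ``s`` for every heterozygous
  locus, so double homozygotes have fitness 1, single heterozygotes ``1 + s``
  and double heterozygotes ``1 + 2s``.  Writing the four genotype-class
  fitnesses as ``a`` (double homozygote), ``b``, ``c`` (single heterozygotes)
  and ``d`` (double heterozygote), the scheme satisfies the additive
  no-epistasis condition ``a - b - c + d = 0`` exactly.

* :class:`MultiplicativeScheme` — per-locus fitness factors are multiplied.
  Symmetric overdominance is approximated by giving heterozygotes a factor
  ``1 + d_dom * s_hom`` with a very large dominance coefficient ``d_dom`` and
  a correspondingly tiny homozygote coefficient ``s_hom``, so the two
  homozygotes differ in fitness by a negligible ``s_hom``.  This is the
  scheme used by generic forward simulators that parameterise selection via
  (dominance, homozygote effect) pairs.

Haplotypes are indexed 0..3 in the fixed order AB, Ab, aB, ab, where the
first letter is the allele at locus 1 and the second the allele at locus 2.
In the multiplicative scheme the uppercase alleles A and B are the "derived"
alleles carrying ``s_hom`` when homozygous; the asymmetry is negligible by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

#: Canonical haplotype labels in index order.
HAPLOTYPES = ("AB", "Ab", "aB", "ab")

# Allele indicator per haplotype: 1 = uppercase (A or B), 0 = lowercase.
_LOCUS1 = np.array([1, 1, 0, 0], dtype=np.int8)
_LOCUS2 = np.array([1, 0, 1, 0], dtype=np.int8)


@dataclass(frozen=True)
class AdditiveScheme:
    """Additive overdominance: fitness ``1 + s * (number of heterozygous loci)``.

    Parameters
    ----------
    s:
        Heterozygote advantage per locus (relative fitness increment, >= 0).
    """

    s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.s) or self.s < 0:
            raise ValueError(f"selection coefficient s must be >= 0, got {self.s}")

    @property
    def het_advantage(self) -> float:
        """Per-locus heterozygote advantage (equals ``s``)."""
        return self.s


@dataclass(frozen=True)
class MultiplicativeScheme:
    """Multiplicative overdominance approximation with a large dominance coefficient.

    Per-locus fitness factor: 1 for the ancestral homozygote, ``1 + s_hom``
    for the derived homozygote, ``1 + d_dom * s_hom`` for the heterozygote.
    Total fitness is the product of the two per-locus factors (background
    fitness fixed at 1; only two sites are modelled).

    Parameters
    ----------
    d_dom:
        Dominance coefficient, very large (default 1e6).
    s_hom:
        Homozygote selection coefficient, very small; pick
        ``s_hom = target_s / d_dom`` so ``d_dom * s_hom`` is the desired
        per-locus heterozygote advantage.
    """

    s_hom: float
    d_dom: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_dom) or self.d_dom <= 0:
            raise ValueError(f"d_dom must be > 0, got {self.d_dom}")
        if not np.isfinite(self.s_hom) or self.s_hom < 0:
            raise ValueError(f"s_hom must be >= 0, got {self.s_hom}")

    @classmethod
    def from_het_advantage(cls, s: float, d_dom: float = 1_000_000.0) -> "MultiplicativeScheme":
        """Build a scheme whose heterozygote advantage ``d_dom * s_hom`` equals ``s``."""
        return cls(s_hom=s / d_dom, d_dom=d_dom)

    @property
    def het_advantage(self) -> float:
        """Per-locus heterozygote advantage ``d_dom * s_hom``."""
        return self.d_dom * self.s_hom


FitnessScheme = Union[AdditiveScheme, MultiplicativeScheme]


def _check_index(i: int) -> int:
    if not isinstance(i, (int, np.integer)) or not 0 <= i <= 3:
        raise ValueError(f"haplotype index must be an integer in 0..3, got {i!r}")
    return int(i)


def genotype_fitness(scheme: FitnessScheme, hap_i: int, hap_j: int) -> float:
    """Relative fitness of the diploid formed by haplotypes ``hap_i`` and ``hap_j``.

    Indices follow the order AB=0, Ab=1, aB=2, ab=3.  Symmetric in its two
    haplotype arguments.
    """
    i = _check_index(hap_i)
    j = _check_index(hap_j)
    return float(fitness_matrix(scheme)[i, j])


def fitness_matrix(scheme: FitnessScheme) -> np.ndarray:
    """4x4 symmetric matrix of genotype fitnesses ``f[i, j]`` over haplotype pairs."""
    het1 = _LOCUS1[:, None] != _LOCUS1[None, :]
    het2 = _LOCUS2[:, None] != _LOCUS2[None, :]
    if isinstance(scheme, AdditiveScheme):
        return 1.0 + scheme.s * (het1.astype(float) + het2.astype(float))
    if isinstance(scheme, MultiplicativeScheme):
        f = np.ones((4, 4))
        for het, allele in ((het1, _LOCUS1), (het2, _LOCUS2)):
            hom_derived = (~het) & (allele[:, None] == 1)
            factor = np.where(
                het,
                1.0 + scheme.d_dom * scheme.s_hom,
                np.where(hom_derived, 1.0 + scheme.s_hom, 1.0),
            )
            f = f * factor
        return f
    raise TypeError(f"unknown fitness scheme: {scheme!r}")


def epistasis_residual(scheme: FitnessScheme) -> float:
    """Additive-epistasis residual ``a - b - c + d`` of the genotype fitness table.

    ``a`` is the double-homozygote fitness, ``b`` and ``c`` the two single
    heterozygote fitnesses, ``d`` the double-heterozygote fitness (all built
    from the AB haplotype against AB, Ab, aB and ab respectively).  Zero means
    no epistasis in the additive sense; the additive scheme returns exactly 0,
    the multiplicative scheme approximately ``het_advantage ** 2``.
    """
    f = fitness_matrix(scheme)
    a = f[0, 0]
    b = f[0, 1]
    c = f[0, 2]
    d = f[0, 3]
    return float(a - b - c + d)
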