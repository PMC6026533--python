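# Methods

## Model and assumptions

Two biallelic loci (alleles A/a and B/b) are tracked through the four gamete
haplotypes AB, Ab, aB, ab in a panmictic population of `N` diploids with
discrete, non-overlapping generations, no mutation, no migration, and no
intervening sequence between the loci.  Both loci are under symmetric
balancing selection modelled as overdominance, and there is no epistasis:
the additive scheme gives a diploid fitness `1 + s·(number of heterozygous
loci)`, which satisfies `a − b − c + d = 0` over the four genotype classes
exactly.  Under these assumptions linkage confers no benefit in a
deterministic (infinite-population) model; any effect of the recombination
rate on the retention of polymorphism is a finite-population phenomenon, which
is exactly what the simulator is built to measure.

The generation update is the classical two-locus recursion: expected gamete
frequencies after selection and recombination (the `−r·w_dh·D` flux between
coupling and repulsion haplotypes), followed by one multinomial draw of `2N`
gametes.  This frequency-based Wright–Fisher update has the same
expectation as sampling diploid parents individual by individual and the
standard drift variance, and is orders of magnitude faster; the package's
own scheme-comparison analysis (additive vs multiplicative engines differing
in exactly such implementation details) bounds the effect of this choice on
retention frequencies at a few percentage points of Monte-Carlo noise.
Selection is applied before recombination inside a single expected-frequency
formula; since `f(AB,ab) = f(Ab,aB)` in both schemes the recursion needs only
the one double-heterozygote fitness `w_dh`.

A locus is fixed when its allele count is 0 or `2N` after sampling; without
mutation this is absorbing, and a replicate stops once both loci are fixed.
A replicate ending with the two complementary haplotypes ({AB, ab} or
{Ab, aB}) is *not* treated as absorbing — drift can still remove one — so
simulation continues to the horizon `G` in that case.  Fixation generations
are counted with the first sampled generation as 1; replicates still
polymorphic at `G` are right-censored.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `s` | heterozygote advantage per locus | 0.005 | dimensionless increment; `N_e·s = 2N·s` is the natural strength scale |
| `N` | diploid census size | 1000 | `N_e = 2N = 2000` gametes sampled per generation |
| `rho` | population-scaled recombination rate `4·N_e·r` | 0 | `r = rho/(4·N_e)`, clamped at 0.5 (free recombination) with a warning; `rho = 4000` at the default `N_e` gives exactly `r = 0.5` |
| `G` | horizon in generations | 100000 | = 50 `N_e` at defaults |
| `replicates` | independent runs per cell | 1000 | binomial SE on a retention percentage ≈ 1–1.6 pp |
| `init_mode` | starting state | `exact_quarters` | all four haplotypes at 25% (p = q = 0.5, D = 0); `random_half` assigns each allele to an exact random half of the gametes, so D starts random with mean 0 |
| `d_dom`, `s_hom` | multiplicative scheme | 1e6, `s/d_dom` | heterozygote factor `1 + d_dom·s_hom`; the two homozygotes differ by the negligible `s_hom` |

The default experiment grid crosses `s ∈ {0.002 … 0.01}` (`N_e·s` 4–20)
with 12 log-spaced `rho` values in [0.005, 20] plus the extremes 0 and 4000.
The exact interior grid is a package choice (declared in the run manifest);
the log–log regressions are insensitive to it beyond Monte-Carlo noise
because the response is close to a power law in `rho`.

## Statistics

* **Retention**: a replicate "retains both" when both loci are polymorphic
  at `G` (outcomes OppositeTwo, Three, All); "retains any" adds SimilarTwo.
* **MTF**: median fixation generation at locus 1, censored replicates
  ranked above every observed time.  The lower of the two middle order
  statistics is used for even counts so the MTF is always an attained
  generation; the MTF is undefined when the median position falls among
  censored replicates (fewer than half fixed).  Locus 1 alone is used; by
  the symmetry of the model locus 2 has the same distribution.
* **Effect sizes**: OLS of log(MTF) on log(rho) and of log(retained + 1) on
  log(rho), two-sided t-test on the slope, no multiple-testing correction.
  `rho = 0` cells (log undefined), `rho = 4000` cells (off-grid saturation
  at `r = 0.5`) and undefined-MTF cells are excluded.  The slope is
  reported as `(2^(−slope) − 1)·100`, the percent change per halving of
  `rho`, which is invariant to the logarithm base.

## Randomness and determinism

Each cell owns one PCG64 generator seeded from `(params, seed)`; the
vectorised batch engine advances all replicates of a cell in lockstep from
that single stream, so a cell is exactly reproducible from its parameters
and seed (and grids additionally derive per-cell seeds from the master seed
via `SeedSequence.spawn` in fixed cell order).  The scalar per-replicate
path (used for trajectory recording) instead gives each replicate its own
spawned stream.  The two paths are distributionally identical but not
draw-for-draw identical; replicate-level order independence is only claimed
for the scalar path.

## Validation strategy

* Closed-form checks of the recursion (symmetric equilibrium invariance,
  LD halving under free recombination at `s = 0`, the `|D'| ≤ s²/16` bound
  from linkage equilibrium, r-independence of marginal allele-frequency
  updates) and a brute-force enumeration of all ordered parental pairs as an
  independent oracle for the expected-gamete formula.
* Neutral-theory identities: fixation probability equals initial frequency;
  heterozygosity decays by `(1 − 1/2N)` per generation.
* An exact Markov chain over haplotype-count states (`N ≤ 4`, built from
  multinomial transition probabilities, solved by linear algebra) validates
  fixation probabilities and expected fixation times of the stochastic
  engine to within Monte-Carlo error.  The oracle reuses the engine's
  expected-frequency recursion deliberately: it is the ground truth for the
  drift/absorption machinery, while the recursion itself is validated by the
  independent enumeration above.

## Problem sizes in the shipped checks

The test suite exercises the full model at the published parameter scale
(N = 1000, G = 100,000, 300–1000 replicates per cell) for the headline
retention and effect-size checks, and uses small populations (N ≤ 100)
elsewhere so the whole suite stays in the minutes range.  The acceptance
script runs every headline cell at 1000 replicates (300 per cell for the
12-cell effect-size grid).  The scheme-agreement test uses 500 replicates
per cell, which adds ≈3 pp of Monte-Carlo noise to the compared retention
difference; its bound is widened accordingly (<10 pp rather than the <5 pp
the 1000-replicate acceptance run is compared against).

## What the simulations do and do not show

The generator *is* the study system here — the model is explicitly a
minimal idealisation, so there is no separate "real data" the synthetic runs
stand in for.  The limitations are the model's own: strictly symmetric
overdominance (equilibrium frequencies 0.5), exactly two loci, constant
selection in time and space, no mutation reintroducing variation, a single
panmictic population, and initialisation at intermediate frequencies.
Retention percentages therefore quantify the *mutual-reinforcement* effect
of linkage in the cleanest case; asymmetric selection, frequency-dependent
mechanisms, or new mutations would change the numbers (though not the
qualitative dependence on `rho`).

## Numerical choices

Expected-frequency vectors are clipped at 0 and renormalised after the
recursion to absorb float round-off before the multinomial draw.  The oracle
floors probabilities at 1e-300 inside the log-pmf so impossible transitions
underflow to zero rather than producing NaNs.  Even-count medians take the
lower middle order statistic (see above).  `rho` values implying `r > 0.5`
are clamped with a warning rather than rejected, since `rho = 4·N_e·0.5` is
the natural "free recombination" endpoint of the grid.
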