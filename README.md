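# linkbal

Forward-time simulation of **linked balanced polymorphisms without
epistasis**: two loci, each under symmetric balancing selection
(overdominance) for unrelated reasons, evolving in a finite Wright–Fisher
population with a tunable recombination rate between them.

The question the package addresses: if two balanced polymorphisms sit close
together on a chromosome but do not interact, does linkage alone help either
of them survive genetic drift?  The answer — yes, strongly, when selection
and drift are of comparable magnitude — matters for interpreting clusters of
balanced polymorphisms (immune-gene complexes, sex-linked regions,
"supergenes"), which are usually assumed to be co-adapted.  It is aimed at
population geneticists who want a reproducible, tested implementation of the
two-locus model together with an exact small-population oracle.

## Model

A population of `N` diploids is tracked as the counts of the four gamete
haplotypes AB, Ab, aB, ab out of `2N`.  Genotype fitness is additive
overdominance: `1 + s·h`, where `h` is the number of heterozygous loci —
double homozygotes have fitness 1, double heterozygotes `1 + 2s`.  Writing
the genotype-class fitnesses `a` (double hom.), `b`, `c` (single het.) and
`d` (double het.), the scheme satisfies `a − b − c + d = 0`: no epistasis in
the additive sense.  A multiplicative alternative (heterozygote factor
`1 + d_dom·s_hom` with a very large dominance coefficient, the way generic
forward simulators approximate symmetric overdominance) is also provided.

Each generation applies the deterministic selection–recombination recursion
to get expected gamete frequencies

```
x₁' = (x₁w₁ − r·w_dh·D)/w̄    x₂' = (x₂w₂ + r·w_dh·D)/w̄
x₄' = (x₄w₄ − r·w_dh·D)/w̄    x₃' = (x₃w₃ + r·w_dh·D)/w̄
```

(`wᵢ` marginal fitness, `w̄` mean fitness, `D = x₁x₄ − x₂x₃` the linkage
disequilibrium, `w_dh` the double-heterozygote fitness, `r` the
recombination fraction), then draws the next generation as one multinomial
sample of `2N` gametes.  There is no mutation, so fixation (allele frequency
0 or 1) is absorbing.  Recombination is parameterised by the
population-scaled rate `ρ = 4·N_e·r` with `N_e = 2N`.

Reported statistics: the five outcome categories (Fixed, SimilarTwo,
OppositeTwo, Three, All), the proportions of replicates retaining
polymorphism at one or both loci, the median time to fixation (MTF) at locus
1 with right-censoring at the horizon, and log–log OLS regressions of MTF
and of retained count + 1 on ρ, whose slope converts to the percent change
per halving of ρ via `(2^(−slope) − 1)·100`.

An exact Markov-chain oracle (`linkbal.oracle`) builds the full transition
matrix over haplotype-count states for `N ≤ 4` and computes absorption
probabilities and expected fixation times by linear solves, as an
independent ground truth for the stochastic engine.

## Worked example

```python
import linkbal as lb

params = lb.SimParams(
    scheme=lb.AdditiveScheme(s=0.005),  # N_e·s = 10 with N = 1000
    N=1000, rho=1.0, G=100_000, replicates=1000, seed=1,
)
summary = lb.summarize_cell(lb.run_batch(params))
print(summary.outcome_counts)
print(f"both retained: {summary.retained_both_pct:.1f}%  MTF: {summary.mtf}")
```

prints

```
{'Fixed': 704, 'SimilarTwo': 134, 'OppositeTwo': 29, 'Three': 76, 'All': 57}
both retained: 16.2%  MTF: 50960.0
```

i.e. with intermediate selection (`N_e·s = 10`) and moderate linkage
(`ρ = 1`), 16.2% of replicate populations kept *both* polymorphisms for the
full 50 `N_e` generations (the OppositeTwo + Three + All categories), and
the median replicate lost polymorphism at locus 1 after ~51,000 generations.
At `ρ = 10` the retained-both fraction collapses below 1%, while at `ρ = 0`
about 80% of replicates keep locus 1 polymorphic — linkage alone, with no
epistasis, decides the fate of the variation.

The same cell from a shell:

```sh
linkbal simulate --s 0.005 --n 1000 --rho 1 --generations 100000 \
    --replicates 1000 --seed 1 --out cell.tsv
linkbal summarize --in cell.tsv --out summary.json
```

and full grids with `linkbal grid --config grid.yaml --out-dir results/`.

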