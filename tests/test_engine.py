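"""Two-locus Wright-Fisher engine: recursion, sampling, initialization, outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkbal import (
    AdditiveScheme,
    SimParams,
    classify_outcome,
    expected_gamete_frequencies,
    initialize,
    linkage_disequilibrium,
    rho_to_r,
    run_batch,
    run_replicate,
    sample_next_generation,
)
from linkbal.fitness import fitness_matrix
from linkbal.engine import _step


class TestRhoToR:
    def test_free_recombination(self):
        assert rho_to_r(4000, 2000) == 0.5

    def test_perfect_linkage(self):
        assert rho_to_r(0, 2000) == 0.0

    def test_small_rho(self):
        assert rho_to_r(1, 2000) == pytest.approx(1.25e-4)

    def test_clamp_with_warning(self):
        with pytest.warns(UserWarning):
            assert rho_to_r(1e6, 2000) == 0.5

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            rho_to_r(-1, 2000)


class TestExpectedGameteFrequencies:
    def test_symmetric_equilibrium_is_invariant(self, additive):
        x = np.full(4, 0.25)
        for r in (0.0, 0.1, 0.5):
            assert expected_gamete_frequencies(x, additive, r) == pytest.approx(x)

    def test_neutral_recombination_decays_ld(self):
        """x=(0.5,0,0,0.5), s=0, r=0.5: D=0.25 halves in one generation."""
        out = expected_gamete_frequencies(
            [0.5, 0, 0, 0.5], AdditiveScheme(0.0), 0.5
        )
        assert out == pytest.approx([0.375, 0.125, 0.125, 0.375])

    def test_overdominance_pushes_segregating_locus_toward_half(self):
        """Locus 1 fixed on A: D=0, r irrelevant, locus-2 frequency moves to 0.5."""
        x = [0.6, 0.4, 0.0, 0.0]
        for r in (0.0, 0.3):
            out = expected_gamete_frequencies(x, AdditiveScheme(0.01), r)
            assert out[0] == pytest.approx(0.6 * 1.004 / 1.0048)
            assert out[2] == out[3] == 0.0

    def test_matches_exhaustive_parental_enumeration(self, rng):
        """Brute-force expectation over all ordered parental haplotype pairs.

        Each ordered pair (i, j) is a diploid parent with weight x_i x_j
        f(i,j); it transmits haplotype i with probability 1 - r and, if
        doubly heterozygous, the recombinant with probability r.
        """
        scheme = AdditiveScheme(0.013)
        f = fitness_matrix(scheme)
        recomb = {(0, 3): 1, (3, 0): 2, (1, 2): 0, (2, 1): 3}
        for _ in range(5):
            x = rng.dirichlet(np.ones(4))
            r = rng.uniform(0, 0.5)
            gam = np.zeros(4)
            for i in range(4):
                for j in range(4):
                    w = x[i] * x[j] * f[i, j]
                    if (i, j) in recomb:
                        gam[i] += w * (1 - r)
                        gam[recomb[(i, j)]] += w * r
                    else:
                        gam[i] += w
            gam /= gam.sum()
            out = expected_gamete_frequencies(x, scheme, r)
            assert out == pytest.approx(gam, abs=1e-12)

    def test_bad_state_rejected(self, additive):
        with pytest.raises(ValueError):
            expected_gamete_frequencies([0.5, 0.5, 0.5, 0.5], additive, 0.0)

    @given(
        raw=st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
        s=st.floats(0, 0.02),
        r=st.floats(0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_output_is_probability_vector(self, raw, s, r):
        x = np.array(raw) / np.sum(raw)
        out = expected_gamete_frequencies(x, AdditiveScheme(s), r)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        raw=st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
        s=st.floats(0, 0.02),
    )
    @settings(max_examples=50, deadline=None)
    def test_allele_frequency_update_is_r_free(self, raw, s):
        """Recombination conserves allele counts: p' identical at r=0 and r=0.5."""
        x = np.array(raw) / np.sum(raw)
        scheme = AdditiveScheme(s)
        p0 = expected_gamete_frequencies(x, scheme, 0.0)
        p5 = expected_gamete_frequencies(x, scheme, 0.5)
        assert p0[0] + p0[1] == pytest.approx(p5[0] + p5[1], abs=1e-14)
        assert p0[0] + p0[2] == pytest.approx(p5[0] + p5[2], abs=1e-14)

    def test_ld_growth_bound_from_linkage_equilibrium(self):
        """From any product-form state (D=0), one additive-map step keeps
        |D'| below s^2/16."""
        s = 0.02
        scheme = AdditiveScheme(s)
        for p in np.linspace(0.05, 0.95, 10):
            for q in np.linspace(0.05, 0.95, 10):
                x = np.array([p * q, p * (1 - q), (1 - p) * q, (1 - p) * (1 - q)])
                out = expected_gamete_frequencies(x, scheme, 0.0)
                assert abs(linkage_disequilibrium(out)) <= s**2 / 16 + 1e-15


class TestSampling:
    def test_degenerate_distribution(self, rng):
        assert np.array_equal(
            sample_next_generation([1.0, 0, 0, 0], 50, rng), [100, 0, 0, 0]
        )

    def test_zero_probability_categories_stay_zero(self, rng):
        draws = np.array(
            [sample_next_generation([0.5, 0.5, 0, 0], 10, rng) for _ in range(200)]
        )
        assert np.all(draws[:, 2:] == 0)
        assert np.all(draws.sum(axis=1) == 20)

    def test_multinomial_moments(self, rng):
        """N=1000 at equal frequencies: each count has mean 500, var 375."""
        draws = np.array(
            [sample_next_generation([0.25] * 4, 1000, rng) for _ in range(10_000)]
        )
        se_mean = np.sqrt(375 / 10_000)
        assert np.allclose(draws.mean(axis=0), 500, atol=4 * se_mean)
        assert np.allclose(draws.var(axis=0), 375, rtol=0.1)


class TestInitialize:
    def test_exact_quarters(self, rng):
        counts = initialize("exact_quarters", 1000, rng)
        assert np.array_equal(counts, [[500, 500, 500, 500]])

    def test_exact_quarters_requires_divisibility(self, rng):
        with pytest.raises(ValueError):
            initialize("exact_quarters", 3, rng)

    def test_random_half_marginals_exact(self, rng):
        counts = initialize("random_half", 1000, rng, replicates=200)
        assert np.all(counts.sum(axis=1) == 2000)
        assert np.all(counts[:, 0] + counts[:, 1] == 1000)  # allele A count
        assert np.all(counts[:, 0] + counts[:, 2] == 1000)  # allele B count

    def test_random_half_tiny_population(self, rng):
        counts = initialize("random_half", 2, rng, replicates=500)
        assert np.all(counts[:, 0] + counts[:, 1] == 2)
        assert np.all(counts[:, 0] + counts[:, 2] == 2)
        # D has mean 0: AB-count k is Hypergeometric(2N=4, N=2, N=2), mean 1
        assert counts[:, 0].mean() == pytest.approx(1.0, abs=0.1)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "presence,expected",
        [
            (("AB",), "Fixed"),
            (("ab",), "Fixed"),
            (("AB", "Ab"), "SimilarTwo"),
            (("aB", "ab"), "SimilarTwo"),
            (("AB", "ab"), "OppositeTwo"),
            (("Ab", "aB"), "OppositeTwo"),
            (("AB", "Ab", "aB"), "Three"),
            (("AB", "Ab", "aB", "ab"), "All"),
        ],
    )
    def test_categories(self, presence, expected):
        assert classify_outcome(presence) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome(())

    def test_unknown_haplotype_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome(("AB", "XY"))


class TestRunReplicate:
    def test_neutral_fixation_probability_is_initial_frequency(self):
        """s=0: allele A fixes with probability 0.5 (its initial frequency)."""
        params = SimParams(
            scheme=AdditiveScheme(0.0), N=20, rho=0.0, G=2000,
            replicates=2000, seed=42,
        )
        batch = run_batch(params)
        assert np.all(batch.fix_gen_locus1 > 0)  # all fixed well before G
        fixed_on_a = batch.final_counts[:, 0] + batch.final_counts[:, 1] == 40
        from scipy.stats import binomtest
        assert binomtest(int(fixed_on_a.sum()), 2000, 0.5).pvalue > 1e-3

    def test_heterozygosity_decays_at_neutral_rate(self):
        """Mean heterozygosity 2p(1-p) shrinks by (1 - 1/2N) per generation."""
        n, gens, reps = 50, 60, 3000
        params = SimParams(
            scheme=AdditiveScheme(0.0), N=n, rho=0.0, G=1, replicates=1, seed=0
        )
        rng = np.random.default_rng(7)
        f = fitness_matrix(params.scheme)
        counts = initialize("exact_quarters", n, rng, replicates=reps).astype(float)
        het = []
        for _ in range(gens):
            e = _step(counts / (2 * n), f, f[0, 3], 0.0)
            counts = rng.multinomial(2 * n, e).astype(float)
            p = (counts[:, 0] + counts[:, 1]) / (2 * n)
            het.append(np.mean(2 * p * (1 - p)))
        slope = np.polyfit(np.arange(gens), np.log(het), 1)[0]
        assert slope == pytest.approx(np.log(1 - 1 / (2 * n)), rel=0.05)

    def test_strong_selection_retains_polymorphism(self):
        """N_e s = 40 with perfect linkage: locus-1 fixation is rare."""
        params = SimParams(
            scheme=AdditiveScheme(0.02), N=1000, rho=0.0, G=1000,
            replicates=400, seed=3,
        )
        batch = run_batch(params)
        assert np.mean(batch.fix_gen_locus1 > 0) < 0.05

    def test_fixed_locus_never_reverts(self):
        """Without mutation a fixed locus stays fixed: final counts are
        consistent with the recorded fixation generations."""
        params = SimParams(
            scheme=AdditiveScheme(0.002), N=30, rho=1.0, G=500,
            replicates=300, seed=9, init_mode="random_half",
        )
        batch = run_batch(params)
        a1 = batch.final_counts[:, 0] + batch.final_counts[:, 1]
        fixed1 = (a1 == 0) | (a1 == 60)
        assert np.array_equal(fixed1, batch.fix_gen_locus1 > 0)

    def test_scalar_replicate_with_trajectory(self):
        params = SimParams(
            scheme=AdditiveScheme(0.005), N=20, rho=1.0, G=300,
            replicates=1, seed=5,
        )
        res = run_replicate(params, record_trajectory=True)
        assert res.outcome in ("Fixed", "SimilarTwo", "OppositeTwo", "Three", "All")
        traj = res.trajectory
        assert traj.shape[1] == 3
        assert traj[0, 0] == 1
        # frequencies bounded, and once fixed the trajectory is constant
        assert np.all((traj[:, 1:] >= 0) & (traj[:, 1:] <= 1))

    def test_r_half_loci_fix_independently(self):
        """Free recombination: joint polymorphism factorises into marginals."""
        params = SimParams(
            scheme=AdditiveScheme(0.02), N=100, rho=400.0, G=1500,
            replicates=4000, seed=21,
        )
        batch = run_batch(params)
        poly1 = batch.fix_gen_locus1 == 0
        poly2 = batch.fix_gen_locus2 == 0
        from scipy.stats import chi2_contingency
        table = np.array(
            [
                [np.sum(poly1 & poly2), np.sum(poly1 & ~poly2)],
                [np.sum(~poly1 & poly2), np.sum(~poly1 & ~poly2)],
            ]
        )
        assert table.min() > 5
        assert chi2_contingency(table).pvalue > 1e-3

    def test_perfect_linkage_correlates_fixation_times(self):
        """rho=0: the two loci behave as alleles of one locus, so their
        fixation times are positively correlated across replicates."""
        params = SimParams(
            scheme=AdditiveScheme(0.004), N=100, rho=0.0, G=5000,
            replicates=1000, seed=22,
        )
        batch = run_batch(params)
        both = (batch.fix_gen_locus1 > 0) & (batch.fix_gen_locus2 > 0)
        t1 = batch.fix_gen_locus1[both]
        t2 = batch.fix_gen_locus2[both]
        assert np.corrcoef(t1, t2)[0, 1] > 0.3

    def test_batch_deterministic_given_seed(self):
        params = SimParams(
            scheme=AdditiveScheme(0.005), N=50, rho=1.0, G=400,
            replicates=100, seed=77,
        )
        b1, b2 = run_batch(params), run_batch(params)
        assert np.array_equal(b1.fix_gen_locus1, b2.fix_gen_locus1)
        assert np.array_equal(b1.final_counts, b2.final_counts)
        assert list(b1.outcomes) == list(b2.outcomes)
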