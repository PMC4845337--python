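"""Heterozygosities, exact HWE test, null-allele EM, LD test, Bonferroni."""

import math

import numpy as np
import pytest

from estssr.genotypes import MISSING, GenotypeMatrix
from estssr.popgen import (
    AllMissingError,
    LocusGenotypeCounts,
    MonomorphicLocusError,
    TestConfig,
    bonferroni,
    expected_het,
    genotypic_ld_test,
    hwe_exact_test,
    null_allele_ml,
    observed_het,
    tally,
)
from estssr.popgen import _enumerate_log_probs

from helpers import grid_null_oracle, simulate_hwe_table


def counts_from(pairs):
    return LocusGenotypeCounts.from_genotypes(pairs)


class TestTally:
    def test_all_heterozygous(self):
        m = GenotypeMatrix("sp", ["L"], [f"i{k}" for k in range(10)], [[(1, 2)]] * 10)
        c = tally(m, "L")
        assert (c.n, c.h) == (10, 10)
        assert c.allele_counts == {1: 10, 2: 10}

    def test_hand_count(self):
        pairs = [(1, 1), (1, 2), (1, 2), (1, 2), (1, 2)]
        c = counts_from(pairs)
        assert (c.n, c.h) == (5, 4)
        assert c.allele_counts == {1: 6, 2: 4}

    def test_missing_excluded(self):
        calls = [[(1, 2)]] * 19 + [[MISSING]] * 2
        m = GenotypeMatrix("sp", ["L"], [f"i{k}" for k in range(21)], calls)
        assert tally(m, "L").n == 19

    def test_all_missing_is_failed_locus(self):
        m = GenotypeMatrix("sp", ["L"], ["a"], [[MISSING]])
        with pytest.raises(AllMissingError):
            tally(m, "L")


class TestHeterozygosity:
    def test_observed(self):
        assert observed_het(counts_from([(1, 2)] * 10)) == 1.0
        assert observed_het(counts_from([(1, 1), (1, 2), (1, 2), (1, 2), (1, 2)])) == 0.8
        assert observed_het(counts_from([(5, 5)] * 4)) == 0.0

    def test_expected_unbiased_closed_form(self):
        c = counts_from([(1, 2)] * 10)  # two alleles at 0.5 each, n=10
        assert expected_het(c) == pytest.approx(20 / 19 * 0.5)
        assert expected_het(c, unbiased=False) == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        assert expected_het(counts_from([(3, 3)] * 5)) == 0.0

    def test_algebraic_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pairs = simulate_hwe_table(rng, 21, [0.4, 0.3, 0.2, 0.1])
            c = counts_from(pairs)
            if c.n < 2:
                continue
            p = np.array(list(c.allele_counts.values())) / (2 * c.n)
            plug = 1 - np.sum(p**2)
            assert expected_het(c) == pytest.approx(2 * c.n / (2 * c.n - 1) * plug)

    def test_limit_many_equifrequent_alleles(self):
        c = counts_from([(i, i + 1) for i in range(1, 2001, 2)])
        # 1000 individuals, 2000 singleton-pair alleles -> He near 1
        assert expected_het(c) > 0.999


class TestHWEExact:
    def test_enumeration_sums_to_one(self):
        for ac in ([10, 10], [21, 13, 8], [5, 3, 2, 2], [30, 8, 2, 1, 1]):
            logps = _enumerate_log_probs(ac, 10**6)
            assert sum(math.exp(x) for x in logps) == pytest.approx(1.0, abs=1e-9)

    def test_complete_heterozygote_deficit(self):
        c = counts_from([(1, 1)] * 5 + [(2, 2)] * 5)
        assert hwe_exact_test(c) < 0.05

    def test_table_at_hwe_proportions_is_modal(self):
        c = counts_from([(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25)
        assert hwe_exact_test(c) > 0.9

    def test_monomorphic_undefined(self):
        with pytest.raises(MonomorphicLocusError):
            hwe_exact_test(counts_from([(1, 1)] * 10))

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(17)
        cfg_mc = TestConfig(hwe_method="monte_carlo", mc_reps=20_000, seed=11)
        for _ in range(5):
            pairs = simulate_hwe_table(rng, 21, [0.5, 0.3, 0.2])
            c = counts_from(pairs)
            if c.num_alleles < 2:
                continue
            p_enum = hwe_exact_test(c, TestConfig(hwe_method="enumerate"))
            p_mc = hwe_exact_test(c, cfg_mc)
            se = math.sqrt(max(p_enum * (1 - p_enum), 1e-9) / cfg_mc.mc_reps)
            assert abs(p_enum - p_mc) <= 3 * se + 1e-4

    def test_monte_carlo_reproducible_under_seed(self):
        c = counts_from([(1, 1)] * 8 + [(1, 2)] * 6 + [(2, 2)] * 7)
        cfg = TestConfig(hwe_method="monte_carlo", mc_reps=5_000, seed=3)
        assert hwe_exact_test(c, cfg) == hwe_exact_test(c, cfg)

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            c = counts_from(simulate_hwe_table(rng, 21, [0.6, 0.3, 0.1]))
            if c.num_alleles < 2:
                continue
            p = hwe_exact_test(c)
            assert 0 < p <= 1 + 1e-12


class TestNullAlleleML:
    def test_hwe_proportions_give_zero(self):
        c = counts_from([(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25)
        r, freqs = null_allele_ml(c)
        assert r == pytest.approx(0.0, abs=1e-4)
        assert sum(freqs.values()) + r == pytest.approx(1.0, abs=1e-6)

    def test_recovers_simulated_null_frequency(self):
        rng = np.random.default_rng(7)
        freqs = np.array([0.5, 0.3, 0.2])  # visible 1, 2; null
        pairs = []
        for _ in range(1000):
            a, b = rng.choice(3, size=2, p=freqs)
            if a == 2 and b == 2:
                continue  # blank, unobserved
            if a == 2:
                a = b
            if b == 2:
                b = a
            pairs.append((int(a) + 1, int(b) + 1))
        r, _ = null_allele_ml(counts_from(pairs))
        assert 0.15 <= r <= 0.25

    def test_em_matches_grid_search_oracle(self):
        tables = [(12, 8, 5), (10, 2, 9), (6, 6, 14), (20, 9, 11), (3, 1, 2)]
        for hom1, hom2, het in tables:
            pairs = [(1, 1)] * hom1 + [(2, 2)] * hom2 + [(1, 2)] * het
            r_em, _ = null_allele_ml(counts_from(pairs))
            r_grid, _ = grid_null_oracle(hom1, hom2, het)
            assert abs(r_em - r_grid) <= 2e-3

    def test_loglik_monotone(self):
        for pairs in (
            [(1, 1)] * 12 + [(2, 2)] * 8 + [(1, 2)] * 5,
            [(1, 1)] * 9 + [(1, 2)] * 2 + [(2, 3)] * 4 + [(3, 3)] * 6,
        ):
            null_allele_ml(counts_from(pairs))
            hist = null_allele_ml.last_loglik_history
            assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_missing_as_blanks_mode(self):
        pairs = [(1, 1)] * 10 + [(2, 2)] * 6 + [(1, 2)] * 4
        r_cond, _ = null_allele_ml(counts_from(pairs))
        r_blank, _ = null_allele_ml(
            counts_from(pairs), include_missing_as_blanks=True, n_blank=2
        )
        assert r_blank > 0  # two blanks are direct evidence of null homozygotes
        assert 0 <= r_cond <= 1 and 0 <= r_blank <= 1

    def test_monomorphic_undefined(self):
        with pytest.raises(MonomorphicLocusError):
            null_allele_ml(counts_from([(1, 1)] * 10))


def _ld_matrix(rng, n=20, freqs_a=(0.5, 0.3, 0.2), freqs_b=(0.6, 0.4)):
    sizes_a = [100, 102, 104][: len(freqs_a)]
    sizes_b = [200, 202, 204][: len(freqs_b)]
    ga = [tuple(sorted(rng.choice(sizes_a, 2, p=freqs_a))) for _ in range(n)]
    gb = [tuple(sorted(rng.choice(sizes_b, 2, p=freqs_b))) for _ in range(n)]
    return GenotypeMatrix(
        "sp", ["A", "B"], [f"i{k}" for k in range(n)], [[a, b] for a, b in zip(ga, gb)]
    )


class TestGenotypicLD:
    def test_perfect_association_attains_minimum_p(self):
        genos = [(100, 100), (100, 102), (102, 102), (100, 104)] * 5
        m = GenotypeMatrix(
            "sp", ["A", "B"], [f"i{k}" for k in range(20)], [[g, g] for g in genos]
        )
        cfg = TestConfig(ld_permutations=1000, seed=5)
        p = genotypic_ld_test(m, "A", "B", cfg)
        assert p < 0.01

    def test_relabeling_individuals_leaves_p_unchanged(self):
        rng = np.random.default_rng(31)
        m = _ld_matrix(rng)
        cfg = TestConfig(ld_permutations=2000, seed=8)
        p1 = genotypic_ld_test(m, "A", "B", cfg)
        m2 = GenotypeMatrix("sp", m.locus_names, [f"x{k}" for k in range(20)], m.calls)
        assert genotypic_ld_test(m2, "A", "B", cfg) == p1

    def test_too_few_genotype_classes_undefined(self):
        m = GenotypeMatrix(
            "sp", ["A", "B"], ["a", "b"], [[(1, 1), (2, 2)], [(1, 1), (2, 3)]]
        )
        with pytest.raises(ValueError):
            genotypic_ld_test(m, "A", "B")

    def test_type_i_error_calibrated(self):
        # independent loci: rejection rate at alpha=0.05 stays near nominal
        rej = 0
        n_pairs = 200
        for k in range(n_pairs):
            rng = np.random.default_rng(50_000 + k)
            m = _ld_matrix(rng, n=21)
            try:
                p = genotypic_ld_test(m, "A", "B", TestConfig(ld_permutations=1000, seed=k))
            except ValueError:
                n_pairs -= 1
                continue
            if p <= 0.05:
                rej += 1
        assert 0.01 <= rej / n_pairs <= 0.09


class TestBonferroni:
    def test_threshold_matches_panel_size(self):
        pvals = [0.001] * 11
        flags, thr = bonferroni(pvals, 0.05)
        assert thr == pytest.approx(0.05 / 11)

    def test_single_test(self):
        flags, thr = bonferroni([0.04], 0.05)
        assert thr == 0.05 and flags == [True]

    def test_flags_and_undefined_entries(self):
        flags, thr = bonferroni([0.004, 0.02, 0.6], 0.05)
        assert thr == pytest.approx(0.05 / 3)
        assert flags == [True, False, False]
        flags, thr = bonferroni([0.004, None, 0.6], 0.05)
        assert thr == pytest.approx(0.025)
        assert flags == [True, None, False]

    def test_no_defined_pvalues(self):
        flags, thr = bonferroni([None, None], 0.05)
        assert thr is None and flags == [None, None]
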