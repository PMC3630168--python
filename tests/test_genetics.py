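"""Genotype QC: allele frequencies, HWE, EM haplotypes, LD, recoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxemed import genetics
from gxemed.cohort import genotype_to_counts
from gxemed.genetics import (
    HaplotypeFreqs,
    SnpGenotypeCounts,
    allele_frequencies,
    code_dominant,
    count_genotypes,
    em_haplotype_freqs,
    hwe_test,
    ld_stats,
)
from gxemed.simulate import SimulationConfig, simulate_genotypes


def _counts(a, b, c, locus="test", major="C", minor="A"):
    return SnpGenotypeCounts(locus, a, b, c, major_allele=major, minor_allele=minor)


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "triple, expected, allele",
        [
            ((77, 63, 18), 0.313, "A"),   # minor allele stays minor
            ((44, 73, 45), 0.497, "C"),   # nominal minor is commoner: re-oriented
            ((100, 0, 0), 0.0, "A"),      # monomorphic
        ],
    )
    def test_oriented_frequency(self, triple, expected, allele):
        maf, label = allele_frequencies(_counts(*triple))
        assert maf == pytest.approx(expected, abs=5e-4)
        if triple == (44, 73, 45):
            # (2*45 + 73) / 324 = 0.503 for the nominal minor allele
            assert label == "C"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="zero genotyped"):
            allele_frequencies(_counts(0, 0, 0))


class TestHwe:
    def test_exact_proportions_give_zero(self):
        res = hwe_test(_counts(25, 50, 25))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_heterozygotes_hand_computed(self):
        # expected 25/50/25 under p=0.5: chi2 = 25 + 50 + 25 = 100
        res = hwe_test(_counts(50, 0, 50))
        assert res.chi_square == pytest.approx(100.0)
        assert res.df == 1

    def test_monomorphic_flagged(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            res = hwe_test(_counts(80, 0, 0))
        assert res.monomorphic and res.chi_square == 0.0 and res.p_value == 1.0

    def test_rejection_rate_near_alpha_under_hwe(self):
        """Simulated HWE cohorts are rejected at roughly the nominal 5%."""
        rng = np.random.default_rng(2024)
        n, reps, alpha = 2000, 200, 0.05
        rejections = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, size=n)
            c = _counts(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            rejections += hwe_test(c).p_value < alpha
        assert 0.015 <= rejections / reps <= 0.095

    def test_exact_test_agrees_with_chisq_in_large_balanced_sample(self):
        c = _counts(360, 480, 160)
        assert genetics.hwe_exact_test(c) == pytest.approx(hwe_test(c).p_value, abs=0.08)


def _genotypes_from_haplotypes(h, n, rng):
    """Draw unphased two-locus genotypes from haplotype frequencies."""
    hap = rng.choice(4, size=(n, 2), p=h)
    g1 = (hap < 2).sum(axis=1)
    g2 = (hap % 2 == 0).sum(axis=1)
    return pd.Series(g1), pd.Series(g2)


def _grid_oracle_loglik(g1, g2, step=0.001):
    """Exhaustive likelihood maximization over p_AB.

    Given the genotype table the marginal allele frequencies are fixed,
    so the haplotype distribution has a single free parameter p_AB; scan
    it on a fine grid and return the best log-likelihood.
    """
    table, n = genetics._genotype_table(g1, g2)
    p1 = (table.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    p2 = (table.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    best = -np.inf
    for pab in np.arange(lo, hi + step / 2, step):
        h = np.array([pab, p1 - pab, p2 - pab, 1 - p1 - p2 + pab])
        if (h < -1e-12).any():
            continue
        best = max(best, genetics._loglik(np.clip(h, 0, 1), table))
    return best


class TestEmHaplotypes:
    def test_phase_unambiguous_equals_gamete_counting(self):
        # no double heterozygotes: phase is certain, EM = direct counting
        g1 = pd.Series([2, 2, 0, 0, 1, 0])
        g2 = pd.Series([2, 1, 0, 0, 0, 1])
        h = em_haplotype_freqs(g1, g2)
        # gametes: AB x4+1, Ab x1, aB x1+... count by hand: subjects
        # (2,2)->2 AB; (2,1)->AB+Ab; (0,0)->2 ab twice; (1,0)->Ab+ab; (0,1)->aB+ab
        assert h.as_array() == pytest.approx(np.array([3, 2, 1, 6]) / 12, abs=1e-9)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.4, 0.1, 0.1, 0.4])
        g1, g2 = _genotypes_from_haplotypes(truth, 10000, rng)
        h = em_haplotype_freqs(g1, g2)
        assert h.as_array() == pytest.approx(truth, abs=0.01)
        assert abs(h.as_array().sum() - 1) < 1e-10

    def test_loglik_matches_grid_oracle_on_small_fixture(self):
        rng = np.random.default_rng(17)
        g1, g2 = _genotypes_from_haplotypes(np.array([0.35, 0.15, 0.2, 0.3]), 20, rng)
        h = em_haplotype_freqs(g1, g2)
        assert h.log_likelihood == pytest.approx(_grid_oracle_loglik(g1, g2), abs=1e-3)

    def test_loglik_monotone_and_order_invariant(self):
        rng = np.random.default_rng(3)
        g1, g2 = _genotypes_from_haplotypes(np.array([0.5, 0.2, 0.1, 0.2]), 400, rng)
        h = em_haplotype_freqs(g1, g2)
        perm = rng.permutation(len(g1))
        h2 = em_haplotype_freqs(g1.iloc[perm].reset_index(drop=True),
                                g2.iloc[perm].reset_index(drop=True))
        assert h.as_array() == pytest.approx(h2.as_array(), abs=1e-12)
        # log-likelihood at the EM solution beats the equilibrium start
        table, n = genetics._genotype_table(g1, g2)
        p1 = (table.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
        p2 = (table.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
        start = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
        assert h.log_likelihood >= genetics._loglik(start, table) - 1e-9

    def test_all_double_heterozygous_flagged(self):
        g = pd.Series([1] * 12)
        with pytest.warns(UserWarning, match="not identifiable"):
            h = em_haplotype_freqs(g, g)
        assert h.non_identifiable

    def test_missing_excluded_pairwise(self):
        g1 = pd.Series([2, 0, np.nan, 2], dtype="Float64")
        g2 = pd.Series([2, 0, 0, np.nan], dtype="Float64")
        assert em_haplotype_freqs(g1, g2).n_subjects == 2


class TestLdStats:
    @pytest.mark.parametrize(
        "freqs, d, dprime, r2",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0, 0.0, 0.0),
            ((0.5, 0.0, 0.0, 0.5), 0.25, 1.0, 1.0),
            ((0.35, 0.15, 0.15, 0.35), 0.10, 0.40, 0.16),
        ],
    )
    def test_hand_computed(self, freqs, d, dprime, r2):
        h = HaplotypeFreqs(*freqs, log_likelihood=0.0, n_iterations=0, n_subjects=100)
        ld = ld_stats(h)
        assert ld.D == pytest.approx(d, abs=1e-12)
        assert ld.d_prime == pytest.approx(dprime, abs=1e-12)
        assert ld.r_squared == pytest.approx(r2, abs=1e-12)

    def test_chi_square_is_2n_r2(self):
        h = HaplotypeFreqs(0.35, 0.15, 0.15, 0.35, 0.0, 0, 500)
        ld = ld_stats(h)
        assert ld.chi_square == pytest.approx(2 * 500 * ld.r_squared)

    def test_monomorphic_rejected(self):
        h = HaplotypeFreqs(0.5, 0.5, 0.0, 0.0, 0.0, 0, 100)
        with pytest.raises(ValueError, match="monomorphic"):
            ld_stats(h)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_dprime_bounds_and_r2_dominance(self, raw):
        h = np.array(raw) / np.sum(raw)
        hf = HaplotypeFreqs(*h, log_likelihood=0.0, n_iterations=0, n_subjects=100)
        p1, p2 = h[0] + h[1], h[0] + h[2]
        if min(p1, 1 - p1, p2, 1 - p2) < 1e-6:
            return
        ld = ld_stats(hf)
        assert 0.0 <= ld.d_prime <= 1.0
        assert ld.r_squared <= ld.d_prime**2 + 1e-9


class TestCodeDominant:
    def test_string_coding(self):
        g = pd.Series(["C/C", "A/C", "A/A", pd.NA])
        coded = code_dominant(g, "C/C", "rs2740210")
        assert coded.tolist()[:3] == [0, 1, 1]
        assert pd.isna(coded.iloc[3])

    def test_count_coding(self):
        coded = code_dominant(pd.Series([0, 1, 2, pd.NA], dtype="Int64"), 0)
        assert coded.tolist()[:3] == [0, 1, 1]
        assert pd.isna(coded.iloc[3])

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="A/T"):
            code_dominant(pd.Series(["C/C", "A/T"]), "C/C", "rs2740210")


def test_count_genotypes_from_strings_and_call_rate():
    g = pd.Series(["C/C", "A/C", "A/A", pd.NA, "C/C"])
    c = count_genotypes(g, "rs2740210")
    assert (c.n_hom_major, c.n_het, c.n_hom_minor) == (2, 1, 1)
    assert c.call_rate == pytest.approx(0.8)
    assert (c.major_allele, c.minor_allele) == ("C", "A")


def test_simulated_genotypes_match_configured_maf_and_ld():
    cfg = SimulationConfig(n_subjects=20000, seed=99, missing_rates={})
    geno = simulate_genotypes(cfg)
    for locus, target in [("rs2740210", 0.31), ("rs4813627", 0.50)]:
        maf, _ = allele_frequencies(count_genotypes(geno[locus], locus))
        assert maf == pytest.approx(target, abs=0.01)
    g1 = genotype_to_counts(geno["rs2740210"], "rs2740210")
    g2 = genotype_to_counts(geno["rs4813627"], "rs4813627")
    ld = ld_stats(em_haplotype_freqs(g1, g2))
    assert ld.d_prime == pytest.approx(0.79, abs=0.03)
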