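import numpy as np
import pytest

from _oracles import coverage_by_enumeration, coverage_by_inclusion_exclusion
from conftest import one_field, random_haplotype_table, random_library
from hemibank.alleles import Locus, OtherAllele, parse_allele_name
from hemibank.bank import HemiCombo, build_library
from hemibank.coverage import (
    analytic_coverage,
    combo_matches,
    cumulative_coverage,
    monte_carlo_coverage,
)
from hemibank.frequencies import Genotype, haplotypes_under_le, normalize_frequency_table


def _combo(a, b):
    return HemiCombo(parse_allele_name(a), parse_allele_name(b))


class TestComboMatches:
    def test_cross_haplotype_match(self):
        g = Genotype(
            (parse_allele_name("A*02"), parse_allele_name("B*44")),
            (parse_allele_name("A*03"), parse_allele_name("B*35")),
        )
        assert combo_matches(_combo("A*02", "B*35"), g)

    def test_homozygous_match(self):
        hap = (parse_allele_name("A*02"), parse_allele_name("B*35"))
        assert combo_matches(_combo("A*02", "B*35"), Genotype(hap, hap))

    def test_other_never_matches(self):
        g = Genotype(
            (OtherAllele(Locus.A), parse_allele_name("B*35")),
            (OtherAllele(Locus.A), parse_allele_name("B*35")),
        )
        assert not combo_matches(_combo("A*02", "B*35"), g)

    def test_requires_both_antigens(self):
        g = Genotype(
            (parse_allele_name("A*02"), parse_allele_name("B*44")),
            (parse_allele_name("A*03"), parse_allele_name("B*07")),
        )
        assert not combo_matches(_combo("A*02", "B*35"), g)


def _le_table(fa_val, fb_val):
    fa = normalize_frequency_table(
        {parse_allele_name("A*01"): fa_val}, "pop", Locus.A
    )
    fb = normalize_frequency_table(
        {parse_allele_name("B*01"): fb_val}, "pop", Locus.B
    )
    return haplotypes_under_le(fa, fb)


class TestAnalyticCoverage:
    def test_empty_library_is_zero(self):
        h = _le_table(0.5, 0.5)
        assert analytic_coverage([], h).coverage == 0.0

    def test_single_combo_closed_form(self):
        h = _le_table(0.5, 0.5)
        res = analytic_coverage([_combo("A*01", "B*01")], h)
        assert res.coverage == pytest.approx(0.5625, abs=1e-12)

    def test_other_mass_caps_coverage_below_one(self):
        # every named genotype matched, but 0.1 OTHER mass per locus remains
        fa = normalize_frequency_table(
            {parse_allele_name("A*01"): 0.9}, "pop", Locus.A
        )
        fb = normalize_frequency_table(
            {parse_allele_name("B*01"): 0.9}, "pop", Locus.B
        )
        h = haplotypes_under_le(fa, fb)
        combos = [_combo("A*01", "B*01")]
        cov = analytic_coverage(combos, h).coverage
        assert cov == pytest.approx(coverage_by_enumeration(combos, h), abs=1e-12)
        assert cov < 1.0

    def test_monotone_in_library(self, rng):
        h = random_haplotype_table(rng, 4, 4)
        lib = random_library(rng, 4, 4, 5)
        prev = 0.0
        for k in range(len(lib) + 1):
            cov = analytic_coverage(lib[:k], h).coverage
            assert cov >= prev - 1e-12
            prev = cov

    def test_coarser_resolution_never_decreases_coverage(self, rng):
        # two-field haplotypes; one-field matching merges subtypes
        a_alleles = [parse_allele_name(f"A*{i:02d}:0{j}") for i in (1, 2) for j in (1, 2)]
        b_alleles = [parse_allele_name(f"B*{i:02d}:0{j}") for i in (7, 8) for j in (1, 2)]
        grid = rng.dirichlet(np.ones(16))
        entries = {
            (a, b): float(p)
            for (a, b), p in zip(
                [(a, b) for a in a_alleles for b in b_alleles], grid
            )
        }
        from hemibank.frequencies import HaplotypeTable

        h = HaplotypeTable("pop", entries, provenance="synthetic")
        lib = [
            HemiCombo(a_alleles[0], b_alleles[0]),
            HemiCombo(a_alleles[3], b_alleles[2]),
        ]
        c2 = analytic_coverage(lib, h, resolution=2).coverage
        c1 = analytic_coverage(lib, h, resolution=1).coverage
        assert c1 >= c2 - 1e-12

    def test_submodular_marginal_gains(self, rng):
        """Marginal gains along a greedy ordering never increase."""
        for trial in range(5):
            h = random_haplotype_table(rng, 4, 4)
            lib = random_library(rng, 4, 4, 6)
            remaining = list(lib)
            cov = 0.0
            chosen = []
            gains = []
            while remaining:
                best = max(
                    remaining,
                    key=lambda c: analytic_coverage(chosen + [c], h).coverage,
                )
                new_cov = analytic_coverage(chosen + [best], h).coverage
                gains.append(new_cov - cov)
                cov = new_cov
                chosen.append(best)
                remaining.remove(best)
            assert all(g1 >= g2 - 1e-12 for g1, g2 in zip(gains, gains[1:]))

    def test_haplotype_model_never_exceeds_genotype_model(self, rng):
        h = random_haplotype_table(rng, 4, 4)
        lib = random_library(rng, 4, 4, 4)
        g_cov = analytic_coverage(lib, h, model="genotype").coverage
        h_cov = analytic_coverage(lib, h, model="haplotype").coverage
        assert h_cov <= g_cov + 1e-12


class TestCumulativeCoverage:
    def test_single_combo_consistency(self):
        h = _le_table(0.5, 0.5)
        combos = [_combo("A*01", "B*01")]
        curve = cumulative_coverage(combos, h)
        assert curve.final == pytest.approx(analytic_coverage(combos, h).coverage)

    def test_permutation_invariant_endpoint(self, rng):
        h = random_haplotype_table(rng, 4, 4)
        lib = random_library(rng, 4, 4, 5)
        final1 = cumulative_coverage(lib, h).final
        final2 = cumulative_coverage(lib[::-1], h).final
        assert final1 == pytest.approx(final2, abs=1e-12)

    def test_nondecreasing_and_matches_enumeration(self, rng):
        h = random_haplotype_table(rng, 3, 3)
        lib = random_library(rng, 3, 3, 4)
        curve = cumulative_coverage(lib, h)
        for k, c in enumerate(curve.cumulative, start=1):
            assert c == pytest.approx(
                coverage_by_enumeration(lib[:k], h), abs=1e-12
            )

    def test_duplicate_keys_rejected(self):
        h = _le_table(0.5, 0.5)
        c = _combo("A*01", "B*01")
        with pytest.raises(ValueError, match="duplicate"):
            cumulative_coverage([c, c], h)


class TestMonteCarlo:
    def test_empty_library_zero(self, rng):
        h = random_haplotype_table(rng, 3, 3)
        assert monte_carlo_coverage([], h, n=100, seed=1).coverage == 0.0

    def test_degenerate_full_match(self):
        fa = normalize_frequency_table({parse_allele_name("A*01"): 1.0}, "p", Locus.A)
        fb = normalize_frequency_table({parse_allele_name("B*01"): 1.0}, "p", Locus.B)
        h = haplotypes_under_le(fa, fb)
        res = monte_carlo_coverage([_combo("A*01", "B*01")], h, n=1000, seed=3)
        assert res.coverage == 1.0
        assert res.se == 0.0

    def test_agrees_with_analytic(self, rng):
        h = random_haplotype_table(rng, 5, 5)
        lib = random_library(rng, 5, 5, 6)
        exact = analytic_coverage(lib, h).coverage
        mc = monte_carlo_coverage(lib, h, n=200_000, seed=5)
        tol = 4 * max(mc.se, np.sqrt(exact * (1 - exact) / 200_000))
        assert abs(mc.coverage - exact) < tol + 1e-12


def test_analytic_equals_inclusion_exclusion_small(rng):
    for trial in range(5):
        n_a, n_b = rng.integers(2, 5, size=2)
        h = random_haplotype_table(rng, int(n_a), int(n_b))
        lib = random_library(rng, int(n_a), int(n_b), 3)
        assert analytic_coverage(lib, h).coverage == pytest.approx(
            coverage_by_inclusion_exclusion(lib, h), abs=1e-12
        )
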