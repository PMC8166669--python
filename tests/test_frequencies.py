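import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemibank.alleles import Locus, OtherAllele, parse_allele_name
from hemibank.frequencies import (
    FrequencyTable,
    HaplotypeTable,
    haplotypes_under_le,
    normalize_frequency_table,
    read_frequency_table,
    read_haplotype_table,
    sample_genotypes,
    write_frequency_table,
    write_haplotype_table,
)


def _freqs(locus, mapping):
    return {parse_allele_name(k): v for k, v in mapping.items()}


class TestNormalize:
    def test_complement_goes_to_other(self):
        t = normalize_frequency_table(
            _freqs(Locus.A, {"A*01": 0.3, "A*02": 0.5}), "pop", Locus.A
        )
        assert t.residual_other == pytest.approx(0.2)

    def test_mass_above_one_rejected(self):
        with pytest.raises(ValueError, match="refusing to rescale"):
            normalize_frequency_table(
                _freqs(Locus.A, {"A*01": 0.6, "A*02": 0.6}), "pop", Locus.A
            )

    def test_duplicates_summed_under_truncation(self):
        t = normalize_frequency_table(
            _freqs(Locus.A, {"A*02:01": 0.3, "A*02:06": 0.2}),
            "pop",
            Locus.A,
            resolution=1,
        )
        assert t.entries == {parse_allele_name("A*02"): pytest.approx(0.5)}
        assert t.residual_other == pytest.approx(0.5)

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            normalize_frequency_table({}, "pop", Locus.A)
        with pytest.raises(ValueError):
            normalize_frequency_table(
                _freqs(Locus.A, {"A*01": -0.1}), "pop", Locus.A
            )
        with pytest.raises(ValueError):
            normalize_frequency_table(
                _freqs(Locus.A, {"A*01": float("nan")}), "pop", Locus.A
            )

    @given(
        st.lists(st.floats(0.001, 0.3), min_size=1, max_size=8),
    )
    def test_normalized_mass_is_one(self, raws):
        raw = {
            parse_allele_name(f"A*{i + 1:02d}"): v for i, v in enumerate(raws)
        }
        if sum(raw.values()) > 1:
            return
        t = normalize_frequency_table(raw, "pop", Locus.A)
        assert sum(t.entries.values()) + t.residual_other == pytest.approx(1.0, abs=1e-9)


class TestLinkageEquilibriumProduct:
    def test_degenerate_single_haplotype(self):
        fa = normalize_frequency_table(_freqs(Locus.A, {"A*01": 1.0}), "pop", Locus.A)
        fb = normalize_frequency_table(_freqs(Locus.B, {"B*01": 1.0}), "pop", Locus.B)
        h = haplotypes_under_le(fa, fb)
        assert h.provenance == "product_LE"
        assert list(h.entries.values()) == [pytest.approx(1.0)]

    def test_uniform_product(self):
        fa = normalize_frequency_table(
            _freqs(Locus.A, {"A*01": 0.5, "A*02": 0.5}), "pop", Locus.A
        )
        fb = normalize_frequency_table(
            _freqs(Locus.B, {"B*01": 0.5, "B*02": 0.5}), "pop", Locus.B
        )
        h = haplotypes_under_le(fa, fb)
        assert len(h.entries) == 4
        assert all(p == pytest.approx(0.25) for p in h.entries.values())

    def test_residual_mass_becomes_other_haplotypes(self):
        fa = normalize_frequency_table(_freqs(Locus.A, {"A*01": 0.7}), "pop", Locus.A)
        fb = normalize_frequency_table(_freqs(Locus.B, {"B*01": 1.0}), "pop", Locus.B)
        h = haplotypes_under_le(fa, fb)
        a01, b01 = parse_allele_name("A*01"), parse_allele_name("B*01")
        assert h.entries[(a01, b01)] == pytest.approx(0.7)
        assert h.entries[(OtherAllele(Locus.A), b01)] == pytest.approx(0.3)

    def test_locus_mismatch_rejected(self):
        fa = normalize_frequency_table(_freqs(Locus.A, {"A*01": 1.0}), "pop", Locus.A)
        with pytest.raises(ValueError):
            haplotypes_under_le(fa, fa)

    def test_population_mismatch_warns(self):
        fa = normalize_frequency_table(_freqs(Locus.A, {"A*01": 1.0}), "p1", Locus.A)
        fb = normalize_frequency_table(_freqs(Locus.B, {"B*01": 1.0}), "p2", Locus.B)
        with pytest.warns(UserWarning, match="population labels differ"):
            haplotypes_under_le(fa, fb)
        with pytest.raises(ValueError):
            haplotypes_under_le(fa, fb, strict_population=True)

    def test_marginals_recover_inputs(self, rng):
        raw_a = rng.dirichlet(np.ones(5) * 0.7) * 0.9
        raw_b = rng.dirichlet(np.ones(4) * 0.7) * 0.95
        fa = normalize_frequency_table(
            {parse_allele_name(f"A*{i+1:02d}"): float(v) for i, v in enumerate(raw_a)},
            "pop", Locus.A,
        )
        fb = normalize_frequency_table(
            {parse_allele_name(f"B*{i+1:02d}"): float(v) for i, v in enumerate(raw_b)},
            "pop", Locus.B,
        )
        h = haplotypes_under_le(fa, fb)
        ma = h.marginal(Locus.A)
        for a, f in fa.as_dict().items():
            assert ma[a] == pytest.approx(f, abs=1e-12)
        mb = h.marginal(Locus.B)
        for b, f in fb.as_dict().items():
            assert mb[b] == pytest.approx(f, abs=1e-12)


class TestSampling:
    def _uniform_2x2(self):
        fa = normalize_frequency_table(
            _freqs(Locus.A, {"A*01": 0.5, "A*02": 0.5}), "pop", Locus.A
        )
        fb = normalize_frequency_table(
            _freqs(Locus.B, {"B*01": 0.5, "B*02": 0.5}), "pop", Locus.B
        )
        return haplotypes_under_le(fa, fb)

    def test_degenerate_table_yields_identical_homozygotes(self):
        fa = normalize_frequency_table(_freqs(Locus.A, {"A*01": 1.0}), "pop", Locus.A)
        fb = normalize_frequency_table(_freqs(Locus.B, {"B*01": 1.0}), "pop", Locus.B)
        h = haplotypes_under_le(fa, fb)
        gs = sample_genotypes(h, 5, seed=1)
        assert len(gs) == 5
        assert all(g.hap1 == g.hap2 for g in gs)

    def test_same_seed_reproduces(self):
        h = self._uniform_2x2()
        assert sample_genotypes(h, 50, seed=7) == sample_genotypes(h, 50, seed=7)

    def test_empirical_frequencies_match_table(self):
        h = self._uniform_2x2()
        n = 100_000
        gs = sample_genotypes(h, n, seed=11)
        counts = {hap: 0 for hap in h.haplotypes}
        for g in gs:
            counts[g.hap1] += 1
            counts[g.hap2] += 1
        se = np.sqrt(0.25 * 0.75 / (2 * n))
        for hap in h.haplotypes:
            assert abs(counts[hap] / (2 * n) - 0.25) < 4 * se

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_genotypes(self._uniform_2x2(), 0, seed=1)


def test_frequency_table_tsv_roundtrip(tmp_path):
    t = normalize_frequency_table(
        _freqs(Locus.A, {"A*01": 0.3, "A*02:01": 0.45}), "KORlike", Locus.A
    )
    path = tmp_path / "freq.tsv"
    write_frequency_table(t, path)
    back = read_frequency_table(path)
    assert back.population == "KORlike"
    assert back.entries == pytest.approx(t.entries)
    assert back.residual_other == pytest.approx(t.residual_other)


def test_haplotype_table_tsv_roundtrip(tmp_path, rng):
    from conftest import random_haplotype_table

    h = random_haplotype_table(rng, 3, 4)
    path = tmp_path / "hap.tsv"
    write_haplotype_table(h, path)
    back = read_haplotype_table(path)
    assert back.population == h.population
    assert set(back.entries) == set(h.entries)
    for k in h.entries:
        assert back.entries[k] == pytest.approx(h.entries[k], abs=1e-12)
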