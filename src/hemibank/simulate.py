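"""Synthetic inputs with controlled statistical structure.

Real haplobank design consumes external resources — published per-population
allele/haplotype frequency tables and HLA-typed registries of established
stem-cell lines. This module generates statistically analogous stand-ins so
that every pipeline stage can be exercised and validated end to end with
known ground truth:

* allele frequency spectra are drawn from a symmetric Dirichlet; a
  concentration below 1 reproduces the skew of real HLA spectra, where a
  handful of alleles dominate a population;
* A-B haplotype tables either multiply two independent per-locus spectra
  (linkage equilibrium) or draw a joint Dirichlet over the allele grid,
  which induces nonzero linkage disequilibrium as real A-B haplotypes show;
* line panels are Hardy-Weinberg draws from a haplotype table, mimicking a
  registry of heterozygous typed lines (~200 lines in published registries);
* allele sequence pairs carry planted substitutions/gaps at recorded
  positions, so guide-design tests assert against known truth instead of
  re-inferring it.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alleles import AlleleName, CellLine, Locus, LocusGenotype, OtherAllele, parse_allele_name
from .frequencies import FrequencyTable, HaplotypeTable
from .guides import SITE_LEN, SPACER_LEN, SEED_LEN, AlleleSequencePair

__all__ = [
    "SynthSpec",
    "synth_frequency_table",
    "synth_haplotype_table",
    "synth_line_panel",
    "synth_allele_pair",
    "SynthPair",
    "synth_discriminating_fixture",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic population + registry.

    Defaults emulate a single real population: ~20 HLA-A and ~30 HLA-B
    one-field allele groups, a skewed frequency spectrum (concentration 0.5),
    and a registry of 202 typed heterozygous lines.
    """

    n_alleles_a: int = 20
    n_alleles_b: int = 30
    concentration: float = 0.5
    ld_mode: str = "independent"  # independent | dirichlet_joint
    n_lines: int = 202
    residual_other: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles_a < 2 or self.n_alleles_b < 2:
            raise ValueError("need at least two alleles per locus")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.ld_mode not in ("independent", "dirichlet_joint"):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if not (0.0 <= self.residual_other < 1.0):
            raise ValueError("residual_other must be in [0, 1)")


def _allele_names(locus: Locus, n: int) -> list[AlleleName]:
    width = max(2, len(str(n)))
    return [AlleleName(locus=locus, fields=(f"{i:0{width}d}",)) for i in range(1, n + 1)]


def synth_frequency_table(
    n_alleles: int,
    concentration: float,
    seed: int,
    locus: Locus,
    population: str = "synthetic",
    residual_other: float = 0.0,
) -> FrequencyTable:
    """Dirichlet-distributed allele frequencies over sequential one-field names."""
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not (0.0 <= residual_other < 1.0):
        raise ValueError("residual_other must be in [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(n_alleles, concentration)) * (1.0 - residual_other)
    names = _allele_names(locus, n_alleles)
    return FrequencyTable(
        population=population,
        locus=locus,
        entries=dict(zip(names, freqs)),
        residual_other=residual_other,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent sub-streams, each below 2**31
    return [int(s >> np.uint32(1)) for s in np.random.SeedSequence(seed).generate_state(n)]


def synth_haplotype_table(spec: SynthSpec, population: str = "synthetic") -> HaplotypeTable:
    """A-B haplotype distribution per the spec's linkage mode.

    ``independent``: product of two per-locus Dirichlet spectra (provenance
    ``product_LE``, zero LD by construction). ``dirichlet_joint``: a joint
    Dirichlet over the |A| x |B| grid (provenance ``synthetic``), whose
    cell-level fluctuations induce nonzero LD.
    """
    seed_a, seed_b = _child_seeds(spec.seed, 2)
    if spec.ld_mode == "independent":
        from .frequencies import haplotypes_under_le

        fa = synth_frequency_table(
            spec.n_alleles_a, spec.concentration, seed_a, Locus.A,
            population=population, residual_other=spec.residual_other,
        )
        fb = synth_frequency_table(
            spec.n_alleles_b, spec.concentration, seed_b, Locus.B,
            population=population, residual_other=spec.residual_other,
        )
        return haplotypes_under_le(fa, fb)

    rng = np.random.default_rng(seed_a)
    grid = rng.dirichlet(
        np.full(spec.n_alleles_a * spec.n_alleles_b, spec.concentration)
    ).reshape(spec.n_alleles_a, spec.n_alleles_b) * (1.0 - spec.residual_other)
    names_a = _allele_names(Locus.A, spec.n_alleles_a)
    names_b = _allele_names(Locus.B, spec.n_alleles_b)
    entries: dict = {
        (a, b): float(grid[i, j])
        for i, a in enumerate(names_a)
        for j, b in enumerate(names_b)
    }
    if spec.residual_other > 0:
        # park unlisted mass on a fully-OTHER haplotype; it can never be matched
        entries[(OtherAllele(Locus.A), OtherAllele(Locus.B))] = spec.residual_other
    return HaplotypeTable(population=population, entries=entries, provenance="synthetic")


_DRB1_PLACEHOLDER = ("DRB1*01", "DRB1*04")


def synth_line_panel(h: HaplotypeTable, n_lines: int, seed: int) -> list[CellLine]:
    """HWE draws of typed heterozygous lines from a haplotype table.

    Each line's A/B genotype is two haplotype draws; draws are conditioned on
    fully named haplotypes (registry lines are completely typed, so OTHER
    never appears in a panel). DRB1 is filled with placeholder heterozygous
    alleles — every bank line is DRB1-null, so its identity is irrelevant.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    named = [
        (hap, p)
        for hap, p in h.entries.items()
        if not isinstance(hap[0], OtherAllele) and not isinstance(hap[1], OtherAllele)
    ]
    if not named:
        raise ValueError("haplotype table has no fully named haplotypes")
    haps = [hap for hap, _ in named]
    p = np.array([q for _, q in named], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(haps), size=(n_lines, 2), p=p)
    drb1 = LocusGenotype(
        Locus.DRB1,
        (parse_allele_name(_DRB1_PLACEHOLDER[0]), parse_allele_name(_DRB1_PLACEHOLDER[1])),
    )
    width = max(3, len(str(n_lines)))
    panel = []
    for k, (i, j) in enumerate(idx, start=1):
        h1, h2 = haps[i], haps[j]
        panel.append(
            CellLine(
                line_id=f"SL{k:0{width}d}",
                a=LocusGenotype(Locus.A, (h1[0], h2[0])),
                b=LocusGenotype(Locus.B, (h1[1], h2[1])),
                drb1=drb1,
            )
        )
    return panel


@dataclass(frozen=True)
class SynthPair:
    """A generated allele sequence pair plus its planted ground truth."""

    pair: AlleleSequencePair
    substitution_positions: tuple[int, ...]  # target coordinates
    gap_intervals: tuple[tuple[int, int], ...]  # half-open deletions in the spare


def synth_allele_pair(
    length: int,
    n_substitutions: int,
    n_gap_events: int,
    seed: int,
    max_gap_len: int = 3,
) -> SynthPair:
    """Random target sequence and a spare derived by planted edits.

    Gap events are deletions in the spare (1..max_gap_len nt, non-overlapping
    and not flanking each other); substitutions are planted outside gaps.
    The true alignment is returned with the pair, so downstream tests assert
    against the planted positions rather than re-inferring them.
    """
    if length < 30:
        raise ValueError("length must be >= 30")
    if n_substitutions < 0 or n_gap_events < 0:
        raise ValueError("edit counts must be nonnegative")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    target = "".join(rng.choice(bases, size=length))

    gaps: list[tuple[int, int]] = []
    attempts = 0
    while len(gaps) < n_gap_events:
        attempts += 1
        if attempts > 1000:
            raise ValueError("cannot place the requested gap events without overlap")
        glen = int(rng.integers(1, max_gap_len + 1))
        start = int(rng.integers(0, length - glen + 1))
        if all(start + glen < s - 1 or start > e for s, e in gaps):
            gaps.append((start, start + glen))
    gaps.sort()
    in_gap = np.zeros(length, dtype=bool)
    for s, e in gaps:
        in_gap[s:e] = True

    free = np.flatnonzero(~in_gap)
    if n_substitutions > len(free):
        raise ValueError("not enough non-gap positions for the substitutions")
    sub_pos = sorted(int(p) for p in rng.choice(free, size=n_substitutions, replace=False))

    spare_aln = list(target)
    for p in sub_pos:
        alts = [b for b in "ACGT" if b != target[p]]
        spare_aln[p] = alts[int(rng.integers(0, 3))]
    for s, e in gaps:
        for p in range(s, e):
            spare_aln[p] = "-"
    aligned_spare = "".join(spare_aln)
    pair = AlleleSequencePair(
        target_id="target",
        spare_id="spare",
        target_seq=target,
        spare_seq=aligned_spare.replace("-", ""),
        aligned_target=target,
        aligned_spare=aligned_spare,
    )
    return SynthPair(
        pair=pair,
        substitution_positions=tuple(sub_pos),
        gap_intervals=tuple(gaps),
    )


def synth_discriminating_fixture(seed: int, length: int = 120) -> tuple[AlleleSequencePair, int, int]:
    """A pair with one guaranteed + strand NGG site and one seed substitution.

    Forces a GG PAM at a random interior site and plants a single spare
    substitution at a random PAM-proximal seed offset of that site. Returns
    ``(pair, site_start, planted_offset)`` where ``planted_offset`` is the
    protospacer-orientation offset (10..19) of the substitution.
    """
    if length < SITE_LEN + 2:
        raise ValueError("length too short for a site")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list("".join(rng.choice(bases, size=length)))
    start = int(rng.integers(0, length - SITE_LEN + 1))
    seq[start + SPACER_LEN + 1] = "G"
    seq[start + SPACER_LEN + 2] = "G"
    target = "".join(seq)
    offset = int(rng.integers(SPACER_LEN - SEED_LEN, SPACER_LEN))
    pos = start + offset
    alts = [b for b in "ACGT" if b != target[pos]]
    spare = list(target)
    spare[pos] = alts[int(rng.integers(0, 3))]
    pair = AlleleSequencePair(
        target_id="target",
        spare_id="spare",
        target_seq=target,
        spare_seq="".join(spare),
        aligned_target=target,
        aligned_spare="".join(spare),
    )
    return pair, start, offset
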