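"""Population frequency models: per-locus allele frequencies, A-B haplotype
distributions and Hardy-Weinberg genotype sampling.

The central object is the :class:`HaplotypeTable`, a probability distribution
p(h) over HLA-A x HLA-B haplotypes. Two ingestion modes are supported and
recorded in ``provenance``:

* ``product_LE`` — built from two per-locus allele frequency tables under
  linkage equilibrium, p(a,b) = f_a * f_b;
* ``supplied`` / ``synthetic`` — haplotype frequencies given directly (real
  A-B linkage disequilibrium is strong, so directly supplied tables are
  preferred when available).

Frequency mass not attributed to a named allele is carried by a reserved
``OTHER`` pseudo-allele per locus. OTHER can never be matched by a bank line,
which makes every coverage number computed downstream an underestimate rather
than an overestimate of the truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import (
    AlleleLike,
    AlleleName,
    Locus,
    OtherAllele,
    format_allele_name,
    match_key,
    parse_allele_name,
)

__all__ = [
    "FrequencyTable",
    "HaplotypeTable",
    "Genotype",
    "normalize_frequency_table",
    "haplotypes_under_le",
    "sample_genotypes",
    "read_frequency_table",
    "write_frequency_table",
    "read_haplotype_table",
    "write_haplotype_table",
]

_TOL = 1e-9
_EXCESS_TOL = 1e-6


@dataclass(frozen=True)
class FrequencyTable:
    """Normalized allele frequencies at one locus for one population.

    ``entries`` maps named alleles to frequencies; ``residual_other`` is the
    mass of alleles absent from the source table, assigned to the OTHER
    pseudo-allele. Entries plus residual sum to 1 within 1e-9.
    """

    population: str
    locus: Locus
    entries: Mapping[AlleleName, float]
    residual_other: float = 0.0

    def __post_init__(self) -> None:
        for a, f in self.entries.items():
            if a.locus != self.locus:
                raise ValueError(f"allele {a} not at locus {self.locus.value}")
            if not math.isfinite(f) or f < 0:
                raise ValueError(f"invalid frequency {f!r} for {a}")
        if self.residual_other < -_TOL:
            raise ValueError(f"negative residual_other {self.residual_other}")
        total = sum(self.entries.values()) + self.residual_other
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"frequencies sum to {total}, not 1")

    def as_dict(self) -> dict[AlleleLike, float]:
        """Entries plus the OTHER pseudo-allele (when it carries mass)."""
        d: dict[AlleleLike, float] = dict(self.entries)
        if self.residual_other > 0:
            d[OtherAllele(self.locus)] = self.residual_other
        return d


def normalize_frequency_table(
    raw: Mapping[AlleleName, float],
    population: str,
    locus: Locus,
    resolution: int | None = None,
) -> FrequencyTable:
    """Validate raw allele frequencies and close them with an OTHER residual.

    Names that coincide after truncation to ``resolution`` are summed (pass
    ``resolution=None`` to keep full-resolution names, summing only exact
    duplicates). A raw sum above 1 (beyond 1e-6) is an error — it indicates a
    data-entry bug and is never silently rescaled.
    """
    if not raw:
        raise ValueError("empty frequency table")
    merged: dict[AlleleName, float] = {}
    for a, f in raw.items():
        if not math.isfinite(f) or f < 0:
            raise ValueError(f"invalid frequency {f!r} for allele {a}")
        if a.locus != locus:
            raise ValueError(f"allele {a} not at locus {locus.value}")
        key = a if resolution is None else match_key(a, resolution)
        merged[key] = merged.get(key, 0.0) + float(f)
    s = sum(merged.values())
    if s > 1.0 + _EXCESS_TOL:
        raise ValueError(f"allele frequencies sum to {s:.6g} > 1; refusing to rescale")
    return FrequencyTable(
        population=population,
        locus=locus,
        entries=merged,
        residual_other=max(0.0, 1.0 - s),
    )


@dataclass(frozen=True)
class HaplotypeTable:
    """Probability distribution over A-B haplotypes for one population."""

    population: str
    entries: Mapping[tuple[AlleleLike, AlleleLike], float]
    provenance: str = "supplied"  # product_LE | supplied | synthetic

    def __post_init__(self) -> None:
        if self.provenance not in {"product_LE", "supplied", "synthetic"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        total = 0.0
        for (a, b), p in self.entries.items():
            if a.locus != Locus.A or b.locus != Locus.B:
                raise ValueError(f"haplotype ({a},{b}) must pair an A allele with a B allele")
            if not math.isfinite(p) or p < 0:
                raise ValueError(f"invalid haplotype probability {p!r} for ({a},{b})")
            total += p
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"haplotype probabilities sum to {total}, not 1")

    @property
    def haplotypes(self) -> list[tuple[AlleleLike, AlleleLike]]:
        return list(self.entries.keys())

    def probabilities(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)

    def marginal(self, locus: Locus) -> dict[AlleleLike, float]:
        """Marginal allele distribution at locus A or B."""
        if locus not in (Locus.A, Locus.B):
            raise ValueError("haplotypes carry only A and B")
        idx = 0 if locus is Locus.A else 1
        out: dict[AlleleLike, float] = {}
        for h, p in self.entries.items():
            out[h[idx]] = out.get(h[idx], 0.0) + p
        return out


def haplotypes_under_le(
    freq_a: FrequencyTable,
    freq_b: FrequencyTable,
    strict_population: bool = False,
) -> HaplotypeTable:
    """Haplotype distribution under linkage equilibrium: p(a,b) = f_a * f_b.

    Both inputs must be normalized tables at loci A and B. A population-label
    mismatch warns by default (``strict_population=True`` turns it into an
    error). OTHER mass on either side propagates into OTHER-bearing
    haplotypes.
    """
    if freq_a.locus is not Locus.A or freq_b.locus is not Locus.B:
        raise ValueError(
            f"expected loci A and B, got {freq_a.locus.value} and {freq_b.locus.value}"
        )
    if freq_a.population != freq_b.population:
        msg = (
            f"population labels differ: {freq_a.population!r} vs {freq_b.population!r}"
        )
        if strict_population:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    entries = {
        (a, b): fa * fb
        for a, fa in freq_a.as_dict().items()
        for b, fb in freq_b.as_dict().items()
    }
    return HaplotypeTable(
        population=freq_a.population, entries=entries, provenance="product_LE"
    )


@dataclass(frozen=True)
class Genotype:
    """An individual under HWE: two haplotypes (unordered)."""

    hap1: tuple[AlleleLike, AlleleLike]
    hap2: tuple[AlleleLike, AlleleLike]

    @property
    def a_alleles(self) -> tuple[AlleleLike, AlleleLike]:
        return (self.hap1[0], self.hap2[0])

    @property
    def b_alleles(self) -> tuple[AlleleLike, AlleleLike]:
        return (self.hap1[1], self.hap2[1])


def sample_genotypes(h: HaplotypeTable, n: int, seed: int) -> list[Genotype]:
    """Draw ``n`` HWE genotypes (two independent haplotypes each) from p(h).

    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    haps = h.haplotypes
    p = h.probabilities()
    p = p / p.sum()  # absorb float drift below the table tolerance
    idx = rng.choice(len(haps), size=(n, 2), p=p)
    return [Genotype(haps[i], haps[j]) for i, j in idx]


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def _parse_allele_or_other(text: str, locus: Locus) -> AlleleLike:
    if text.strip().upper() == "OTHER":
        return OtherAllele(locus)
    a = parse_allele_name(text)
    if a.locus != locus:
        raise ValueError(f"allele {text!r} not at locus {locus.value}")
    return a


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read one-locus allele frequencies from TSV columns
    ``population, locus, allele, frequency`` (OTHER spelled literally)."""
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "population": str})
    pops = df["population"].unique()
    loci = df["locus"].unique()
    if len(pops) != 1 or len(loci) != 1:
        raise ValueError(f"{path} must hold one population/locus, got {pops}/{loci}")
    locus = Locus(str(loci[0]).upper())
    raw: dict[AlleleName, float] = {}
    residual = 0.0
    for _, row in df.iterrows():
        a = _parse_allele_or_other(row["allele"], locus)
        if isinstance(a, OtherAllele):
            residual += float(row["frequency"])
        else:
            raw[a] = raw.get(a, 0.0) + float(row["frequency"])
    table = normalize_frequency_table(raw, population=str(pops[0]), locus=locus)
    if residual and abs(residual - table.residual_other) > 1e-6:
        raise ValueError(
            f"explicit OTHER mass {residual} inconsistent with complement "
            f"{table.residual_other}"
        )
    return table


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    rows = [
        {
            "population": table.population,
            "locus": table.locus.value,
            "allele": format_allele_name(a),
            "frequency": f,
        }
        for a, f in table.entries.items()
    ]
    if table.residual_other > 0:
        rows.append(
            {
                "population": table.population,
                "locus": table.locus.value,
                "allele": "OTHER",
                "frequency": table.residual_other,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_haplotype_table(path: str | Path, provenance: str = "supplied") -> HaplotypeTable:
    """Read A-B haplotype frequencies from TSV columns
    ``population, allele_A, allele_B, frequency``."""
    df = pd.read_csv(path, sep="\t", dtype={"allele_A": str, "allele_B": str})
    pops = df["population"].unique()
    if len(pops) != 1:
        raise ValueError(f"{path} must hold a single population, got {pops}")
    entries: dict[tuple[AlleleLike, AlleleLike], float] = {}
    for _, row in df.iterrows():
        a = _parse_allele_or_other(row["allele_A"], Locus.A)
        b = _parse_allele_or_other(row["allele_B"], Locus.B)
        entries[(a, b)] = entries.get((a, b), 0.0) + float(row["frequency"])
    return HaplotypeTable(population=str(pops[0]), entries=entries, provenance=provenance)


def write_haplotype_table(h: HaplotypeTable, path: str | Path) -> None:
    rows = [
        {
            "population": h.population,
            "allele_A": format_allele_name(a),
            "allele_B": format_allele_name(b),
            "frequency": p,
        }
        for (a, b), p in h.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
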