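"""Enumeration of hemizygous A x B edit products and combo libraries.

A parental line heterozygous at HLA-A and HLA-B can yield four distinct
"hemizygous" daughter lines by mono-allelic knockout: one retained A allele
crossed with one retained B allele. Each such product is a :class:`HemiCombo`.
A panel of parental lines yields a :class:`ComboLibrary` — the deduplicated
union of all products, with the parental lines that can produce each combo
tracked as its ``sources``. DRB1 is excluded from combo identity because every
bank line carries a bi-allelic DRB1 knockout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alleles import AlleleName, CellLine, format_allele_name, match_key

__all__ = ["HemiCombo", "ComboLibrary", "enumerate_combos", "build_library", "write_library"]


@dataclass(frozen=True)
class HemiCombo:
    """One hemizygous edit product: retained A allele x retained B allele."""

    a: AlleleName
    b: AlleleName
    sources: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[AlleleName, AlleleName]:
        return (self.a, self.b)

    @property
    def label(self) -> str:
        return f"{format_allele_name(self.a)}/{format_allele_name(self.b)}"

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class ComboLibrary:
    """Set of distinct combos at a working resolution, keyed by (a, b)."""

    combos: tuple[HemiCombo, ...]
    resolution: int

    def __post_init__(self) -> None:
        keys = [c.key for c in self.combos]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate combo keys in library")

    def __len__(self) -> int:
        return len(self.combos)

    def __iter__(self):
        return iter(self.combos)

    @property
    def source_lines(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.combos:
            out |= c.sources
        return frozenset(out)


def enumerate_combos(line: CellLine, resolution: int = 1) -> set[HemiCombo]:
    """All distinct hemizygous products of one line at the working resolution.

    Four combos for a line heterozygous at both loci, two if homozygous at
    one locus, one if homozygous at both (truncation to the resolution can
    collapse a heterozygous pair).
    """
    a_alleles = {match_key(a, resolution) for a in line.a.alleles}
    b_alleles = {match_key(b, resolution) for b in line.b.alleles}
    return {
        HemiCombo(a=a, b=b, sources=frozenset({line.line_id}))
        for a in a_alleles
        for b in b_alleles
    }


def build_library(panel: Sequence[CellLine], resolution: int = 1) -> ComboLibrary:
    """Deduplicated union of every panel line's combos, sources accumulated.

    Order-independent: combos are returned sorted by (a, b). The library size
    is at most 4x the panel size.
    """
    if not panel:
        raise ValueError("empty panel")
    ids = [ln.line_id for ln in panel]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate line_id(s): {dupes}")
    merged: dict[tuple[AlleleName, AlleleName], set[str]] = {}
    for line in panel:
        for combo in enumerate_combos(line, resolution):
            merged.setdefault(combo.key, set()).update(combo.sources)
    combos = tuple(
        HemiCombo(a=k[0], b=k[1], sources=frozenset(src))
        for k, src in sorted(merged.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    )
    return ComboLibrary(combos=combos, resolution=resolution)


def write_library(lib: ComboLibrary, path: str | Path) -> None:
    """Export as TSV: allele_A, allele_B, sources (semicolon-joined)."""
    rows = [
        {
            "allele_A": format_allele_name(c.a),
            "allele_B": format_allele_name(c.b),
            "sources": ";".join(sorted(c.sources)),
        }
        for c in lib.combos
    ]
    pd.DataFrame(rows, columns=["allele_A", "allele_B", "sources"]).to_csv(
        path, sep="\t", index=False
    )
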