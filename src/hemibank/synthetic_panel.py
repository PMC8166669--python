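"""Synthetic reconstruction of the four-parental-line reference panel.

The published study derived its 14-combo mini-library from four established
hESC lines (H9, CHA6, CHA15, SNU31). The complete HLA typings of those lines
live in supplementary material that is not redistributed here, so this module
provides a SYNTHETIC stand-in panel constrained to the facts the main text
does state:

* H9 is heterozygous A*02/A*03, B*35/B*44 (its realized clones include
  A02/- B35/- and A-/03 B-/44);
* the library contains the haplotype combos A*33/B*44 and A*33/B*58;
* the four double-heterozygous lines yield 16 raw combos of which exactly
  two coincide, leaving 14 distinct hemizygous products.

Only H9's genotype is authentic; the other three genotypes are plausible
common Korean alleles chosen to satisfy the structural constraints above.
Any analysis of the real bank must substitute the actual typings.
"""

from __future__ import annotations

from .alleles import CellLine, Locus, LocusGenotype, parse_allele_name

__all__ = ["synthetic_four_line_panel"]

_PANEL_SPEC = [
    # line_id, A1, A2, B1, B2, DRB1_1, DRB1_2
    ("H9", "A*02", "A*03", "B*35", "B*44", "DRB1*04", "DRB1*15"),
    ("CHA15", "A*33", "A*24", "B*44", "B*58", "DRB1*03", "DRB1*07"),
    ("CHA6", "A*02", "A*11", "B*35", "B*51", "DRB1*01", "DRB1*09"),
    ("SNU31", "A*24", "A*26", "B*07", "B*44", "DRB1*08", "DRB1*13"),
]


def synthetic_four_line_panel() -> list[CellLine]:
    """The synthetic four-line panel (H9 genotype authentic, rest stand-ins).

    The panel's 16 raw hemizygous products overlap in exactly two combos —
    (A*02, B*35) shared by H9 and CHA6, and (A*24, B*44) shared by CHA15 and
    SNU31 — so the deduplicated library holds 14 distinct combos.
    """
    panel = []
    for lid, a1, a2, b1, b2, d1, d2 in _PANEL_SPEC:
        panel.append(
            CellLine(
                line_id=lid,
                a=LocusGenotype(Locus.A, (parse_allele_name(a1), parse_allele_name(a2))),
                b=LocusGenotype(Locus.B, (parse_allele_name(b1), parse_allele_name(b2))),
                drb1=LocusGenotype(
                    Locus.DRB1, (parse_allele_name(d1), parse_allele_name(d2))
                ),
            )
        )
    return panel
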