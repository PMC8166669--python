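"""HLA allele nomenclature: parsing, formatting, resolution truncation and comparison.

An HLA allele name such as ``A*02:01N`` consists of a locus (``A``), colon-separated
numeric fields (``02``, ``01``) and an optional expression-suffix letter (``N``).
Fewer fields means lower typing resolution: ``A*02`` (one field, roughly the
serological antigen) groups every ``A*02:xx`` protein. Bank matching in this
package operates at an explicit field resolution, defaulting to one field,
because graft-versus-host antigen identity is what matters for a hemizygous
bank line and one-field names are how such banks are described.

Expression suffixes are preserved on parse but ignored for matching: the bank
model never distinguishes null/low-expression variants.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "Locus",
    "AlleleName",
    "OtherAllele",
    "AlleleLike",
    "LocusGenotype",
    "CellLine",
    "AlleleParseError",
    "parse_allele_name",
    "format_allele_name",
    "truncate_resolution",
    "alleles_equal",
    "read_panel",
    "write_panel",
]


class Locus(str, enum.Enum):
    """HLA loci handled by the bank model (class I A/B/C and class II DRB1)."""

    A = "A"
    B = "B"
    C = "C"
    DRB1 = "DRB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AlleleParseError(ValueError):
    """Raised when a string is not a well-formed HLA allele name."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A parsed HLA allele designation.

    Parameters
    ----------
    locus : Locus
        The gene the allele belongs to.
    fields : tuple of str
        Ordered numeric field strings, e.g. ``("02", "01")`` for ``A*02:01``.
        At least one field; digits only. Leading zeros are significant for
        display and preserved verbatim.
    suffix : str
        Optional expression-suffix letter(s) (``N``, ``L``, ...); empty when absent.
    """

    locus: Locus
    fields: tuple[str, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleParseError("allele needs at least one numeric field")
        for f in self.fields:
            if not f or not f.isdigit():
                raise AlleleParseError(f"non-numeric allele field {f!r}")

    @property
    def resolution(self) -> int:
        """Number of numeric fields carried by this name."""
        return len(self.fields)

    def __str__(self) -> str:
        return format_allele_name(self)


@dataclass(frozen=True, order=True)
class OtherAllele:
    """Reserved pseudo-allele absorbing unlisted frequency mass at one locus.

    ``OtherAllele`` compares equal only to itself (same locus) and never to a
    named allele, so residual population mass can never be "matched" by a bank
    line. This keeps coverage estimates conservative.
    """

    locus: Locus

    def __str__(self) -> str:
        return "OTHER"


AlleleLike = Union[AlleleName, OtherAllele]

# suffix restricted to the recognised expression letters (Null, Low, Secreted,
# Cytoplasm, Aberrant, Questionable)
_ALLELE_RE = re.compile(
    r"^\s*(?P<locus>[A-Za-z][A-Za-z0-9]*)\*(?P<fields>\d+(?::\d+)*)(?P<suffix>[NLSCAQnlscaq]?)\s*$"
)


def parse_allele_name(text: str) -> AlleleName:
    """Parse an allele name string like ``"A*33"`` or ``"B*44:02"``.

    The locus token is matched case-insensitively against the supported loci;
    fields must be digits. The literal string ``"OTHER"`` is *not* accepted
    here — residual mass is handled by :class:`OtherAllele` at the frequency
    table level, never typed into a panel.

    Raises
    ------
    AlleleParseError
        If the locus is unknown or the name is malformed.
    """
    m = _ALLELE_RE.match(text)
    if m is None:
        raise AlleleParseError(
            f"malformed allele name {text!r}: expected '<locus>*<field>[:<field>...][suffix]'"
        )
    locus_token = m.group("locus").upper()
    try:
        locus = Locus(locus_token)
    except ValueError:
        raise AlleleParseError(f"unknown locus {m.group('locus')!r} in {text!r}") from None
    fields = tuple(m.group("fields").split(":"))
    return AlleleName(locus=locus, fields=fields, suffix=m.group("suffix").upper())


def format_allele_name(a: AlleleLike) -> str:
    """Canonical string form; inverse of :func:`parse_allele_name` for named alleles."""
    if isinstance(a, OtherAllele):
        return "OTHER"
    return f"{a.locus.value}*{':'.join(a.fields)}{a.suffix}"


def truncate_resolution(a: AlleleLike, n_fields: int) -> AlleleLike:
    """Truncate an allele name to its ``n_fields`` leading fields.

    The suffix is dropped whenever truncation actually removes fields (a
    suffix qualifies the full-resolution name only). Idempotent; names already
    at or below the requested resolution are returned unchanged. ``OTHER``
    passes through untouched.
    """
    if n_fields < 1:
        raise ValueError(f"n_fields must be >= 1, got {n_fields}")
    if isinstance(a, OtherAllele):
        return a
    if len(a.fields) <= n_fields:
        return a
    return AlleleName(locus=a.locus, fields=a.fields[:n_fields], suffix="")


def match_key(a: AlleleLike, resolution: int) -> AlleleLike:
    """The identity used for matching at a resolution: truncated, suffix-free."""
    if isinstance(a, OtherAllele):
        return a
    t = truncate_resolution(a, resolution)
    if t.suffix:
        t = AlleleName(locus=t.locus, fields=t.fields, suffix="")
    return t


def alleles_equal(x: AlleleLike, y: AlleleLike, resolution: int = 1) -> bool:
    """True iff the two alleles are the same locus and agree at the resolution.

    Expression suffixes are ignored. ``OTHER`` equals only ``OTHER`` at the
    same locus; it never equals a named allele.
    """
    if isinstance(x, OtherAllele) or isinstance(y, OtherAllele):
        return isinstance(x, OtherAllele) and isinstance(y, OtherAllele) and x.locus == y.locus
    if x.locus != y.locus:
        return False
    return match_key(x, resolution) == match_key(y, resolution)


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered allele pair at one locus; equal alleles mean homozygous."""

    locus: Locus
    alleles: tuple[AlleleName, AlleleName]

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a.locus != self.locus:
                raise ValueError(
                    f"allele {a} does not belong to locus {self.locus.value}"
                )

    def is_homozygous(self, resolution: int | None = None) -> bool:
        a, b = self.alleles
        if resolution is None:
            return a == b
        return alleles_equal(a, b, resolution)


@dataclass(frozen=True)
class CellLine:
    """A candidate parental line with genotypes at HLA-A, -B and -DRB1."""

    line_id: str
    a: LocusGenotype
    b: LocusGenotype
    drb1: LocusGenotype

    def __post_init__(self) -> None:
        expected = {"a": Locus.A, "b": Locus.B, "drb1": Locus.DRB1}
        for attr, locus in expected.items():
            g: LocusGenotype = getattr(self, attr)
            if g.locus != locus:
                raise ValueError(f"{attr} genotype has locus {g.locus.value}, expected {locus.value}")

    def genotype(self, locus: Locus) -> LocusGenotype:
        return {Locus.A: self.a, Locus.B: self.b, Locus.DRB1: self.drb1}[locus]


_PANEL_COLUMNS = ["line_id", "A_1", "A_2", "B_1", "B_2", "DRB1_1", "DRB1_2"]


def _line_from_record(rec: Mapping[str, str]) -> CellLine:
    def pair(locus: Locus, k1: str, k2: str) -> LocusGenotype:
        return LocusGenotype(
            locus, (parse_allele_name(str(rec[k1])), parse_allele_name(str(rec[k2])))
        )

    return CellLine(
        line_id=str(rec["line_id"]),
        a=pair(Locus.A, "A_1", "A_2"),
        b=pair(Locus.B, "B_1", "B_2"),
        drb1=pair(Locus.DRB1, "DRB1_1", "DRB1_2"),
    )


def read_panel(path: str | Path) -> list[CellLine]:
    """Read a line panel from TSV (header row mandatory) or a JSON record list.

    Expected keys/columns: ``line_id, A_1, A_2, B_1, B_2, DRB1_1, DRB1_2``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel file {path} missing columns {missing}")
        records = df.to_dict("records")
    lines = [_line_from_record(r) for r in records]
    ids = [ln.line_id for ln in lines]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate line_id(s) in panel: {dupes}")
    return lines


def write_panel(panel: Sequence[CellLine], path: str | Path) -> None:
    """Write a panel to the TSV layout accepted by :func:`read_panel`."""
    rows = []
    for ln in panel:
        rows.append(
            {
                "line_id": ln.line_id,
                "A_1": str(ln.a.alleles[0]),
                "A_2": str(ln.a.alleles[1]),
                "B_1": str(ln.b.alleles[0]),
                "B_2": str(ln.b.alleles[1]),
                "DRB1_1": str(ln.drb1.alleles[0]),
                "DRB1_2": str(ln.drb1.alleles[1]),
            }
        )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)
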