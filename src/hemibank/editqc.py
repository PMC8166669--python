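"""Edit-outcome quantification: indel pattern classification, frameshift and
knockout genotype calls, indel frequencies, and the mitotic index.

Indel patterns use the aligned dash/lowercase convention common in amplicon
deep-sequencing figures: in the observed read, a dash marks a deleted
reference base, a lowercase letter (opposite a dash in the reference) marks
an inserted base, and an uppercase mismatch is a substitution. A frameshift
is called purely from the net length change modulo 3 — a premature stop via
frameshift triggers nonsense-mediated decay and hence loss of expression,
which is what knockout selection relies on.

The mitotic index summarises a division-generation histogram (e.g. from dye
dilution): with n_g cells observed in generation g, the absolute precursor
count is P = sum n_g * 2^-g and the number of mitotic events needed to
produce the observed population is M = sum n_g * (1 - 2^-g); the index is
M / P, i.e. mitotic events per precursor. An undivided population has index
0; one synchronous division gives 1; two give 3 (each precursor undergoes
1 + 2 = 3 divisions down the binary tree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .alleles import AlleleName, Locus

__all__ = [
    "IndelCall",
    "AlleleEditStatus",
    "classify_indel",
    "indel_frequency",
    "IndelFrequency",
    "knockout_call",
    "mitotic_index",
]

_BASES = set("ACGTN")
_INS = set("acgtn")


@dataclass(frozen=True)
class IndelCall:
    inserted_nt: int
    deleted_nt: int
    substitutions: int

    def __post_init__(self) -> None:
        if min(self.inserted_nt, self.deleted_nt, self.substitutions) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def net_change(self) -> int:
        return self.inserted_nt - self.deleted_nt

    @property
    def frameshift(self) -> bool:
        return self.net_change % 3 != 0


def classify_indel(ref_pattern: str, obs_pattern: str) -> IndelCall:
    """Tally an aligned ref/observed pattern pair into an indel call.

    Both strings must have equal length. Legal columns: matched or
    substituted uppercase bases; ``-`` in the observed row against a
    reference base (deletion); a lowercase base in the observed row against
    ``-`` in the reference (insertion).
    """
    if len(ref_pattern) != len(obs_pattern):
        raise ValueError(
            f"pattern length mismatch: {len(ref_pattern)} vs {len(obs_pattern)}"
        )
    if not ref_pattern:
        raise ValueError("empty patterns")
    ins = dele = sub = 0
    for i, (r, o) in enumerate(zip(ref_pattern, obs_pattern)):
        if r == "-":
            if o not in _INS:
                raise ValueError(
                    f"column {i}: reference gap must face a lowercase inserted base, got {o!r}"
                )
            ins += 1
        elif r in _BASES:
            if o == "-":
                dele += 1
            elif o in _BASES:
                if o != r:
                    sub += 1
            else:
                raise ValueError(f"column {i}: illegal observed character {o!r}")
        else:
            raise ValueError(f"column {i}: illegal reference character {r!r}")
    return IndelCall(inserted_nt=ins, deleted_nt=dele, substitutions=sub)


@dataclass(frozen=True)
class IndelFrequency:
    value: float
    n_edited: int
    n_total: int
    low_confidence: bool

    def __float__(self) -> float:
        return self.value


def indel_frequency(
    n_edited_reads: int, n_total_reads: int, min_reads: int = 100
) -> IndelFrequency:
    """Edited-read fraction with a low-confidence flag below ``min_reads``."""
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    if not (0 <= n_edited_reads <= n_total_reads):
        raise ValueError("n_edited_reads must lie in [0, n_total_reads]")
    return IndelFrequency(
        value=n_edited_reads / n_total_reads,
        n_edited=n_edited_reads,
        n_total=n_total_reads,
        low_confidence=n_total_reads < min_reads,
    )


@dataclass(frozen=True)
class AlleleEditStatus:
    """Per-allele edit outcome at one locus."""

    allele: AlleleName
    call: str  # intact | in_frame_indel | frameshift
    indel: IndelCall | None = None

    def __post_init__(self) -> None:
        if self.call not in ("intact", "in_frame_indel", "frameshift"):
            raise ValueError(f"unknown call {self.call!r}")
        if self.indel is not None:
            if self.call == "frameshift" and not self.indel.frameshift:
                raise ValueError("frameshift call with in-frame indel")
            if self.call == "in_frame_indel" and self.indel.frameshift:
                raise ValueError("in_frame_indel call with frameshifting indel")
            if self.call == "intact" and (self.indel.inserted_nt or self.indel.deleted_nt):
                raise ValueError("intact call with an indel present")


_LOCUS_PREFIX = {Locus.A: "A", Locus.B: "B", Locus.C: "C", Locus.DRB1: "D"}


def knockout_call(statuses: Sequence[AlleleEditStatus]) -> str:
    """Genotype label for one locus from its two allele edit statuses.

    Both frameshifted -> null ("D-/-"); exactly one frameshifted ->
    hemizygous, retaining the intact allele's first field in its slot
    ("A02/-" or "A-/03"); neither -> "+/+". An in-frame indel retains
    expression and never counts as knockout (warned, since the edit was
    presumably intended to disrupt).
    """
    if len(statuses) != 2:
        raise ValueError("exactly two allele statuses required")
    s1, s2 = statuses
    if s1.allele.locus != s2.allele.locus:
        raise ValueError(
            f"locus mismatch: {s1.allele.locus.value} vs {s2.allele.locus.value}"
        )
    prefix = _LOCUS_PREFIX[s1.allele.locus]
    fs = [s.call == "frameshift" for s in statuses]
    if all(fs):
        return f"{prefix}-/-"
    if any(fs):
        slots = [
            "-" if s.call == "frameshift" else s.allele.fields[0] for s in statuses
        ]
        return f"{prefix}{slots[0]}/{slots[1]}"
    if any(s.call == "in_frame_indel" for s in statuses):
        warnings.warn(
            "in-frame indel retains expression; locus called +/+", stacklevel=2
        )
    return "+/+"


def mitotic_index(hist: Union[Mapping[int, float], Sequence[float]]) -> float:
    """Mitotic events per absolute precursor from a division-generation histogram.

    ``hist`` maps generation g (0 = undivided) to the observed cell count
    n_g, or is a sequence indexed by g. Precursors P = sum n_g 2^-g; mitotic
    events M = sum n_g (1 - 2^-g); returns M / P. Scale-invariant in the
    counts.
    """
    if isinstance(hist, Mapping):
        items = list(hist.items())
    else:
        items = list(enumerate(hist))
    if not items:
        raise ValueError("empty histogram")
    total = precursors = 0.0
    for g, n in items:
        if g < 0 or int(g) != g:
            raise ValueError(f"generation must be a nonnegative integer, got {g}")
        if n < 0:
            raise ValueError(f"negative count {n} at generation {g}")
        total += n
        precursors += n * 2.0 ** (-g)
    if total <= 0:
        raise ValueError("histogram has no cells")
    return (total - precursors) / precursors
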