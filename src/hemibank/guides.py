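"""Allele-discriminating SpCas9 guide design for HLA knockouts.

Mono-allelic (hemizygous) knockout needs a guide that cuts one allele of a
heterozygous locus but spares the other; bi-allelic knockout (DRB1-null)
needs a guide whose site is identical in both alleles. Given a pair of
allele sequences — the *target* (to be cut) and the *spare* (to be kept) —
this module enumerates canonical SpCas9 protospacers (20-nt spacer + NGG PAM,
blunt cut 3 nt 5' of the PAM) on the target and classifies each site by its
aligned counterpart in the spare:

* *discriminating*: the spare counterpart differs by at least
  ``min_seed_mismatches`` substitutions inside the PAM-proximal 10-nt seed or
  the PAM GG dinucleotide, or is disrupted by an alignment gap; additionally
  the exact 20-nt spacer must have no perfect match anywhere in the spare
  (either strand). Seed/PAM mismatches are the strongest determinants of
  Cas9 allele specificity, hence the criterion.
* *shared*: the 23-nt site is perfectly identical in both alleles.

Coordinates are 0-based half-open on the + strand of the target; minus-strand
guides are reported in protospacer orientation with their genomic interval on
the + reference. ``N`` never counts as a match and disqualifies a PAM GG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "AlleleSequencePair",
    "ProtospacerSite",
    "GuideCandidate",
    "find_protospacers",
    "discriminating_guides",
    "read_allele_pair",
    "write_guides",
]

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN
SEED_LEN = 10  # PAM-proximal spacer nucleotides
# protospacer-orientation offsets whose mismatches count toward the seed:
# spacer positions 10..19 plus the PAM GG (offsets 21, 22)
_SEED_OFFSETS = frozenset(range(SPACER_LEN - SEED_LEN, SPACER_LEN)) | {21, 22}
# cut is between spacer positions 17 and 18, i.e. 3 nt 5' of the PAM
_CUT_OFFSET = 17

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _revcomp_gapped(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN-", "TGCAN-"))[::-1]


def _clean(seq: str, what: str) -> str:
    seq = seq.strip().upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in {what} sequence")
    if not seq:
        raise ValueError(f"empty {what} sequence")
    return seq


class ProtospacerSite(NamedTuple):
    spacer: str
    pam: str
    strand: str  # '+' or '-'
    start: int  # 0-based start of the 23-nt window on the + reference


def find_protospacers(seq: str) -> list[ProtospacerSite]:
    """All canonical SpCas9 sites: 23-nt windows ending NGG (+) or starting CCN (-).

    Minus-strand sites are reported in protospacer orientation (spacer and
    PAM reverse-complemented) with ``start`` still on the + reference.
    Windows whose PAM GG contains an N are excluded. Sorted by start, then
    strand (+ before -).
    """
    seq = _clean(seq, "input")
    if len(seq) < SITE_LEN:
        raise ValueError(f"sequence of {len(seq)} nt is shorter than {SITE_LEN}")
    sites: list[ProtospacerSite] = []
    for i in range(len(seq) - SITE_LEN + 1):
        window = seq[i : i + SITE_LEN]
        if window[SPACER_LEN + 1] == "G" and window[SPACER_LEN + 2] == "G":
            sites.append(ProtospacerSite(window[:SPACER_LEN], window[SPACER_LEN:], "+", i))
        if window[0] == "C" and window[1] == "C":
            rc = _revcomp(window)
            sites.append(ProtospacerSite(rc[:SPACER_LEN], rc[SPACER_LEN:], "-", i))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM hit annotated against the spare allele."""

    spacer: str
    pam: str
    strand: str
    start: int  # 0-based, + reference of the target allele
    end: int  # start + 23 (half-open)
    cut_site: int  # + reference coordinate of the blunt cut point
    seed_mismatches: int
    discriminating_positions: tuple[int, ...]  # protospacer-orientation offsets 0..22
    gap_overlap: bool
    mode: str  # discriminating | shared

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN or len(self.pam) != PAM_LEN:
            raise ValueError("malformed guide geometry")
        if self.end - self.start != SITE_LEN:
            raise ValueError("site interval must span 23 nt")


@dataclass(frozen=True)
class AlleleSequencePair:
    """Target and spare allele sequences with an end-to-end alignment.

    ``aligned_target``/``aligned_spare`` are equal-length gapped strings whose
    ungapped forms are exactly ``target_seq``/``spare_seq``. Supply them for a
    curated alignment, or omit both to have a global pairwise alignment built
    internally.
    """

    target_id: str
    spare_id: str
    target_seq: str
    spare_seq: str
    aligned_target: str = ""
    aligned_spare: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_seq", _clean(self.target_seq, "target"))
        object.__setattr__(self, "spare_seq", _clean(self.spare_seq, "spare"))
        if bool(self.aligned_target) != bool(self.aligned_spare):
            raise ValueError("provide both aligned strings or neither")
        if not self.aligned_target:
            at, as_ = _global_align(self.target_seq, self.spare_seq)
            object.__setattr__(self, "aligned_target", at)
            object.__setattr__(self, "aligned_spare", as_)
        else:
            object.__setattr__(self, "aligned_target", self.aligned_target.strip().upper())
            object.__setattr__(self, "aligned_spare", self.aligned_spare.strip().upper())
        if len(self.aligned_target) != len(self.aligned_spare):
            raise ValueError("aligned strings differ in length")
        if self.aligned_target.replace("-", "") != self.target_seq:
            raise ValueError("aligned_target does not spell target_seq")
        if self.aligned_spare.replace("-", "") != self.spare_seq:
            raise ValueError("aligned_spare does not spell spare_seq")

    def target_columns(self) -> list[int]:
        """Alignment column index of each target (ungapped) position."""
        return [i for i, ch in enumerate(self.aligned_target) if ch != "-"]


def _global_align(a: str, b: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _window_in_alignment(pair: AlleleSequencePair, start: int) -> tuple[str, str]:
    """Aligned target/spare slices spanning target positions [start, start+23)."""
    cols = pair.target_columns()
    lo, hi = cols[start], cols[start + SITE_LEN - 1]
    return pair.aligned_target[lo : hi + 1], pair.aligned_spare[lo : hi + 1]


def _compare_window(tgt_aln: str, sp_aln: str, strand: str) -> tuple[tuple[int, ...], int, bool]:
    """Differences between aligned windows, in protospacer orientation.

    Returns (differing offsets 0..22, seed mismatch count, gap overlap flag).
    With gaps present, offsets index the target's non-gap characters; a spare
    insertion (target gap column) is attributed to the next target offset.
    """
    if strand == "-":
        tgt_aln, sp_aln = _revcomp_gapped(tgt_aln), _revcomp_gapped(sp_aln)
    gap = "-" in tgt_aln or "-" in sp_aln
    diffs: set[int] = set()
    offset = 0
    for t, s in zip(tgt_aln, sp_aln):
        if t == "-":
            diffs.add(min(offset, SITE_LEN - 1))
            continue
        if s == "-" or t != s or t == "N" or s == "N":
            diffs.add(offset)
        offset += 1
    positions = tuple(sorted(diffs))
    seed_mm = sum(1 for p in positions if p in _SEED_OFFSETS)
    return positions, seed_mm, gap


Mode = Literal["discriminating", "shared"]


def discriminating_guides(
    pair: AlleleSequencePair,
    mode: Mode = "discriminating",
    min_seed_mismatches: int = 1,
) -> list[GuideCandidate]:
    """Guides on the target allele, filtered against the spare allele.

    ``mode="discriminating"``: keep sites with >= ``min_seed_mismatches``
    substitutions in the seed/PAM-GG, or any alignment gap across the site;
    the exact spacer must additionally be absent from the spare on both
    strands. Sorted by seed mismatches (descending), then start.

    ``mode="shared"``: keep sites perfectly identical in both alleles
    (intended for bi-allelic knockouts). Sorted by start.

    An empty protospacer set yields an empty result, not an error.
    """
    if mode not in ("discriminating", "shared"):
        raise ValueError(f"unknown mode {mode!r}")
    if min_seed_mismatches < 1:
        raise ValueError("min_seed_mismatches must be >= 1")
    spare = pair.spare_seq
    spare_rc = _revcomp(spare)
    out: list[GuideCandidate] = []
    for site in find_protospacers(pair.target_seq):
        tgt_aln, sp_aln = _window_in_alignment(pair, site.start)
        positions, seed_mm, gap = _compare_window(tgt_aln, sp_aln, site.strand)
        if mode == "shared":
            if positions or gap or "N" in tgt_aln:
                continue
        else:
            if seed_mm < min_seed_mismatches and not gap:
                continue
            if site.spacer in spare or site.spacer in spare_rc:
                continue  # a perfect protospacer elsewhere in the spare would cut it
        # boundary coordinate: the cut falls between cut-1 and cut on the + reference
        cut = site.start + _CUT_OFFSET if site.strand == "+" else site.start + (SITE_LEN - _CUT_OFFSET)
        out.append(
            GuideCandidate(
                spacer=site.spacer,
                pam=site.pam,
                strand=site.strand,
                start=site.start,
                end=site.start + SITE_LEN,
                cut_site=cut,
                seed_mismatches=seed_mm,
                discriminating_positions=positions,
                gap_overlap=gap,
                mode=mode,
            )
        )
    if mode == "discriminating":
        out.sort(key=lambda g: (-g.seed_mismatches, g.start, g.strand))
    else:
        out.sort(key=lambda g: (g.start, g.strand))
    return out


def read_allele_pair(path: str | Path) -> AlleleSequencePair:
    """Read a FASTA with two records (target first, spare second).

    Records of equal length containing ``-`` are treated as a pre-built
    alignment; otherwise a global alignment is computed internally.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path} must contain exactly two records, found {len(records)}")
    t, s = records
    t_str, s_str = str(t.seq).upper(), str(s.seq).upper()
    if "-" in t_str or "-" in s_str:
        if len(t_str) != len(s_str):
            raise ValueError("gapped records must have equal aligned length")
        return AlleleSequencePair(
            target_id=t.id,
            spare_id=s.id,
            target_seq=t_str.replace("-", ""),
            spare_seq=s_str.replace("-", ""),
            aligned_target=t_str,
            aligned_spare=s_str,
        )
    return AlleleSequencePair(target_id=t.id, spare_id=s.id, target_seq=t_str, spare_seq=s_str)


def write_guides(guides: Sequence[GuideCandidate], path: str | Path) -> None:
    """Export guides as TSV."""
    rows = [
        {
            "spacer": g.spacer,
            "pam": g.pam,
            "strand": g.strand,
            "start": g.start,
            "end": g.end,
            "cut_site": g.cut_site,
            "seed_mismatches": g.seed_mismatches,
            "discriminating_positions": ";".join(map(str, g.discriminating_positions)),
            "mode": g.mode,
        }
        for g in guides
    ]
    cols = [
        "spacer", "pam", "strand", "start", "end", "cut_site",
        "seed_mismatches", "discriminating_positions", "mode",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
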