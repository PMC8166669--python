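"""Population coverage of a hemizygous combo library.

A recipient is *matched* by a bank combo (a, b) when both of the graft's two
expressed antigens are present in the recipient's genotype: a among the
recipient's two HLA-A alleles and b among the two HLA-B alleles. Only the
host-versus-graft direction matters for a hemizygous ("homozygous-like")
line, so the recipient's unshared alleles are irrelevant, and the two
required alleles may sit on different recipient haplotypes.

Coverage of a library is the probability, under Hardy-Weinberg random mating
over the haplotype distribution p(h), that a random individual is matched by
at least one combo:

    C = sum over ordered haplotype pairs (h1, h2) of
        p(h1) p(h2) 1[some combo matches the genotype (h1, h2)]

The exact computation enumerates haplotype pairs with vectorised boolean
indicator matrices — O(|H|^2) per combo — which stays well under a minute for
|H| <= 2500 haplotypes and libraries of ~100 combos on one CPU. A
haplotype-level variant (individual covered only if a single haplotype
carries both antigens of one combo) is provided for comparison; the
genotype-level rule is the default.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .alleles import AlleleLike, OtherAllele, format_allele_name, match_key
from .bank import ComboLibrary, HemiCombo
from .frequencies import Genotype, HaplotypeTable, sample_genotypes

__all__ = [
    "CoverageResult",
    "CoverageCurve",
    "combo_matches",
    "analytic_coverage",
    "cumulative_coverage",
    "monte_carlo_coverage",
    "CoverageState",
]

MatchModel = Literal["genotype", "haplotype"]


@dataclass(frozen=True)
class CoverageResult:
    """Coverage C in [0, 1] with its method and provenance metadata."""

    coverage: float
    method: str  # analytic | monte_carlo
    population: str
    resolution: int
    n_samples: int | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.coverage <= 1 + 1e-12):
            raise ValueError(f"coverage {self.coverage} outside [0,1]")
        if (self.method == "monte_carlo") != (self.se is not None):
            raise ValueError("standard error present iff method is monte_carlo")


@dataclass(frozen=True)
class CoverageCurve:
    """Cumulative coverage C_k along an ordered combo list; C_0 = 0."""

    combo_labels: tuple[str, ...]
    cumulative: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.combo_labels) != len(self.cumulative):
            raise ValueError("labels and cumulative values differ in length")
        prev = 0.0
        for c in self.cumulative:
            if c < prev - 1e-12:
                raise ValueError("cumulative coverage must be nondecreasing")
            prev = c

    @property
    def final(self) -> float:
        return self.cumulative[-1] if self.cumulative else 0.0


def combo_matches(c: HemiCombo, g: Genotype, resolution: int = 1) -> bool:
    """True iff the recipient genotype carries both of the combo's antigens.

    Allele-level and cross-haplotype: c.a must appear among the genotype's
    two A alleles and c.b among its two B alleles, on either haplotype.
    OTHER pseudo-alleles never match.
    """
    ca, cb = match_key(c.a, resolution), match_key(c.b, resolution)
    if isinstance(ca, OtherAllele) or isinstance(cb, OtherAllele):
        return False
    a_keys = {match_key(x, resolution) for x in g.a_alleles}
    b_keys = {match_key(x, resolution) for x in g.b_alleles}
    return ca in a_keys and cb in b_keys


def _combo_keys(
    combos: Iterable[HemiCombo], resolution: int
) -> list[tuple[AlleleLike, AlleleLike]]:
    seen: list[tuple[AlleleLike, AlleleLike]] = []
    for c in combos:
        k = (match_key(c.a, resolution), match_key(c.b, resolution))
        if k not in seen:
            seen.append(k)
    return seen


class CoverageState:
    """Incremental exact coverage over a haplotype table.

    Maintains the boolean matched-matrix over ordered haplotype pairs so that
    combos can be added one at a time in O(|H|^2); used by the greedy
    selectors and the cumulative-coverage curve.
    """

    def __init__(self, h: HaplotypeTable, resolution: int = 1):
        self.table = h
        self.resolution = resolution
        self._haps = h.haplotypes
        self._p = h.probabilities()
        # per-haplotype allele identity keys at the working resolution
        self._a_keys = [match_key(a, resolution) for a, _ in self._haps]
        self._b_keys = [match_key(b, resolution) for _, b in self._haps]
        n = len(self._haps)
        self._matched = np.zeros((n, n), dtype=bool)
        self._hap_matched = np.zeros(n, dtype=bool)  # haplotype-level rule

    def _indicator(self, combo: HemiCombo) -> tuple[np.ndarray, np.ndarray]:
        ca = match_key(combo.a, self.resolution)
        cb = match_key(combo.b, self.resolution)
        if isinstance(ca, OtherAllele) or isinstance(cb, OtherAllele):
            n = len(self._haps)
            return np.zeros(n, dtype=bool), np.zeros(n, dtype=bool)
        va = np.array([k == ca for k in self._a_keys], dtype=bool)
        vb = np.array([k == cb for k in self._b_keys], dtype=bool)
        return va, vb

    def _pair_match(self, combo: HemiCombo) -> np.ndarray:
        va, vb = self._indicator(combo)
        has_a = va[:, None] | va[None, :]
        has_b = vb[:, None] | vb[None, :]
        return has_a & has_b

    def gain(self, combo: HemiCombo) -> float:
        """Marginal coverage gain of adding one combo (state unchanged)."""
        new = self._pair_match(combo) & ~self._matched
        return float(self._p @ new @ self._p)

    def gain_of(self, combos: Sequence[HemiCombo]) -> float:
        """Marginal gain of adding several combos at once (state unchanged)."""
        n = len(self._haps)
        new = np.zeros((n, n), dtype=bool)
        for c in combos:
            new |= self._pair_match(c)
        new &= ~self._matched
        return float(self._p @ new @ self._p)

    def add(self, combo: HemiCombo) -> float:
        """Add a combo; returns its marginal gain."""
        pm = self._pair_match(combo)
        g = float(self._p @ (pm & ~self._matched) @ self._p)
        self._matched |= pm
        va, vb = self._indicator(combo)
        self._hap_matched |= va & vb
        return g

    @property
    def coverage(self) -> float:
        return float(self._p @ self._matched @ self._p)

    @property
    def haplotype_coverage(self) -> float:
        """P(at least one of the individual's two haplotypes is fully matched)."""
        q = float(self._p @ self._hap_matched)
        return 1.0 - (1.0 - q) ** 2


def analytic_coverage(
    lib: ComboLibrary | Iterable[HemiCombo],
    h: HaplotypeTable,
    resolution: int = 1,
    model: MatchModel = "genotype",
) -> CoverageResult:
    """Exact coverage of a combo library under the haplotype distribution.

    ``model="genotype"`` (default): matched iff the genotype carries both
    antigens of some combo, cross-haplotype allowed. ``model="haplotype"``:
    matched iff one haplotype is itself a library combo. An empty library has
    coverage 0.
    """
    combos = list(lib)
    state = CoverageState(h, resolution)
    for c in combos:
        state.add(c)
    cov = state.coverage if model == "genotype" else state.haplotype_coverage
    return CoverageResult(
        coverage=min(cov, 1.0),
        method="analytic",
        population=h.population,
        resolution=resolution,
    )


def cumulative_coverage(
    ordered: Sequence[HemiCombo],
    h: HaplotypeTable,
    resolution: int = 1,
) -> CoverageCurve:
    """Cumulative coverage C_k after each prefix of an ordered combo list.

    Duplicate combo keys in the list are rejected. The final point equals the
    analytic coverage of the whole set.
    """
    keys = _combo_keys(ordered, resolution)
    if len(keys) != len(list(ordered)):
        raise ValueError("duplicate combo keys in ordered list")
    state = CoverageState(h, resolution)
    labels, cums = [], []
    for c in ordered:
        state.add(c)
        labels.append(c.label)
        cums.append(state.coverage)
    return CoverageCurve(combo_labels=tuple(labels), cumulative=tuple(cums))


def monte_carlo_coverage(
    lib: ComboLibrary | Iterable[HemiCombo],
    h: HaplotypeTable,
    n: int,
    seed: int,
    resolution: int = 1,
) -> CoverageResult:
    """Coverage estimated from n simulated HWE genotypes, with binomial SE.

    Deterministic for a fixed seed; validates the analytic computation.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    combos = list(lib)
    haps = h.haplotypes
    p = h.probabilities()
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(haps), size=(n, 2), p=p)

    # integer-coded allele identities per haplotype for vectorised matching
    a_keys = [match_key(a, resolution) for a, _ in haps]
    b_keys = [match_key(b, resolution) for _, b in haps]
    a_code_of = {k: i for i, k in enumerate(dict.fromkeys(a_keys))}
    b_code_of = {k: i for i, k in enumerate(dict.fromkeys(b_keys))}
    a_code = np.array([a_code_of[k] for k in a_keys])
    b_code = np.array([b_code_of[k] for k in b_keys])
    a1, a2 = a_code[idx[:, 0]], a_code[idx[:, 1]]
    b1, b2 = b_code[idx[:, 0]], b_code[idx[:, 1]]

    matched = np.zeros(n, dtype=bool)
    for c in combos:
        ca = match_key(c.a, resolution)
        cb = match_key(c.b, resolution)
        if isinstance(ca, OtherAllele) or isinstance(cb, OtherAllele):
            continue
        if ca not in a_code_of or cb not in b_code_of:
            continue
        ia, ib = a_code_of[ca], b_code_of[cb]
        matched |= ((a1 == ia) | (a2 == ia)) & ((b1 == ib) | (b2 == ib))
    c_hat = float(matched.mean())
    se = math.sqrt(c_hat * (1.0 - c_hat) / n)
    return CoverageResult(
        coverage=c_hat,
        method="monte_carlo",
        population=h.population,
        resolution=resolution,
        n_samples=n,
        se=se,
    )


def library_fingerprint(lib: ComboLibrary | Iterable[HemiCombo]) -> str:
    """Stable short hash of a library's combo keys, for report provenance."""
    labels = sorted(c.label for c in lib)
    return hashlib.sha256("|".join(labels).encode()).hexdigest()[:12]
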