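"""Independent reference implementations used as test oracles.

These deliberately avoid the vectorised matrix code paths in
``hemibank.coverage``: coverage is recomputed by plain-Python enumeration of
ordered haplotype pairs, and by inclusion-exclusion over combo subsets.
"""

from __future__ import annotations

import itertools

from hemibank.alleles import OtherAllele, match_key
from hemibank.frequencies import HaplotypeTable


def _combo_key(combo, resolution):
    return (match_key(combo.a, resolution), match_key(combo.b, resolution))


def _pair_matched_by(ca, cb, h1, h2, resolution):
    if isinstance(ca, OtherAllele) or isinstance(cb, OtherAllele):
        return False
    a_set = {match_key(h1[0], resolution), match_key(h2[0], resolution)}
    b_set = {match_key(h1[1], resolution), match_key(h2[1], resolution)}
    return ca in a_set and cb in b_set


def coverage_by_enumeration(combos, h: HaplotypeTable, resolution: int = 1) -> float:
    """Sum p(h1)p(h2) over ordered pairs matched by at least one combo."""
    keys = [_combo_key(c, resolution) for c in combos]
    total = 0.0
    for h1, p1 in h.entries.items():
        for h2, p2 in h.entries.items():
            if any(_pair_matched_by(ca, cb, h1, h2, resolution) for ca, cb in keys):
                total += p1 * p2
    return total


def coverage_by_inclusion_exclusion(combos, h: HaplotypeTable, resolution: int = 1) -> float:
    """P(union of per-combo match events) via inclusion-exclusion.

    Each subset probability is evaluated by direct enumeration of haplotype
    pairs against *all* combos of the subset simultaneously.
    """
    keys = list(dict.fromkeys(_combo_key(c, resolution) for c in combos))
    total = 0.0
    for r in range(1, len(keys) + 1):
        sign = (-1) ** (r + 1)
        for subset in itertools.combinations(keys, r):
            p_subset = 0.0
            for h1, p1 in h.entries.items():
                for h2, p2 in h.entries.items():
                    if all(
                        _pair_matched_by(ca, cb, h1, h2, resolution)
                        for ca, cb in subset
                    ):
                        p_subset += p1 * p2
            total += sign * p_subset
    return total
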