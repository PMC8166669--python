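"""Greedy accumulative selection of combos or parental lines to a coverage
threshold, plus an exhaustive minimal-subset oracle for small panels.

Coverage is a monotone submodular set function of the chosen combos, so the
classic greedy heuristic (repeatedly add the item with the largest marginal
gain) is the natural banking strategy and carries the usual (1 - 1/e)
worst-case guarantee relative to the optimum of the same cardinality. Two
units of selection are offered:

* ``combo_greedy`` — pick individual hemizygous combos; the parental lines
  needed are derived afterwards by a greedy hitting set over each combo's
  sources.
* ``line_greedy`` (default) — pick whole parental lines (a line contributes
  all of its combos at once), then prune each chosen line's combos to those
  with a positive marginal gain in pick order. This directly yields both a
  line count and a combo count for a bank plan.

All ties break lexicographically, making plans deterministic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .alleles import CellLine
from .bank import ComboLibrary, HemiCombo, build_library, enumerate_combos
from .coverage import CoverageState
from .frequencies import HaplotypeTable

__all__ = [
    "SelectionPick",
    "SelectionPlan",
    "greedy_select_combos",
    "greedy_select_lines",
    "exhaustive_min_lines",
    "ExhaustiveResult",
    "write_plan",
]

_GAIN_EPS = 1e-15  # below this a marginal gain is numerically zero


@dataclass(frozen=True)
class SelectionPick:
    identifier: str
    gain: float
    cumulative: float


@dataclass(frozen=True)
class SelectionPlan:
    """Ordered greedy picks with cumulative coverage and the bank head-counts."""

    strategy: str  # combo_greedy | line_greedy
    threshold: float
    picks: tuple[SelectionPick, ...]
    reached: bool
    n_lines: int
    n_combos: int
    resolution: int
    population: str

    def __post_init__(self) -> None:
        prev = 0.0
        for p in self.picks:
            if p.gain <= 0:
                raise ValueError("every recorded pick must have positive gain")
            if p.cumulative < prev - 1e-12:
                raise ValueError("cumulative coverage must be nondecreasing")
            prev = p.cumulative
        if self.reached != (self.final_coverage >= self.threshold - 1e-12):
            raise ValueError("reached flag inconsistent with final coverage")

    @property
    def final_coverage(self) -> float:
        return self.picks[-1].cumulative if self.picks else 0.0


def _check_threshold(threshold: float) -> None:
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")


def _hitting_lines(chosen: Sequence[HemiCombo]) -> set[str]:
    """Greedy minimal hitting set of parental lines over the picks' sources.

    Repeatedly take the line that can produce the most still-unassigned
    combos (ties: lexicographic line_id).
    """
    remaining = [c for c in chosen]
    lines: set[str] = set()
    while remaining:
        counts: dict[str, int] = {}
        for c in remaining:
            for src in c.sources:
                counts[src] = counts.get(src, 0) + 1
        best = min(counts, key=lambda s: (-counts[s], s))
        lines.add(best)
        remaining = [c for c in remaining if best not in c.sources]
    return lines


def greedy_select_combos(
    candidates: ComboLibrary,
    h: HaplotypeTable,
    threshold: float,
    resolution: int | None = None,
) -> SelectionPlan:
    """Greedy combo-level selection until coverage >= threshold.

    Each step adds the candidate with the largest marginal analytic coverage
    gain (ties by the (a, b) label). Stops when the threshold is reached or no
    candidate has positive gain. ``n_lines`` is the size of a greedy hitting
    set of parental sources over the chosen combos.
    """
    _check_threshold(threshold)
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    res = candidates.resolution if resolution is None else resolution
    state = CoverageState(h, res)
    pool = list(candidates)
    picks: list[SelectionPick] = []
    chosen: list[HemiCombo] = []
    while pool and state.coverage < threshold - 1e-12:
        gains = [(state.gain(c), c) for c in pool]
        best_gain, best = min(gains, key=lambda gc: (-gc[0], gc[1].label))
        if best_gain <= _GAIN_EPS:
            break
        state.add(best)
        chosen.append(best)
        picks.append(SelectionPick(best.label, best_gain, state.coverage))
        pool.remove(best)
    cov = picks[-1].cumulative if picks else 0.0
    return SelectionPlan(
        strategy="combo_greedy",
        threshold=threshold,
        picks=tuple(picks),
        reached=cov >= threshold - 1e-12,
        n_lines=len(_hitting_lines(chosen)),
        n_combos=len(chosen),
        resolution=res,
        population=h.population,
    )


def greedy_select_lines(
    panel: Sequence[CellLine],
    h: HaplotypeTable,
    threshold: float,
    resolution: int = 1,
) -> SelectionPlan:
    """Greedy line-level selection, then prune redundant combos.

    A line's gain is the coverage gained by adding all of its combos at once;
    the line with the largest gain is picked (ties by line_id) until the
    threshold is reached or no line adds coverage. The chosen lines' combos
    are then replayed in pick order and only those with positive marginal
    gain are kept — ``n_combos`` counts the hemizygous daughter lines a bank
    would actually derive.
    """
    _check_threshold(threshold)
    if not panel:
        raise ValueError("empty panel")
    state = CoverageState(h, resolution)
    combos_of = {
        ln.line_id: sorted(enumerate_combos(ln, resolution), key=lambda c: c.label)
        for ln in panel
    }
    pool = sorted(combos_of, key=str)
    picks: list[SelectionPick] = []
    order: list[str] = []
    while pool and state.coverage < threshold - 1e-12:
        gains = [(state.gain_of(combos_of[lid]), lid) for lid in pool]
        best_gain, best = min(gains, key=lambda gl: (-gl[0], gl[1]))
        if best_gain <= _GAIN_EPS:
            break
        for c in combos_of[best]:
            state.add(c)
        order.append(best)
        picks.append(SelectionPick(best, best_gain, state.coverage))
        pool.remove(best)

    # prune: replay combos in pick order, keep only positive-gain ones
    prune_state = CoverageState(h, resolution)
    kept = 0
    for lid in order:
        for c in combos_of[lid]:
            if prune_state.add(c) > _GAIN_EPS:
                kept += 1
    cov = picks[-1].cumulative if picks else 0.0
    return SelectionPlan(
        strategy="line_greedy",
        threshold=threshold,
        picks=tuple(picks),
        reached=cov >= threshold - 1e-12,
        n_lines=len(order),
        n_combos=kept,
        resolution=resolution,
        population=h.population,
    )


@dataclass(frozen=True)
class ExhaustiveResult:
    feasible: bool
    n_lines: int | None
    lines: tuple[str, ...] | None
    coverage: float | None


def exhaustive_min_lines(
    panel: Sequence[CellLine],
    h: HaplotypeTable,
    threshold: float,
    resolution: int = 1,
    max_panel: int = 15,
) -> ExhaustiveResult:
    """Smallest line subset reaching the threshold, by exhaustive search.

    Searches subsets in increasing cardinality (within a cardinality, in
    lexicographic panel order), so the first hit is a minimum-size witness.
    Only intended as an oracle for small panels (``|panel| <= max_panel``).
    """
    _check_threshold(threshold)
    if len(panel) > max_panel:
        raise ValueError(f"panel of {len(panel)} exceeds max_panel={max_panel}")
    for k in range(1, len(panel) + 1):
        for subset in itertools.combinations(panel, k):
            state = CoverageState(h, resolution)
            for ln in subset:
                for c in enumerate_combos(ln, resolution):
                    state.add(c)
            if state.coverage >= threshold - 1e-12:
                return ExhaustiveResult(
                    feasible=True,
                    n_lines=k,
                    lines=tuple(ln.line_id for ln in subset),
                    coverage=state.coverage,
                )
    return ExhaustiveResult(feasible=False, n_lines=None, lines=None, coverage=None)


def write_plan(plan: SelectionPlan, path: str | Path) -> None:
    """Export a selection plan as JSON."""
    payload = {
        "strategy": plan.strategy,
        "threshold": plan.threshold,
        "population": plan.population,
        "resolution": plan.resolution,
        "reached": plan.reached,
        "n_lines": plan.n_lines,
        "n_combos": plan.n_combos,
        "final_coverage": plan.final_coverage,
        "picks": [
            {"identifier": p.identifier, "gain": p.gain, "cumulative": p.cumulative}
            for p in plan.picks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
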