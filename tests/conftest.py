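from __future__ import annotations

import hypothesis
import numpy as np
import pytest

from hemibank.alleles import AlleleName, Locus
from hemibank.bank import HemiCombo
from hemibank.frequencies import HaplotypeTable

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


def one_field(locus: Locus, i: int) -> AlleleName:
    return AlleleName(locus=locus, fields=(f"{i:02d}",))


def random_haplotype_table(
    rng: np.random.Generator,
    n_a: int,
    n_b: int,
    population: str = "test",
    concentration: float = 0.8,
) -> HaplotypeTable:
    """Joint Dirichlet over an n_a x n_b allele grid (has LD in general)."""
    grid = rng.dirichlet(np.full(n_a * n_b, concentration)).reshape(n_a, n_b)
    entries = {
        (one_field(Locus.A, i + 1), one_field(Locus.B, j + 1)): float(grid[i, j])
        for i in range(n_a)
        for j in range(n_b)
    }
    return HaplotypeTable(population=population, entries=entries, provenance="synthetic")


def random_library(rng: np.random.Generator, n_a: int, n_b: int, n_combos: int):
    """Distinct random combos over the same allele grid as the table."""
    cells = [(i + 1, j + 1) for i in range(n_a) for j in range(n_b)]
    picks = rng.choice(len(cells), size=min(n_combos, len(cells)), replace=False)
    return [
        HemiCombo(a=one_field(Locus.A, cells[k][0]), b=one_field(Locus.B, cells[k][1]))
        for k in picks
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
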