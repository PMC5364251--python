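import numpy as np
import pytest

from wecreg import FactorSpec, SimulationConfig, TwoWayCellTable, generate
from wecreg.reproduce import table4_fixture


@pytest.fixture
def table4():
    return table4_fixture()


@pytest.fixture
def table4_table(table4):
    """Published cell counts with cell means reconstructed from the
    saturated dummy parameterization."""
    return table4.table()


def random_table(rng: np.random.Generator, k: int, l: int,
                 with_means: bool = True, max_count: int = 30,
                 random_omitted: bool = True) -> TwoWayCellTable:
    """An unbalanced K x L cell table with positive counts and, optionally,
    normal cell means."""
    a_levels = tuple(f"a{i}" for i in range(k))
    b_levels = tuple(f"b{j}" for j in range(l))
    counts = {(a, b): int(rng.integers(1, max_count + 1))
              for a in a_levels for b in b_levels}
    fa = FactorSpec(
        name="A", levels=a_levels,
        counts={a: sum(counts[(a, b)] for b in b_levels) for a in a_levels},
        omitted=a_levels[rng.integers(k)] if random_omitted else a_levels[0])
    fb = FactorSpec(
        name="B", levels=b_levels,
        counts={b: sum(counts[(a, b)] for a in a_levels) for b in b_levels},
        omitted=b_levels[rng.integers(l)] if random_omitted else b_levels[0])
    means = None
    if with_means:
        means = {c: float(rng.normal(0.0, 2.0)) for c in counts}
    return TwoWayCellTable(factor_a=fa, factor_b=fb, cell_counts=counts,
                           cell_means=means)


def table_dataset(table: TwoWayCellTable, residual_sd: float = 0.0,
                  seed: int = 0):
    """Observation-level dataset realizing a cell table's counts and means."""
    cfg = SimulationConfig.from_table(table, residual_sd=residual_sd,
                                      seed=seed)
    return generate(cfg)


def cell_dot(table: TwoWayCellTable, w1: dict, w2: dict) -> float:
    """Brute-force cell-level summation oracle for observation-level dot
    products of two cell-constant columns given as cell -> weight maps."""
    return sum(table.cell_counts[c] * w1.get(c, 0.0) * w2.get(c, 0.0)
               for c in table.cells)
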