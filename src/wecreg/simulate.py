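"""Synthetic unbalanced two-factor data with known cell means.

The generator emulates the structure of unbalanced observational designs:
cell counts are fixed by design (not random), the outcome within a cell is
its configured mean plus homoskedastic normal noise, and an optional
standard-normal control variable can enter with a linear slope.  Every
estimation property of the package is testable on this output without any
external data.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .factors import Cell, Dataset, TwoWayCellTable


@dataclass(frozen=True)
class SimulationConfig:
    """Cell layout, signal, and noise for one simulated dataset.

    Parameters
    ----------
    cell_counts : mapping (levelA, levelB) -> int
        Observations per cell; all >= 1.  Counts are design, not random:
        the generated data reproduce them exactly.
    cell_means : mapping (levelA, levelB) -> float
        True outcome mean per cell, in outcome units.
    residual_sd : float
        Within-cell standard deviation of the normal noise; 0 gives
        noise-free data whose observed cell means equal the configured
        ones exactly.
    seed : int
        Seed of the single generator stream.
    control_slope : float, optional
        When set, a standard-normal control ``x`` is drawn per observation
        and ``control_slope * x`` is added to the outcome.
    """

    cell_counts: Mapping[Cell, int]
    cell_means: Mapping[Cell, float]
    residual_sd: float = 0.0
    seed: int = 0
    control_slope: float | None = None
    factor_a_name: str = "A"
    factor_b_name: str = "B"
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        counts = {tuple(c): int(n) for c, n in self.cell_counts.items()}
        means = {tuple(c): float(m) for c, m in self.cell_means.items()}
        if set(counts) != set(means):
            raise ValidationError("cell_counts and cell_means keys differ")
        if any(n < 1 for n in counts.values()):
            raise ValidationError("all cell counts must be >= 1")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        object.__setattr__(self, "cell_counts", counts)
        object.__setattr__(self, "cell_means", means)

    @property
    def cells(self) -> list[Cell]:
        """Cells in (levelA, levelB) label-sorted order — the order in
        which random draws are consumed (fixed for reproducibility)."""
        return sorted(self.cell_counts)

    @property
    def n(self) -> int:
        return sum(self.cell_counts.values())

    def to_dict(self) -> dict:
        return {"cell_counts": [[a, b, n] for (a, b), n in self.cell_counts.items()],
                "cell_means": [[a, b, m] for (a, b), m in self.cell_means.items()],
                "residual_sd": self.residual_sd, "seed": self.seed,
                "control_slope": self.control_slope,
                "factor_a_name": self.factor_a_name,
                "factor_b_name": self.factor_b_name,
                "outcome_name": self.outcome_name}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(cell_counts={(a, b): int(n) for a, b, n in d["cell_counts"]},
                   cell_means={(a, b): float(m) for a, b, m in d["cell_means"]},
                   residual_sd=float(d.get("residual_sd", 0.0)),
                   seed=int(d.get("seed", 0)),
                   control_slope=d.get("control_slope"),
                   factor_a_name=d.get("factor_a_name", "A"),
                   factor_b_name=d.get("factor_b_name", "B"),
                   outcome_name=d.get("outcome_name", "y"))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_table(cls, table: TwoWayCellTable, residual_sd: float = 0.0,
                   seed: int = 0, **kwargs) -> "SimulationConfig":
        """Use a cell table's counts and means as the true layout."""
        if table.cell_means is None:
            raise ValidationError("table has no cell means")
        occupied = table.occupied_cells
        return cls(cell_counts={c: table.cell_counts[c] for c in occupied},
                   cell_means={c: table.cell_means[c] for c in occupied},
                   residual_sd=residual_sd, seed=seed,
                   factor_a_name=table.factor_a.name,
                   factor_b_name=table.factor_b.name, **kwargs)


def generate(config: SimulationConfig) -> Dataset:
    """Draw one dataset; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    a_out, b_out, y_out, x_out = [], [], [], []
    for (a, b) in config.cells:
        n = config.cell_counts[(a, b)]
        y = np.full(n, config.cell_means[(a, b)])
        if config.residual_sd > 0:
            y = y + config.residual_sd * rng.standard_normal(n)
        if config.control_slope is not None:
            x = rng.standard_normal(n)
            y = y + config.control_slope * x
            x_out.append(x)
        a_out.extend([a] * n)
        b_out.extend([b] * n)
        y_out.append(y)
    controls = {}
    if config.control_slope is not None:
        controls["control"] = np.concatenate(x_out)
    return Dataset(outcome=np.concatenate(y_out),
                   factor_a_values=np.array(a_out, dtype=object),
                   factor_b_values=np.array(b_out, dtype=object),
                   factor_a_name=config.factor_a_name,
                   factor_b_name=config.factor_b_name,
                   outcome_name=config.outcome_name,
                   controls=controls)


def balanced_counterpart(config: SimulationConfig) -> SimulationConfig:
    """Same cell means, all counts raised to the maximum cell count.

    On the result, weighted effect coding collapses to plain effect coding
    (all weights become +/-1); idempotent on already-balanced configs.
    """
    m = max(config.cell_counts.values())
    return replace(config, cell_counts={c: m for c in config.cell_counts})
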