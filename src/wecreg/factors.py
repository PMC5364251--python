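"""Domain types for categorical factors, two-way cross-classifications, and
observation-level datasets.

A :class:`FactorSpec` records the ordered levels of one categorical
variable, the number of observations per level, and which level is omitted
from the design matrix for identifiability.  A :class:`TwoWayCellTable`
holds the K x L cross-classification of two factors -- per-cell counts and,
when an outcome is available, per-cell outcome means.  These two objects
carry all the information the weighted-effect coding weights need: the
weights are ratios of marginal counts (main effects) and of cell counts
(interactions).

Levels are always keyed by label, never by position.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateFactorError, ValidationError

logger = logging.getLogger(__name__)

Cell = tuple[str, str]

#: Recognised coding schemes, in the order they are usually compared.
SCHEMES = ("dummy", "effect", "weighted_effect")


@dataclass(frozen=True)
class FactorSpec:
    """One categorical variable: ordered levels, per-level counts, and the
    omitted (reference) level.

    Parameters
    ----------
    name : str
        Variable name; used as a prefix in design-matrix column labels.
    levels : tuple of str
        Ordered level labels, length K >= 2.
    counts : mapping level -> int
        Number of observations per level; all counts >= 1.
    omitted : str
        The reference level dropped from the design matrix.  Its
        coefficient is recoverable by completion (see ``estimation``).
    """

    name: str
    levels: tuple[str, ...]
    counts: Mapping[str, int]
    omitted: str

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise DegenerateFactorError(
                f"degenerate factor {self.name!r}: needs >= 2 levels, "
                f"got {list(self.levels)!r}")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"duplicate levels in factor {self.name!r}")
        if self.omitted not in self.levels:
            raise ValidationError(
                f"omitted level {self.omitted!r} is not a level of "
                f"factor {self.name!r}")
        if set(self.counts) != set(self.levels):
            raise ValidationError(
                f"counts keys do not match levels for factor {self.name!r}")
        for lev, n in self.counts.items():
            if int(n) < 1:
                raise ValidationError(
                    f"factor {self.name!r}, level {lev!r}: count must be "
                    f">= 1, got {n}")
        object.__setattr__(self, "counts",
                           {lev: int(self.counts[lev]) for lev in self.levels})

    @property
    def k(self) -> int:
        return len(self.levels)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def non_omitted(self) -> tuple[str, ...]:
        return tuple(lev for lev in self.levels if lev != self.omitted)

    def with_omitted(self, level: str) -> "FactorSpec":
        """Same factor with a different reference level (used by the
        refit-based completion of omitted-category estimates)."""
        return replace(self, omitted=level)

    def to_dict(self) -> dict:
        return {"name": self.name, "levels": list(self.levels),
                "counts": dict(self.counts), "omitted": self.omitted}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FactorSpec":
        return cls(name=d["name"], levels=tuple(d["levels"]),
                   counts=dict(d["counts"]), omitted=d["omitted"])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FactorSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def make_factor(name: str, values: Sequence[str],
                omitted: str = "auto") -> FactorSpec:
    """Build a :class:`FactorSpec` from observed level labels.

    Levels are ordered by first appearance.  ``omitted="auto"`` picks the
    most frequent level (ties broken by appearance order), which maximises
    the information available for completing the omitted-level estimate.
    """
    values = [str(v) for v in values]
    levels: list[str] = []
    counts: dict[str, int] = {}
    for v in values:
        if v not in counts:
            levels.append(v)
            counts[v] = 0
        counts[v] += 1
    if len(levels) < 2:
        raise DegenerateFactorError(
            f"degenerate factor {name!r}: only {len(levels)} distinct "
            f"level(s) observed")
    if omitted == "auto":
        omitted = max(levels, key=lambda lev: (counts[lev], -levels.index(lev)))
    elif omitted not in counts:
        raise ValidationError(
            f"omitted level {omitted!r} does not occur in factor {name!r}")
    return FactorSpec(name=name, levels=tuple(levels), counts=counts,
                      omitted=omitted)


@dataclass(frozen=True)
class TwoWayCellTable:
    """The K x L cross-classification of two factors.

    ``cell_counts`` maps ``(levelA, levelB)`` to a non-negative integer and
    must be marginally consistent with both factors' counts.  ``cell_means``
    optionally maps each cell to its outcome mean (in outcome units) and is
    what grouped least squares fits on.
    """

    factor_a: FactorSpec
    factor_b: FactorSpec
    cell_counts: Mapping[Cell, int]
    cell_means: Mapping[Cell, float] | None = None

    def __post_init__(self) -> None:
        expected = {(a, b) for a in self.factor_a.levels
                    for b in self.factor_b.levels}
        if set(self.cell_counts) != expected:
            raise ValidationError("cell_counts must cover every (A, B) cell")
        counts = {c: int(n) for c, n in self.cell_counts.items()}
        if any(n < 0 for n in counts.values()):
            raise ValidationError("cell counts must be non-negative")
        for a in self.factor_a.levels:
            row = sum(counts[(a, b)] for b in self.factor_b.levels)
            if row != self.factor_a.counts[a]:
                raise ValidationError(
                    f"row sum for {self.factor_a.name}={a!r} is {row}, "
                    f"expected {self.factor_a.counts[a]}")
        for b in self.factor_b.levels:
            col = sum(counts[(a, b)] for a in self.factor_a.levels)
            if col != self.factor_b.counts[b]:
                raise ValidationError(
                    f"column sum for {self.factor_b.name}={b!r} is {col}, "
                    f"expected {self.factor_b.counts[b]}")
        object.__setattr__(self, "cell_counts", counts)
        if self.cell_means is not None:
            means = {c: float(m) for c, m in self.cell_means.items()}
            missing = {c for c in expected
                       if counts[c] > 0 and c not in means}
            if missing:
                raise ValidationError(
                    f"cell_means missing for occupied cells: {sorted(missing)}")
            object.__setattr__(self, "cell_means", means)

    @property
    def cells(self) -> tuple[Cell, ...]:
        """All cells in row-major (factor A outer) declared level order."""
        return tuple((a, b) for a in self.factor_a.levels
                     for b in self.factor_b.levels)

    @property
    def occupied_cells(self) -> tuple[Cell, ...]:
        return tuple(c for c in self.cells if self.cell_counts[c] > 0)

    @property
    def total(self) -> int:
        return sum(self.cell_counts.values())

    @property
    def is_balanced(self) -> bool:
        return len(set(self.cell_counts.values())) == 1

    def with_means(self, cell_means: Mapping[Cell, float]) -> "TwoWayCellTable":
        return replace(self, cell_means=dict(cell_means))

    def with_omitted(self, omitted_a: str | None = None,
                     omitted_b: str | None = None) -> "TwoWayCellTable":
        fa = self.factor_a if omitted_a is None else self.factor_a.with_omitted(omitted_a)
        fb = self.factor_b if omitted_b is None else self.factor_b.with_omitted(omitted_b)
        return replace(self, factor_a=fa, factor_b=fb)

    def grand_mean(self) -> float:
        """Count-weighted (arithmetic sample) mean of the outcome."""
        if self.cell_means is None:
            raise ValidationError("table has no cell means")
        num = sum(self.cell_counts[c] * self.cell_means[c]
                  for c in self.occupied_cells)
        return num / self.total

    def to_dict(self) -> dict:
        d = {"factor_a": self.factor_a.to_dict(),
             "factor_b": self.factor_b.to_dict(),
             "cell_counts": [[a, b, n] for (a, b), n in self.cell_counts.items()]}
        if self.cell_means is not None:
            d["cell_means"] = [[a, b, m] for (a, b), m in self.cell_means.items()]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TwoWayCellTable":
        means = None
        if "cell_means" in d and d["cell_means"] is not None:
            means = {(a, b): float(m) for a, b, m in d["cell_means"]}
        return cls(factor_a=FactorSpec.from_dict(d["factor_a"]),
                   factor_b=FactorSpec.from_dict(d["factor_b"]),
                   cell_counts={(a, b): int(n) for a, b, n in d["cell_counts"]},
                   cell_means=means)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TwoWayCellTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Dataset:
    """Observation-level data: one outcome value and two factor labels per
    row, plus optional named numeric controls."""

    outcome: np.ndarray
    factor_a_values: np.ndarray
    factor_b_values: np.ndarray
    factor_a_name: str = "A"
    factor_b_name: str = "B"
    outcome_name: str = "y"
    controls: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float)
        a = np.asarray(self.factor_a_values, dtype=object)
        b = np.asarray(self.factor_b_values, dtype=object)
        if not (len(y) == len(a) == len(b)):
            raise ValidationError("outcome and factor value lengths differ")
        ctrl = {k: np.asarray(v, dtype=float) for k, v in self.controls.items()}
        for k, v in ctrl.items():
            if len(v) != len(y):
                raise ValidationError(f"control {k!r} length differs")
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "factor_a_values", a)
        object.__setattr__(self, "factor_b_values", b)
        object.__setattr__(self, "controls", ctrl)

    @property
    def n(self) -> int:
        return len(self.outcome)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, factor_a: str,
                       factor_b: str,
                       controls: Sequence[str] = ()) -> "Dataset":
        """Extract a dataset from a data frame.

        Rows with a missing outcome, factor label, or control value are
        dropped (listwise deletion); the number of dropped rows is logged.
        """
        cols = [outcome, factor_a, factor_b, *controls]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"columns not in data: {missing}")
        sub = df[cols]
        kept = sub.dropna()
        dropped = len(sub) - len(kept)
        if dropped:
            logger.info("listwise deletion dropped %d of %d rows",
                        dropped, len(sub))
        return cls(outcome=kept[outcome].to_numpy(dtype=float),
                   factor_a_values=kept[factor_a].astype(str).to_numpy(dtype=object),
                   factor_b_values=kept[factor_b].astype(str).to_numpy(dtype=object),
                   factor_a_name=factor_a, factor_b_name=factor_b,
                   outcome_name=outcome,
                   controls={c: kept[c].to_numpy(dtype=float) for c in controls})

    def to_dataframe(self) -> pd.DataFrame:
        d = {self.outcome_name: self.outcome,
             self.factor_a_name: self.factor_a_values,
             self.factor_b_name: self.factor_b_values}
        d.update(self.controls)
        return pd.DataFrame(d)

    @classmethod
    def read_csv(cls, path, outcome: str, factor_a: str, factor_b: str,
                 controls: Sequence[str] = ()) -> "Dataset":
        return cls.from_dataframe(pd.read_csv(path), outcome, factor_a,
                                  factor_b, controls)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def factor(self, which: str, omitted: str = "auto") -> FactorSpec:
        """Derive the :class:`FactorSpec` for factor ``"a"`` or ``"b"``."""
        if which == "a":
            return make_factor(self.factor_a_name, self.factor_a_values, omitted)
        if which == "b":
            return make_factor(self.factor_b_name, self.factor_b_values, omitted)
        raise ValidationError(f"unknown factor selector {which!r}")


def cross_tabulate(dataset: Dataset, factor_a: FactorSpec,
                   factor_b: FactorSpec) -> TwoWayCellTable:
    """Cross-classify a dataset by two factors.

    The factors must be bound to the dataset: their counts must match the
    observed marginal counts exactly (enforced by the table's invariants).
    Cell means are computed from the outcome.
    """
    observed_a = set(np.unique(dataset.factor_a_values.astype(str)))
    observed_b = set(np.unique(dataset.factor_b_values.astype(str)))
    if not observed_a <= set(factor_a.levels):
        raise ValidationError(
            f"undeclared levels in {factor_a.name!r}: "
            f"{sorted(observed_a - set(factor_a.levels))}")
    if not observed_b <= set(factor_b.levels):
        raise ValidationError(
            f"undeclared levels in {factor_b.name!r}: "
            f"{sorted(observed_b - set(factor_b.levels))}")
    counts: dict[Cell, int] = {}
    means: dict[Cell, float] = {}
    a_vals = dataset.factor_a_values.astype(str)
    b_vals = dataset.factor_b_values.astype(str)
    for a in factor_a.levels:
        in_a = a_vals == a
        for b in factor_b.levels:
            mask = in_a & (b_vals == b)
            n = int(mask.sum())
            counts[(a, b)] = n
            if n:
                means[(a, b)] = float(dataset.outcome[mask].mean())
    return TwoWayCellTable(factor_a=factor_a, factor_b=factor_b,
                           cell_counts=counts, cell_means=means)
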