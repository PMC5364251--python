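"""Design-matrix builders for dummy, effect, and weighted effect coding.

All three schemes span the same column space, so fitted values are
identical whichever is used; they differ in what the coefficients mean.

* **Dummy coding** -- 0/1 indicators; coefficients are contrasts against a
  reference category; interaction columns are products of indicators.
* **Effect coding** -- the omitted category is coded -1; coefficients are
  deviations from the *unweighted* grand mean, the natural baseline for a
  balanced design; interaction columns are again products.
* **Weighted effect coding (WEC)** -- the omitted category of a main-effect
  column for level ``k`` is coded ``-n_k / n_omitted``; coefficients are
  deviations from the count-weighted (arithmetic sample) mean, the natural
  baseline for unbalanced observational data.

WEC interaction columns are *not* products of the WEC main-effect columns.
The column for cell ``(k, l)`` (with omitted levels ``rA``, ``rB``) follows
a four-cell pattern::

    cell (k,  l)  ->  1
    cell (k,  rB) ->  -n_kl / n_{k,rB}
    cell (rA, l)  ->  -n_kl / n_{rA,l}
    cell (rA, rB) ->  +n_kl / n_{rA,rB}
    elsewhere     ->  0

With these weights every interaction column sums to zero over observations
and is exactly orthogonal to the intercept and to every WEC main-effect
column of both factors, so adding the interaction block leaves the
intercept and main effects of an identity-link fit unchanged.  When all
cell counts are equal the weights reduce to +/-1 and WEC coincides with
effect coding entrywise.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError, ZeroCellError
from .factors import SCHEMES, Cell, Dataset, FactorSpec, TwoWayCellTable

__all__ = [
    "DesignMatrix",
    "main_columns", "interaction_columns", "build_design",
    "dummy_main_columns", "effect_main_columns", "wec_main_columns",
    "dummy_interaction_columns", "effect_interaction_columns",
    "wec_interaction_columns",
    "symbolic_main_scheme", "symbolic_interaction_scheme",
]


@dataclass(frozen=True)
class DesignMatrix:
    """An observations x columns real matrix with labelled, provenance-
    tracked columns.

    ``provenance`` maps each column label to a tuple describing how it was
    built: ``("intercept",)``, ``("main", factor_name, level)``,
    ``("interaction", levelA, levelB)``, or ``("control", name)``.
    """

    values: np.ndarray
    column_labels: tuple[str, ...]
    scheme: str
    provenance: Mapping[str, tuple]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.column_labels):
            raise ValidationError("design shape does not match column labels")
        if set(self.provenance) != set(self.column_labels):
            raise ValidationError("provenance keys must match column labels")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.column_labels.index(label)]

    def hstack(self, other: "DesignMatrix") -> "DesignMatrix":
        if other.n != self.n:
            raise ValidationError("row counts differ")
        overlap = set(self.column_labels) & set(other.column_labels)
        if overlap:
            raise ValidationError(f"duplicate columns: {sorted(overlap)}")
        return DesignMatrix(
            values=np.hstack([self.values, other.values]),
            column_labels=self.column_labels + other.column_labels,
            scheme=self.scheme,
            provenance={**self.provenance, **other.provenance})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_labels))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_scheme(scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ValidationError(
            f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def _main_codes(factor: FactorSpec, scheme: str) -> dict[str, dict[str, float]]:
    """Per non-omitted level, the level -> weight map of its column."""
    _check_scheme(scheme)
    codes: dict[str, dict[str, float]] = {}
    for k in factor.non_omitted:
        if scheme == "dummy":
            codes[k] = {k: 1.0}
        elif scheme == "effect":
            codes[k] = {k: 1.0, factor.omitted: -1.0}
        else:  # weighted_effect: omitted carries -(n_k / n_omitted)
            codes[k] = {k: 1.0,
                        factor.omitted: -factor.counts[k] / factor.counts[factor.omitted]}
    return codes


def _interaction_codes(table: TwoWayCellTable,
                       scheme: str) -> dict[Cell, dict[Cell, float]]:
    """Per interaction column (k, l), the cell -> weight map."""
    _check_scheme(scheme)
    fa, fb = table.factor_a, table.factor_b
    ra, rb = fa.omitted, fb.omitted
    codes: dict[Cell, dict[Cell, float]] = {}
    if scheme in ("dummy", "effect"):
        ca = _main_codes(fa, scheme)
        cb = _main_codes(fb, scheme)
        for k in fa.non_omitted:
            for l in fb.non_omitted:
                cell_map: dict[Cell, float] = {}
                for a, wa in ca[k].items():
                    for b, wb in cb[l].items():
                        cell_map[(a, b)] = wa * wb
                codes[(k, l)] = cell_map
        return codes
    n = table.cell_counts
    for k in fa.non_omitted:
        for l in fb.non_omitted:
            referenced = [(k, l), (k, rb), (ra, l), (ra, rb)]
            for cell in referenced:
                if n[cell] < 1:
                    raise ZeroCellError(
                        f"weighted-effect interaction column ({k} x {l}) "
                        f"requires a positive count in cell "
                        f"({cell[0]}, {cell[1]}), which is empty")
            codes[(k, l)] = {
                (k, l): 1.0,
                (k, rb): -n[(k, l)] / n[(k, rb)],
                (ra, l): -n[(k, l)] / n[(ra, l)],
                (ra, rb): n[(k, l)] / n[(ra, rb)],
            }
    return codes


def main_columns(factor: FactorSpec, values: Sequence[str],
                 scheme: str) -> DesignMatrix:
    """The K-1 main-effect columns of ``factor`` under ``scheme``."""
    codes = _main_codes(factor, scheme)
    vals = np.asarray(values, dtype=object).astype(str)
    unseen = set(np.unique(vals)) - set(factor.levels)
    if unseen:
        raise ValidationError(
            f"undeclared levels in {factor.name!r}: {sorted(unseen)}")
    cols, labels, prov = [], [], {}
    for k in factor.non_omitted:
        lut = codes[k]
        cols.append(np.array([lut.get(v, 0.0) for v in vals]))
        label = f"{factor.name}={k}"
        labels.append(label)
        prov[label] = ("main", factor.name, k)
    return DesignMatrix(values=np.column_stack(cols),
                        column_labels=tuple(labels), scheme=scheme,
                        provenance=prov)


def interaction_columns(table: TwoWayCellTable, values_a: Sequence[str],
                        values_b: Sequence[str], scheme: str) -> DesignMatrix:
    """The (K-1)(L-1) two-factor interaction columns under ``scheme``."""
    codes = _interaction_codes(table, scheme)
    va = np.asarray(values_a, dtype=object).astype(str)
    vb = np.asarray(values_b, dtype=object).astype(str)
    if len(va) != len(vb):
        raise ValidationError("factor value lengths differ")
    cols, labels, prov = [], [], {}
    for k in table.factor_a.non_omitted:
        for l in table.factor_b.non_omitted:
            lut = codes[(k, l)]
            cols.append(np.array([lut.get((a, b), 0.0)
                                  for a, b in zip(va, vb)]))
            label = f"{k}×{l}"
            labels.append(label)
            prov[label] = ("interaction", k, l)
    return DesignMatrix(values=np.column_stack(cols),
                        column_labels=tuple(labels), scheme=scheme,
                        provenance=prov)


# Named builders matching the three published coding tables.

def dummy_main_columns(factor: FactorSpec, values: Sequence[str]) -> DesignMatrix:
    return main_columns(factor, values, "dummy")


def effect_main_columns(factor: FactorSpec, values: Sequence[str]) -> DesignMatrix:
    return main_columns(factor, values, "effect")


def wec_main_columns(factor: FactorSpec, values: Sequence[str]) -> DesignMatrix:
    return main_columns(factor, values, "weighted_effect")


def dummy_interaction_columns(table: TwoWayCellTable, values_a, values_b) -> DesignMatrix:
    return interaction_columns(table, values_a, values_b, "dummy")


def effect_interaction_columns(table: TwoWayCellTable, values_a, values_b) -> DesignMatrix:
    return interaction_columns(table, values_a, values_b, "effect")


def wec_interaction_columns(table: TwoWayCellTable, values_a, values_b) -> DesignMatrix:
    return interaction_columns(table, values_a, values_b, "weighted_effect")


def build_design(dataset: Dataset, table: TwoWayCellTable, scheme: str,
                 interactions: bool = False,
                 include_intercept: bool = False,
                 controls: Sequence[str] = ()) -> DesignMatrix:
    """Assemble the full design for a dataset: main effects of both
    factors, optionally the interaction block, controls, and an intercept.

    By default the weights baked into WEC columns come from the analysis
    sample's counts (via ``table``); passing a table with externally
    supplied counts (e.g. known population margins) substitutes those.
    """
    dm = main_columns(table.factor_a, dataset.factor_a_values, scheme)
    dm = dm.hstack(main_columns(table.factor_b, dataset.factor_b_values, scheme))
    if interactions:
        dm = dm.hstack(interaction_columns(
            table, dataset.factor_a_values, dataset.factor_b_values, scheme))
    for name in controls:
        if name not in dataset.controls:
            raise ValidationError(f"unknown control {name!r}")
        ctrl = DesignMatrix(values=dataset.controls[name][:, None],
                            column_labels=(name,), scheme=scheme,
                            provenance={name: ("control", name)})
        dm = dm.hstack(ctrl)
    if include_intercept:
        ones = DesignMatrix(values=np.ones((dm.n, 1)),
                            column_labels=("intercept",), scheme=scheme,
                            provenance={"intercept": ("intercept",)})
        dm = ones.hstack(dm)
    return dm


def cell_design(table: TwoWayCellTable, scheme: str,
                interactions: bool = False,
                include_intercept: bool = True) -> DesignMatrix:
    """One-row-per-occupied-cell design (all predictors are cell-constant,
    so this carries the same information as the observation-level design)."""
    cells = table.occupied_cells
    va = [a for a, _ in cells]
    vb = [b for _, b in cells]
    dm = main_columns(table.factor_a, va, scheme)
    dm = dm.hstack(main_columns(table.factor_b, vb, scheme))
    if interactions:
        dm = dm.hstack(interaction_columns(table, va, vb, scheme))
    if include_intercept:
        ones = DesignMatrix(values=np.ones((dm.n, 1)),
                            column_labels=("intercept",), scheme=scheme,
                            provenance={"intercept": ("intercept",)})
        dm = ones.hstack(dm)
    return dm


def symbolic_main_scheme(factor: FactorSpec, scheme: str) -> dict[str, dict[str, float]]:
    """Column label -> {level: weight} for audit/JSON export."""
    codes = _main_codes(factor, scheme)
    return {f"{factor.name}={k}": dict(lut) for k, lut in codes.items()}


def symbolic_interaction_scheme(table: TwoWayCellTable,
                                scheme: str) -> dict[str, dict[str, float]]:
    """Column label -> {"levelA|levelB": weight} for audit/JSON export."""
    codes = _interaction_codes(table, scheme)
    return {f"{k}×{l}": {f"{a}|{b}": w for (a, b), w in lut.items()}
            for (k, l), lut in codes.items()}


def export_symbolic_scheme(table: TwoWayCellTable, scheme: str, path) -> None:
    """Write the full symbolic coding scheme (main + interaction weight
    maps) as JSON."""
    out = {"scheme": scheme,
           "main": {**symbolic_main_scheme(table.factor_a, scheme),
                    **symbolic_main_scheme(table.factor_b, scheme)},
           "interaction": symbolic_interaction_scheme(table, scheme)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2)
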