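"""Least-squares and GLM fitting on coded designs, plus completion of the
omitted-category estimates.

Two fitting routes are provided and agree exactly (all coded predictors
are constant within cells of the cross-classification, so the coefficients
depend on the data only through cell counts and cell means):

* :func:`fit_ols_raw` -- ordinary least squares on observation-level data;
  reports standard errors and R^2.
* :func:`fit_ols_grouped` -- count-weighted least squares on the cell
  means; needs only the sufficient statistics (counts + means), so a
  published table of counts and a recoverable set of cell means suffice to
  reproduce coefficient estimates.  No standard errors (the within-cell
  variance is unknown).

:func:`complete_estimates` recovers the coefficients of the omitted
categories: the primary method refits the model with a different omitted
level, and every completed value is cross-checked against the scheme's
sum-to-zero constraint (count-weighted for weighted effect coding,
unweighted for effect coding); disagreement raises, since it can only come
from a coding bug.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import linalg as sla

from .coding import DesignMatrix, build_design, cell_design
from .errors import (CompletionError, ConvergenceError, RankDeficiencyError,
                     ValidationError)
from .factors import Cell, Dataset, FactorSpec, TwoWayCellTable, cross_tabulate

MODEL_ORDERS = ("additive", "with_interactions")

#: Absolute tolerance for the refit-vs-constraint completion cross-check.
COMPLETION_TOL = 1e-6

#: Relative rank tolerance for the collinearity check.
RANK_TOL = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Coefficients (keyed by column label) and fit diagnostics."""

    scheme: str
    model_order: str
    coefficients: Mapping[str, float]
    provenance: Mapping[str, tuple]
    factor_a: FactorSpec
    factor_b: FactorSpec
    nobs: int
    standard_errors: Mapping[str, float] | None = None
    fitted_cell_means: Mapping[Cell, float] = field(default_factory=dict)
    r_squared: float | None = None

    @property
    def intercept(self) -> float:
        return self.coefficients["intercept"]

    def main_effects(self, factor_name: str) -> dict[str, float]:
        """Fitted main-effect coefficients of one factor, keyed by level
        (omitted level absent)."""
        return {p[2]: self.coefficients[lab]
                for lab, p in self.provenance.items()
                if p[0] == "main" and p[1] == factor_name}

    def interaction_effects(self) -> dict[Cell, float]:
        """Fitted interaction coefficients keyed by (levelA, levelB)."""
        return {(p[1], p[2]): self.coefficients[lab]
                for lab, p in self.provenance.items()
                if p[0] == "interaction"}

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "model_order": self.model_order,
                "nobs": self.nobs, "r_squared": self.r_squared,
                "coefficients": dict(self.coefficients),
                "standard_errors": (dict(self.standard_errors)
                                    if self.standard_errors else None)}


@dataclass(frozen=True)
class CompletedEstimates:
    """Coefficients for *all* levels and cells, omitted ones included.

    ``main_effects[factor_name][level]`` and ``interaction_effects[cell]``
    satisfy the scheme's sum-to-zero constraints: count-weighted sums for
    weighted effect coding (over levels; over each row and each column of
    the interaction table), unweighted sums for effect coding.
    """

    intercept: float
    main_effects: Mapping[str, Mapping[str, float]]
    interaction_effects: Mapping[Cell, float] | None
    scheme: str

    def to_dict(self) -> dict:
        d = {"scheme": self.scheme, "intercept": self.intercept,
             "main_effects": {f: dict(m) for f, m in self.main_effects.items()}}
        if self.interaction_effects is not None:
            d["interaction_effects"] = [[a, b, v] for (a, b), v
                                        in self.interaction_effects.items()]
        return d


@dataclass(frozen=True)
class InvarianceReport:
    """Observed change in intercept and main effects when the interaction
    block is added to an identity-link model."""

    scheme: str
    intercept_change: float
    main_effect_changes: Mapping[str, float]

    @property
    def max_main_change(self) -> float:
        return max(abs(v) for v in self.main_effect_changes.values())

    @property
    def max_change(self) -> float:
        return max(abs(self.intercept_change), self.max_main_change)


def _check_rank(x: np.ndarray, labels: Sequence[str]) -> None:
    """QR-with-pivoting rank check; names the columns past the numerical
    rank when the design is deficient."""
    _, r, piv = sla.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        return
    rank = int(np.sum(diag > RANK_TOL * diag[0]))
    if rank < x.shape[1]:
        bad = tuple(labels[i] for i in piv[rank:])
        raise RankDeficiencyError(
            f"design is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {list(bad)}", columns=bad)


def _with_intercept(design: DesignMatrix) -> DesignMatrix:
    if "intercept" in design.column_labels:
        return design
    ones = DesignMatrix(values=np.ones((design.n, 1)),
                        column_labels=("intercept",), scheme=design.scheme,
                        provenance={"intercept": ("intercept",)})
    return ones.hstack(design)


def _model_order(design: DesignMatrix) -> str:
    kinds = {p[0] for p in design.provenance.values()}
    return "with_interactions" if "interaction" in kinds else "additive"


def fit_ols_raw(dataset: Dataset, design: DesignMatrix,
                include_intercept: bool = True) -> FitResult:
    """OLS on observation-level data; standard errors and R^2 reported."""
    if design.n != dataset.n:
        raise ValidationError("design rows do not match dataset rows")
    dm = _with_intercept(design) if include_intercept else design
    _check_rank(dm.values, dm.column_labels)
    res = sm.OLS(dataset.outcome, dm.values).fit()
    coefs = dict(zip(dm.column_labels, res.params))
    ses = dict(zip(dm.column_labels, res.bse))
    fa = _bound_factor(dataset, "a", dm)
    fb = _bound_factor(dataset, "b", dm)
    fitted = np.asarray(res.fittedvalues)
    cell_fit: dict[Cell, float] = {}
    a_vals = dataset.factor_a_values.astype(str)
    b_vals = dataset.factor_b_values.astype(str)
    for a in fa.levels:
        for b in fb.levels:
            mask = (a_vals == a) & (b_vals == b)
            if mask.any():
                cell_fit[(a, b)] = float(fitted[mask].mean())
    return FitResult(scheme=design.scheme, model_order=_model_order(dm),
                     coefficients=coefs, provenance=dict(dm.provenance),
                     factor_a=fa, factor_b=fb, nobs=dataset.n,
                     standard_errors=ses, fitted_cell_means=cell_fit,
                     r_squared=float(res.rsquared))


def _bound_factor(dataset: Dataset, which: str,
                  design: DesignMatrix) -> FactorSpec:
    # The omitted level is the unique observed level with no main-effect
    # column in the design.
    spec = dataset.factor(which, "auto")
    name = spec.name
    present = {p[2] for p in design.provenance.values()
               if p[0] == "main" and p[1] == name}
    absent = [lev for lev in spec.levels if lev not in present]
    if present and len(absent) == 1:
        return spec.with_omitted(absent[0])
    return spec


def fit_ols_grouped(table: TwoWayCellTable, scheme: str,
                    model_order: str = "additive") -> FitResult:
    """Count-weighted least squares on cell means.

    Exactly reproduces the observation-level OLS coefficients, because all
    predictors are cell-constant.  Standard errors are not reported: the
    within-cell outcome variance is not part of the sufficient statistics.
    """
    if model_order not in MODEL_ORDERS:
        raise ValidationError(
            f"model_order must be one of {MODEL_ORDERS}, got {model_order!r}")
    if table.cell_means is None:
        raise ValidationError("grouped fit requires cell means")
    dm = cell_design(table, scheme,
                     interactions=(model_order == "with_interactions"),
                     include_intercept=True)
    cells = table.occupied_cells
    y = np.array([table.cell_means[c] for c in cells])
    w = np.array([table.cell_counts[c] for c in cells], dtype=float)
    _check_rank(np.sqrt(w)[:, None] * dm.values, dm.column_labels)
    res = sm.WLS(y, dm.values, weights=w).fit()
    coefs = dict(zip(dm.column_labels, res.params))
    fitted = dm.values @ np.asarray(res.params)
    cell_fit = {c: float(v) for c, v in zip(cells, fitted)}
    return FitResult(scheme=scheme, model_order=model_order,
                     coefficients=coefs, provenance=dict(dm.provenance),
                     factor_a=table.factor_a, factor_b=table.factor_b,
                     nobs=table.total, standard_errors=None,
                     fitted_cell_means=cell_fit, r_squared=None)


def _main_constraint_gap(levels, counts, effects, scheme) -> float:
    if scheme == "weighted_effect":
        return sum(counts[k] * effects[k] for k in levels)
    return sum(effects[k] for k in levels)


def _complete_mains(orig: FitResult, refit: FitResult, factor: FactorSpec,
                    scheme: str, tol: float) -> dict[str, float]:
    known = orig.main_effects(factor.name)
    other = refit.main_effects(factor.name)
    completed = dict(known)
    completed[factor.omitted] = other[factor.omitted]
    for lev in set(known) & set(other):
        if abs(known[lev] - other[lev]) > tol:
            raise CompletionError(
                f"refit disagreement for {factor.name}={lev}: "
                f"{known[lev]!r} vs {other[lev]!r}")
    gap = _main_constraint_gap(factor.levels, factor.counts, completed, scheme)
    # The weighted constraint sums K terms of order n_k * |b|; scale the
    # tolerance accordingly.
    scale = factor.total if scheme == "weighted_effect" else factor.k
    if abs(gap) > tol * scale:
        raise CompletionError(
            f"sum-to-zero constraint violated for factor {factor.name!r}: "
            f"residual {gap}")
    return completed


def _complete_interactions(orig: FitResult, refit: FitResult,
                           table: TwoWayCellTable, scheme: str,
                           tol: float) -> dict[Cell, float]:
    fa, fb = table.factor_a, table.factor_b
    known = orig.interaction_effects()
    other = refit.interaction_effects()
    for cell in set(known) & set(other):
        if abs(known[cell] - other[cell]) > tol:
            raise CompletionError(
                f"refit disagreement for interaction {cell}: "
                f"{known[cell]!r} vs {other[cell]!r}")
    completed = {**other, **known}
    n = table.cell_counts

    def wgt(cell: Cell) -> float:
        return n[cell] if scheme == "weighted_effect" else 1.0

    # Constraint propagation: any row or column with a single missing cell
    # is resolved by its (weighted) sum-to-zero constraint.
    missing = {(a, b) for a in fa.levels for b in fb.levels} - set(completed)
    while missing:
        progressed = False
        for a in fa.levels:
            row = [(a, b) for b in fb.levels]
            gap = [c for c in row if c in missing]
            if len(gap) == 1:
                c0 = gap[0]
                s = sum(wgt(c) * completed[c] for c in row if c != c0)
                completed[c0] = -s / wgt(c0)
                missing.discard(c0)
                progressed = True
        for b in fb.levels:
            col = [(a, b) for a in fa.levels]
            gap = [c for c in col if c in missing]
            if len(gap) == 1:
                c0 = gap[0]
                s = sum(wgt(c) * completed[c] for c in col if c != c0)
                completed[c0] = -s / wgt(c0)
                missing.discard(c0)
                progressed = True
        if not progressed:
            raise CompletionError(
                f"cannot complete interaction cells {sorted(missing)}")
    scale = max(n.values()) * max(fa.k, fb.k)
    for a in fa.levels:
        gap = sum(wgt((a, b)) * completed[(a, b)] for b in fb.levels)
        if abs(gap) > tol * scale:
            raise CompletionError(
                f"interaction row constraint violated at {fa.name}={a!r}: "
                f"residual {gap}")
    for b in fb.levels:
        gap = sum(wgt((a, b)) * completed[(a, b)] for a in fa.levels)
        if abs(gap) > tol * scale:
            raise CompletionError(
                f"interaction column constraint violated at "
                f"{fb.name}={b!r}: residual {gap}")
    return completed


def complete_estimates(fit: FitResult, table: TwoWayCellTable,
                       tol: float = COMPLETION_TOL) -> CompletedEstimates:
    """Recover the omitted-category coefficients of an effect-coded or
    weighted-effect-coded fit.

    The model is refitted (grouped, on ``table``) with different omitted
    levels; the union of both fits covers every level and all but three
    interaction cells, which follow from the scheme's sum-to-zero
    constraints.  Every doubly-determined value is cross-checked at
    absolute tolerance ``tol``; disagreement raises
    :class:`~wecreg.errors.CompletionError`.
    """
    if fit.scheme not in ("effect", "weighted_effect"):
        raise ValidationError(
            "completion is defined for effect and weighted_effect schemes; "
            "dummy-coded omitted categories are fixed at zero by design")
    if any(p[0] == "control" for p in fit.provenance.values()):
        raise ValidationError("completion with control columns is not supported")
    fa, fb = fit.factor_a, fit.factor_b
    tbl = table.with_omitted(fa.omitted, fb.omitted)
    refit_tbl = tbl.with_omitted(fa.non_omitted[0], fb.non_omitted[0])
    refit = fit_ols_grouped(refit_tbl, fit.scheme, fit.model_order)
    if abs(refit.intercept - fit.intercept) > tol:
        raise CompletionError(
            f"intercept changed under refit: {fit.intercept!r} vs "
            f"{refit.intercept!r}")
    mains = {fa.name: _complete_mains(fit, refit, fa, fit.scheme, tol),
             fb.name: _complete_mains(fit, refit, fb, fit.scheme, tol)}
    inter = None
    if fit.model_order == "with_interactions":
        inter = _complete_interactions(fit, refit, tbl, fit.scheme, tol)
    return CompletedEstimates(intercept=fit.intercept, main_effects=mains,
                              interaction_effects=inter, scheme=fit.scheme)


def verify_invariance(table: TwoWayCellTable,
                      scheme: str = "weighted_effect") -> InvarianceReport:
    """Fit the additive and the interaction model and report how much the
    intercept and main effects move.

    For weighted effect coding under an identity link the interaction
    columns are exactly orthogonal to the intercept and main-effect
    columns, so the change is zero to numerical precision.
    """
    add = fit_ols_grouped(table, scheme, "additive")
    sat = fit_ols_grouped(table, scheme, "with_interactions")
    changes = {}
    for f in (table.factor_a, table.factor_b):
        ma, ms = add.main_effects(f.name), sat.main_effects(f.name)
        for lev in ma:
            changes[f"{f.name}={lev}"] = ms[lev] - ma[lev]
    return InvarianceReport(scheme=scheme,
                            intercept_change=sat.intercept - add.intercept,
                            main_effect_changes=changes)


def fit_glm(dataset: Dataset, design: DesignMatrix,
            family: str = "gaussian",
            include_intercept: bool = True) -> FitResult:
    """Maximum-likelihood GLM on the coded columns.

    ``family`` is ``"gaussian"`` (identity link; reproduces OLS) or
    ``"binomial"`` (logit link).  Under the logit link the coded effects
    relate to the *odds* p/(1-p), not to the probability itself, and the
    exact orthogonality argument for main-effect invariance does not carry
    over; use :func:`verify_invariance` to inspect the observed change.
    """
    fams = {"gaussian": sm.families.Gaussian,
            "binomial": sm.families.Binomial,
            "logit": sm.families.Binomial}
    if family not in fams:
        raise ValidationError(
            f"unknown family {family!r}; expected one of {sorted(fams)}")
    dm = _with_intercept(design) if include_intercept else design
    _check_rank(dm.values, dm.column_labels)
    model = sm.GLM(dataset.outcome, dm.values, family=fams[family]())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit()
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise ConvergenceError(f"GLM fit failed: {exc}") from exc
    sep = [w for w in caught
           if "separation" in str(w.message).lower()
           or "domain" in str(w.message).lower()]
    if sep:
        raise ConvergenceError(
            f"GLM did not identify all parameters: {sep[0].message}",
            iterations=len(getattr(res, "fit_history", {}).get("deviance", [])))
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            "IRLS failed to converge",
            iterations=len(res.fit_history.get("deviance", [])),
            history=res.fit_history)
    if family in ("binomial", "logit"):
        mu = np.asarray(res.fittedvalues)
        # probabilities numerically at 0 or 1 mean the likelihood has no
        # finite maximum (perfect separation in some cell)
        if np.any(mu > 1 - 1e-6) or np.any(mu < 1e-6):
            raise ConvergenceError(
                "no finite maximum-likelihood estimate: fitted "
                "probabilities reach 0/1 (perfect separation)",
                iterations=len(res.fit_history.get("deviance", [])),
                history=res.fit_history)
    coefs = dict(zip(dm.column_labels, res.params))
    ses = dict(zip(dm.column_labels, res.bse))
    fa = dataset.factor("a")
    fb = dataset.factor("b")
    fitted = np.asarray(res.fittedvalues)
    a_vals = dataset.factor_a_values.astype(str)
    b_vals = dataset.factor_b_values.astype(str)
    cell_fit: dict[Cell, float] = {}
    for a in fa.levels:
        for b in fb.levels:
            mask = (a_vals == a) & (b_vals == b)
            if mask.any():
                cell_fit[(a, b)] = float(fitted[mask].mean())
    return FitResult(scheme=design.scheme, model_order=_model_order(dm),
                     coefficients=coefs, provenance=dict(dm.provenance),
                     factor_a=fa, factor_b=fb, nobs=dataset.n,
                     standard_errors=ses, fitted_cell_means=cell_fit,
                     r_squared=None)


def fit_raw_from_dataset(dataset: Dataset, scheme: str,
                         model_order: str = "additive",
                         omitted_a: str = "auto", omitted_b: str = "auto",
                         controls: Sequence[str] = ()) -> FitResult:
    """Convenience: derive factors, cross-tabulate, build the design, and
    run :func:`fit_ols_raw` in one call."""
    fa = dataset.factor("a", omitted_a)
    fb = dataset.factor("b", omitted_b)
    table = cross_tabulate(dataset, fa, fb)
    dm = build_design(dataset, table, scheme,
                      interactions=(model_order == "with_interactions"),
                      controls=controls)
    fit = fit_ols_raw(dataset, dm)
    # fit_ols_raw re-derives factors with "auto"; restore the requested
    # omitted levels for downstream completion.
    return FitResult(scheme=fit.scheme, model_order=fit.model_order,
                     coefficients=fit.coefficients, provenance=fit.provenance,
                     factor_a=fa, factor_b=fb, nobs=fit.nobs,
                     standard_errors=fit.standard_errors,
                     fitted_cell_means=fit.fitted_cell_means,
                     r_squared=fit.r_squared)
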