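"""Model / Results front door, in the style of statsmodels.

:class:`TwoFactorModel` is built from observation-level data (a data
frame or :class:`~wecreg.factors.Dataset`) or from cell-level sufficient
statistics (a :class:`~wecreg.factors.TwoWayCellTable` with means);
``fit()`` returns a :class:`TwoFactorResults` carrying the estimates,
their uncertainties where available, diagnostics, and a ``summary()``
table.  Completion of omitted-category estimates, the main-effect
invariance check, and simulation from the fitted cell means hang off the
results object.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from . import estimation
from .coding import DesignMatrix, build_design, cell_design
from .errors import ValidationError
from .factors import Dataset, TwoWayCellTable, cross_tabulate
from .simulate import SimulationConfig, generate

_SCHEME_ALIASES = {"dummy": "dummy", "effect": "effect",
                   "wec": "weighted_effect",
                   "weighted_effect": "weighted_effect"}


def resolve_scheme(scheme: str) -> str:
    try:
        return _SCHEME_ALIASES[scheme]
    except KeyError:
        raise ValidationError(
            f"unknown scheme {scheme!r}; expected one of "
            f"{sorted(_SCHEME_ALIASES)}") from None


class TwoFactorModel:
    """A linear (or generalized linear) model of an outcome on two
    categorical factors under a chosen coding scheme.

    Parameters
    ----------
    dataset : Dataset, optional
        Observation-level data.  Either this or ``table`` is required.
    table : TwoWayCellTable, optional
        Cell-level sufficient statistics (counts and means).  When given
        without ``dataset``, fitting uses count-weighted least squares on
        the cell means.
    scheme : {"dummy", "effect", "wec", "weighted_effect"}
        Coding scheme for the factor columns.
    interactions : bool
        Include the (K-1)(L-1) two-factor interaction block.
    omitted_a, omitted_b : str
        Reference level per factor; ``"auto"`` picks the most frequent.
    controls : sequence of str
        Names of numeric control columns (observation-level data only).
    family : {"gaussian", "binomial"}
        Error family; ``"binomial"`` fits a logit GLM.

    Examples
    --------
    >>> model = TwoFactorModel.from_dataframe(df, outcome="bmi",
    ...     factors=("children", "age"), scheme="wec", interactions=True)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, dataset: Dataset | None = None, *,
                 table: TwoWayCellTable | None = None,
                 scheme: str = "weighted_effect", interactions: bool = False,
                 omitted_a: str = "auto", omitted_b: str = "auto",
                 controls: Sequence[str] = (), family: str = "gaussian"):
        if dataset is None and table is None:
            raise ValidationError("either dataset or table is required")
        self.dataset = dataset
        self.scheme = resolve_scheme(scheme)
        self.interactions = bool(interactions)
        self.controls = tuple(controls)
        self.family = family
        if dataset is not None:
            fa = dataset.factor("a", omitted_a)
            fb = dataset.factor("b", omitted_b)
            derived = cross_tabulate(dataset, fa, fb)
            if table is not None and table.cell_counts != derived.cell_counts:
                raise ValidationError(
                    "supplied table is inconsistent with the dataset")
            # External tables may carry e.g. population counts for the
            # coding weights; keep them if supplied.
            self.table = (table.with_omitted(fa.omitted, fb.omitted)
                          if table is not None else derived)
        else:
            if table.cell_means is None:
                raise ValidationError("cell-level fitting requires cell means")
            if omitted_a != "auto":
                table = table.with_omitted(omitted_a=omitted_a)
            if omitted_b != "auto":
                table = table.with_omitted(omitted_b=omitted_b)
            if controls:
                raise ValidationError(
                    "controls require observation-level data")
            self.table = table
        self.model_order = ("with_interactions" if self.interactions
                            else "additive")

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       factors: tuple[str, str],
                       controls: Sequence[str] = (),
                       **kwargs) -> "TwoFactorModel":
        ds = Dataset.from_dataframe(df, outcome, factors[0], factors[1],
                                    controls)
        return cls(ds, controls=controls, **kwargs)

    @classmethod
    def from_cell_table(cls, table: TwoWayCellTable,
                        **kwargs) -> "TwoFactorModel":
        return cls(table=table, **kwargs)

    # ------------------------------------------------------------------
    @property
    def design(self) -> DesignMatrix:
        """The design matrix actually fitted (intercept first)."""
        if self.dataset is not None:
            dm = build_design(self.dataset, self.table, self.scheme,
                              interactions=self.interactions,
                              controls=self.controls)
            return estimation._with_intercept(dm)
        return cell_design(self.table, self.scheme,
                           interactions=self.interactions)

    def fit(self) -> "TwoFactorResults":
        if self.dataset is not None:
            dm = build_design(self.dataset, self.table, self.scheme,
                              interactions=self.interactions,
                              controls=self.controls)
            if self.family == "gaussian":
                fit = estimation.fit_ols_raw(self.dataset, dm)
            else:
                fit = estimation.fit_glm(self.dataset, dm, self.family)
            fit = estimation.FitResult(
                scheme=fit.scheme, model_order=fit.model_order,
                coefficients=fit.coefficients, provenance=fit.provenance,
                factor_a=self.table.factor_a, factor_b=self.table.factor_b,
                nobs=fit.nobs, standard_errors=fit.standard_errors,
                fitted_cell_means=fit.fitted_cell_means,
                r_squared=fit.r_squared)
        else:
            if self.family != "gaussian":
                raise ValidationError(
                    "cell-level fitting supports the gaussian family only")
            fit = estimation.fit_ols_grouped(self.table, self.scheme,
                                             self.model_order)
        return TwoFactorResults(self, fit)


class TwoFactorResults:
    """Fitted coefficients, uncertainties, and diagnostics."""

    def __init__(self, model: TwoFactorModel, fit: estimation.FitResult):
        self.model = model
        self._fit = fit

    # -- statsmodels-flavoured accessors -------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(dict(self._fit.coefficients), name="coef")

    @property
    def bse(self) -> pd.Series | None:
        if self._fit.standard_errors is None:
            return None
        return pd.Series(dict(self._fit.standard_errors), name="std err")

    @property
    def rsquared(self) -> float | None:
        return self._fit.r_squared

    @property
    def nobs(self) -> int:
        return self._fit.nobs

    @property
    def scheme(self) -> str:
        return self._fit.scheme

    @property
    def fitted_cell_means(self) -> dict:
        return dict(self._fit.fitted_cell_means)

    @property
    def fittedvalues(self) -> np.ndarray:
        design = self.model.design
        beta = np.array([self._fit.coefficients[lab]
                         for lab in design.column_labels])
        return design.values @ beta

    @property
    def fit_result(self) -> estimation.FitResult:
        """The underlying :class:`~wecreg.estimation.FitResult`."""
        return self._fit

    # -- completion / invariance ----------------------------------------
    def complete_estimates(self) -> estimation.CompletedEstimates:
        """Coefficients for every level and cell, omitted ones included."""
        return estimation.complete_estimates(self._fit, self.model.table)

    def verify_invariance(self) -> estimation.InvarianceReport:
        """How much the intercept and main effects move when the
        interaction block is added (zero, to numerical precision, for
        weighted effect coding under an identity link)."""
        return estimation.verify_invariance(self.model.table, self.scheme)

    # -- simulation ------------------------------------------------------
    def simulate(self, residual_sd: float, seed: int = 0) -> Dataset:
        """Generate a synthetic dataset whose true cell means are this
        fit's fitted cell means, with the observed cell counts."""
        table = self.model.table.with_means(self._fit.fitted_cell_means)
        return generate(SimulationConfig.from_table(
            table, residual_sd=residual_sd, seed=seed))

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        fit = self._fit
        lines = []
        title = "Two-factor categorical model"
        lines.append(title)
        lines.append("=" * 64)
        lines.append(f"Scheme:       {fit.scheme:<20} Model: {fit.model_order}")
        lines.append(f"Family:       {self.model.family:<20} N:     {fit.nobs}")
        if fit.r_squared is not None:
            lines.append(f"R-squared:    {fit.r_squared:.4f}")
        lines.append("-" * 64)
        has_se = fit.standard_errors is not None
        head = f"{'term':<28}{'coef':>12}"
        if has_se:
            head += f"{'std err':>12}{'t':>10}"
        lines.append(head)
        lines.append("-" * 64)
        for lab in fit.coefficients:
            row = f"{lab:<28}{fit.coefficients[lab]:>12.6g}"
            if has_se:
                se = fit.standard_errors[lab]
                t = fit.coefficients[lab] / se if se > 0 else float("nan")
                row += f"{se:>12.6g}{t:>10.3f}"
            lines.append(row)
        lines.append("=" * 64)
        if fit.scheme == "weighted_effect":
            lines.append("Main effects are deviations from the count-weighted "
                         "sample mean;")
            lines.append("interaction effects are orthogonal add-ons to the "
                         "additive model.")
        if self.model.family != "gaussian":
            lines.append("Logit family: effects relate to the odds p/(1-p).")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<TwoFactorResults scheme={self._fit.scheme} "
                f"model={self._fit.model_order} nobs={self._fit.nobs}>")
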