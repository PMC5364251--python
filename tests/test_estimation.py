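import numpy as np
import pytest

from wecreg import (CompletionError, ConvergenceError, RankDeficiencyError,
                    ValidationError, build_design, complete_estimates,
                    cross_tabulate, fit_glm, fit_ols_grouped, fit_ols_raw,
                    verify_invariance, wec_main_columns)
from wecreg.estimation import fit_raw_from_dataset

from conftest import random_table, table_dataset


def _fit_both(table, scheme, model_order, seed=0, sd=1.5):
    ds = table_dataset(table, residual_sd=sd, seed=seed)
    raw = fit_raw_from_dataset(ds, scheme, model_order,
                               omitted_a=table.factor_a.omitted,
                               omitted_b=table.factor_b.omitted)
    observed = cross_tabulate(ds, table.factor_a, table.factor_b)
    grouped = fit_ols_grouped(observed, scheme, model_order)
    return ds, raw, grouped


@pytest.mark.parametrize("scheme", ["dummy", "effect", "weighted_effect"])
@pytest.mark.parametrize("model_order", ["additive", "with_interactions"])
def test_grouped_equals_raw(scheme, model_order):
    """Count-weighted least squares on cell means reproduces the
    observation-level OLS coefficients (sufficient-statistic identity)."""
    rng = np.random.default_rng(3)
    table = random_table(rng, 3, 4)
    _, raw, grouped = _fit_both(table, scheme, model_order, seed=11)
    for lab, val in grouped.coefficients.items():
        assert raw.coefficients[lab] == pytest.approx(val, abs=1e-8)


def test_saturated_dummy_intercept_is_reference_cell_mean():
    rng = np.random.default_rng(5)
    table = random_table(rng, 3, 3)
    ds, raw, _ = _fit_both(table, "dummy", "with_interactions", sd=0.0)
    ref = (table.factor_a.omitted, table.factor_b.omitted)
    assert raw.coefficients["intercept"] == \
        pytest.approx(table.cell_means[ref], abs=1e-10)


def test_zero_noise_r_squared_is_one():
    rng = np.random.default_rng(6)
    table = random_table(rng, 2, 3)
    ds, raw, _ = _fit_both(table, "weighted_effect", "with_interactions",
                           sd=0.0)
    assert raw.r_squared == pytest.approx(1.0, abs=1e-12)


def test_zero_noise_saturated_fit_recovers_cell_means_exactly():
    rng = np.random.default_rng(7)
    table = random_table(rng, 3, 2)
    for scheme in ("dummy", "effect", "weighted_effect"):
        _, raw, grouped = _fit_both(table, scheme, "with_interactions",
                                    sd=0.0)
        for cell, mean in table.cell_means.items():
            assert raw.fitted_cell_means[cell] == pytest.approx(mean, abs=1e-9)
            assert grouped.fitted_cell_means[cell] == \
                pytest.approx(mean, abs=1e-9)


def test_fitted_values_agree_across_schemes():
    """All three schemes span the same column space, so fitted values and
    R^2 coincide for a fixed model order."""
    rng = np.random.default_rng(8)
    table = random_table(rng, 3, 3)
    for model_order in ("additive", "with_interactions"):
        fits = [_fit_both(table, s, model_order, seed=2)[1]
                for s in ("dummy", "effect", "weighted_effect")]
        for other in fits[1:]:
            for cell in fits[0].fitted_cell_means:
                assert other.fitted_cell_means[cell] == \
                    pytest.approx(fits[0].fitted_cell_means[cell], abs=1e-8)
            assert other.r_squared == pytest.approx(fits[0].r_squared,
                                                    abs=1e-8)


def test_single_factor_wec_closed_form():
    """With one weighted-effect-coded factor, each coefficient is that
    level's outcome mean minus the count-weighted grand mean."""
    rng = np.random.default_rng(9)
    table = random_table(rng, 4, 2)
    ds = table_dataset(table, residual_sd=1.0, seed=4)
    fa = ds.factor("a", table.factor_a.omitted)
    dm = wec_main_columns(fa, ds.factor_a_values)
    fit = fit_ols_raw(ds, dm)
    grand = float(ds.outcome.mean())
    a_vals = ds.factor_a_values.astype(str)
    for lev in fa.non_omitted:
        expected = float(ds.outcome[a_vals == lev].mean()) - grand
        assert fit.coefficients[f"A={lev}"] == pytest.approx(expected,
                                                             abs=1e-8)
    assert fit.coefficients["intercept"] == pytest.approx(grand, abs=1e-8)


class TestCompletion:
    def test_published_counterpart_example(self, table4_table):
        """Childless -0.61 with counts 1060/2254 completes to +0.29 for
        the with-children reference under weighted effect coding."""
        fit = fit_ols_grouped(table4_table, "weighted_effect", "additive")
        done = complete_estimates(fit, table4_table)
        assert done.main_effects["children"]["childless"] == \
            pytest.approx(-0.61, abs=0.03)
        assert done.main_effects["children"]["with children"] == \
            pytest.approx(0.29, abs=0.03)

    def test_effect_scheme_is_negation_for_two_levels(self, table4_table):
        fit = fit_ols_grouped(table4_table, "effect", "additive")
        done = complete_estimates(fit, table4_table)
        c = done.main_effects["children"]
        assert c["with children"] == pytest.approx(-c["childless"], abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("scheme", ["effect", "weighted_effect"])
    def test_sum_to_zero_constraints(self, seed, scheme):
        """Completed main effects and interaction effects satisfy the
        scheme's sum-to-zero constraints: count-weighted for weighted
        effect coding, unweighted for effect coding."""
        rng = np.random.default_rng(seed)
        table = random_table(rng, int(rng.integers(2, 5)),
                             int(rng.integers(2, 5)))
        fit = fit_ols_grouped(table, scheme, "with_interactions")
        done = complete_estimates(fit, table)
        for f in (table.factor_a, table.factor_b):
            effs = done.main_effects[f.name]
            if scheme == "weighted_effect":
                s = sum(f.counts[k] * effs[k] for k in f.levels) / f.total
            else:
                s = sum(effs.values())
            assert s == pytest.approx(0, abs=1e-8)
        n = table.cell_counts

        def w(c):
            return n[c] if scheme == "weighted_effect" else 1.0

        for a in table.factor_a.levels:
            s = sum(w((a, b)) * done.interaction_effects[(a, b)]
                    for b in table.factor_b.levels)
            assert s / max(table.total, 1) == pytest.approx(0, abs=1e-8)
        for b in table.factor_b.levels:
            s = sum(w((a, b)) * done.interaction_effects[(a, b)]
                    for a in table.factor_a.levels)
            assert s / max(table.total, 1) == pytest.approx(0, abs=1e-8)

    def test_saturated_identity(self):
        """The completed weighted-effect interaction for cell (k, l) is
        the cell mean minus (intercept + main_k + main_l) of the additive
        fit."""
        rng = np.random.default_rng(12)
        table = random_table(rng, 3, 3)
        add = fit_ols_grouped(table, "weighted_effect", "additive")
        add_done = complete_estimates(add, table)
        sat = fit_ols_grouped(table, "weighted_effect", "with_interactions")
        sat_done = complete_estimates(sat, table)
        ma = add_done.main_effects[table.factor_a.name]
        mb = add_done.main_effects[table.factor_b.name]
        for (a, b), eff in sat_done.interaction_effects.items():
            expected = table.cell_means[(a, b)] - (
                add_done.intercept + ma[a] + mb[b])
            assert eff == pytest.approx(expected, abs=1e-8)

    def test_completion_rejects_dummy_scheme(self, table4_table):
        fit = fit_ols_grouped(table4_table, "dummy", "additive")
        with pytest.raises(ValidationError):
            complete_estimates(fit, table4_table)


class TestInvariance:
    def test_published_table_invariance(self, table4_table):
        rep = verify_invariance(table4_table, "weighted_effect")
        assert rep.max_change < 1e-8

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_random_unbalanced_invariance(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, int(rng.integers(2, 5)),
                             int(rng.integers(2, 5)))
        rep = verify_invariance(table, "weighted_effect")
        assert rep.max_change < 1e-8

    def test_balanced_effect_scheme_invariance(self):
        """On balanced tables the plain effect columns are orthogonal too,
        so the same invariance holds for effect coding."""
        from wecreg import FactorSpec, TwoWayCellTable
        rng = np.random.default_rng(2)
        fa = FactorSpec("A", ("a", "b"), {"a": 6, "b": 6}, "a")
        fb = FactorSpec("B", ("x", "y", "z"), {"x": 4, "y": 4, "z": 4}, "x")
        counts = {(a, b): 2 for a in fa.levels for b in fb.levels}
        table = TwoWayCellTable(fa, fb, counts,
                                {c: float(rng.normal()) for c in counts})
        rep = verify_invariance(table, "effect")
        assert rep.max_change < 1e-8

    def test_effect_scheme_not_invariant_when_unbalanced(self, table4_table):
        rep = verify_invariance(table4_table, "effect")
        assert rep.max_change > 0.01


class TestGLM:
    def test_gaussian_family_reproduces_ols(self):
        rng = np.random.default_rng(13)
        table = random_table(rng, 2, 3)
        ds = table_dataset(table, residual_sd=1.0, seed=3)
        dm = build_design(ds, table, "weighted_effect", interactions=True)
        ols = fit_ols_raw(ds, dm)
        glm = fit_glm(ds, dm, "gaussian")
        for lab, val in ols.coefficients.items():
            assert glm.coefficients[lab] == pytest.approx(val, abs=1e-8)

    def test_saturated_logit_recovers_cell_proportions(self):
        """A saturated logit's fitted probabilities equal the observed
        cell proportions."""
        from wecreg import FactorSpec, TwoWayCellTable
        fa = FactorSpec("A", ("a", "b"), {"a": 80, "b": 100}, "a")
        fb = FactorSpec("B", ("x", "y"), {"x": 90, "y": 90}, "x")
        counts = {("a", "x"): 30, ("a", "y"): 50,
                  ("b", "x"): 60, ("b", "y"): 40}
        table = TwoWayCellTable(fa, fb, counts,
                                {c: 0.0 for c in counts})
        ds = table_dataset(table, seed=0)
        probs = {c: p for c, p in zip(table.cells, (0.3, 0.6, 0.5, 0.4))}
        a_vals = ds.factor_a_values.astype(str)
        b_vals = ds.factor_b_values.astype(str)
        y = np.zeros(ds.n)
        for cell, p in probs.items():
            mask = (a_vals == cell[0]) & (b_vals == cell[1])
            k = int(round(p * mask.sum()))
            idx = np.where(mask)[0]
            y[idx[:k]] = 1.0
        from wecreg import Dataset
        binary = Dataset(outcome=y, factor_a_values=ds.factor_a_values,
                         factor_b_values=ds.factor_b_values)
        dm = build_design(binary, table, "weighted_effect",
                          interactions=True)
        fit = fit_glm(binary, dm, "binomial")
        observed = cross_tabulate(binary, table.factor_a, table.factor_b)
        for cell in table.cells:
            assert fit.fitted_cell_means[cell] == \
                pytest.approx(observed.cell_means[cell], abs=1e-6)

    def test_separated_cell_raises(self):
        """A cell whose outcomes are all 1 has no finite saturated-logit
        estimate."""
        rng = np.random.default_rng(15)
        table = random_table(rng, 2, 2, with_means=False, max_count=40)
        ds = table_dataset(table.with_means({c: 0.0 for c in table.cells}))
        a_vals = ds.factor_a_values.astype(str)
        y = rng.integers(0, 2, ds.n).astype(float)
        y[a_vals == table.factor_a.levels[0]] = 1.0
        from wecreg import Dataset
        binary = Dataset(outcome=y, factor_a_values=ds.factor_a_values,
                         factor_b_values=ds.factor_b_values)
        dm = build_design(binary, table, "weighted_effect",
                          interactions=True)
        with pytest.raises(ConvergenceError):
            fit_glm(binary, dm, "binomial")


def test_rank_deficiency_names_columns():
    rng = np.random.default_rng(16)
    table = random_table(rng, 2, 2)
    ds = table_dataset(table)
    dm = build_design(ds, table, "dummy", interactions=False)
    dup = dm.hstack(type(dm)(values=dm.values[:, :1],
                             column_labels=("dup",), scheme="dummy",
                             provenance={"dup": ("control", "dup")}))
    with pytest.raises(RankDeficiencyError) as err:
        fit_ols_raw(ds, dup)
    assert err.value.columns


def test_grouped_requires_cell_means():
    rng = np.random.default_rng(17)
    table = random_table(rng, 2, 2, with_means=False)
    with pytest.raises(ValidationError):
        fit_ols_grouped(table, "effect", "additive")
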