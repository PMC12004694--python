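"""Model battery: designs, fits, closed-form contrasts, equivalences."""

import numpy as np
import pandas as pd
import pytest

import codasub as cs
from codasub.models import FAMILIES, ModelSpec, build_design
from codasub.truth import SCENARIOS, SubstitutionQuery


def query(scenario, delta, start):
    scen = SCENARIOS[scenario]
    return SubstitutionQuery(scen.exposure, scen.reference, delta, start)


class TestBuildDesign:
    def test_linear_leave_one_out_columns(self, fixed_data):
        design = build_design(ModelSpec("1A"), fixed_data)
        assert list(design.columns) == ["MVPA", "SB", "Sleep"]  # no LPA, no total

    def test_log2_all_components_columns(self, variable_data):
        design = build_design(ModelSpec("2Cprime"), variable_data)
        assert list(design.columns) == [
            "log2_Carbs", "log2_Fat", "log2_Alcohol", "log2_Protein",
        ]
        assert design["log2_Carbs"].to_numpy() == pytest.approx(
            np.log2(variable_data["Carbs"].to_numpy())
        )

    def test_ratio_design_divides_by_constant_for_fixed_total(self, fixed_data):
        design = build_design(ModelSpec("1B"), fixed_data)
        assert design["MVPA_over_Total"].to_numpy() == pytest.approx(
            (fixed_data["MVPA"] / 1440.0).to_numpy()
        )

    def test_nutrient_density_uses_per_row_total(self, variable_data):
        design = build_design(ModelSpec("2B"), variable_data)
        assert design["Carbs_over_Total"].to_numpy() == pytest.approx(
            (variable_data["Carbs"] / variable_data["Total"]).to_numpy()
        )

    def test_log2_rejects_nonpositive(self):
        bad = pd.DataFrame(
            {"Carbs": [100.0, -1.0], "Fat": [1, 1], "Alcohol": [1, 1], "Protein": [1, 1]}
        )
        with pytest.raises(ValueError, match="Carbs"):
            build_design(ModelSpec("2Cprime"), bad)


class TestFit:
    def test_noiseless_linear_truth_recovered_exactly(self, fixed_data, fixed_truths):
        spec = fixed_truths["linear"]
        y = spec.linear_predictor(fixed_data)  # no residual noise
        fitted = cs.fit(ModelSpec("1A"), fixed_data, y)
        assert fitted.params["MVPA"] == pytest.approx(spec.coefficients["MVPA"], abs=1e-8)
        assert fitted.params["SB"] == pytest.approx(spec.coefficients["SB"], abs=1e-8)

    def test_ilr_regression_recovers_truth_at_large_n(self, variable_truths):
        spec = variable_truths["ilr"]
        data = cs.simulate_variable_total(n=20_000, seed=31)
        y = cs.simulate_outcome(data, spec, seed=32)
        fitted = cs.fit(ModelSpec("2E"), data, y)
        for j in (1, 2, 3):
            se = 3 * fitted.ols_result.bse[j]
            assert abs(fitted.params[f"z{j}"] - spec.coefficients[f"z{j}"]) < se

    def test_too_few_rows_rejected(self, fixed_data):
        with pytest.raises(ValueError):
            cs.fit(ModelSpec("1A"), fixed_data.head(3), np.zeros(3))


class TestSubstitutionContrasts:
    def test_fixed_total_ratio_and_linear_models_equivalent(self, fixed_data, fixed_truths):
        y = cs.simulate_outcome(fixed_data, fixed_truths["log2"], seed=6)
        fa = cs.fit(ModelSpec("1A"), fixed_data, y)
        fb = cs.fit(ModelSpec("1B"), fixed_data, y)
        start = fixed_truths["log2"].start
        for delta in (1.0, 10.0, -5.0):
            q = query("fixed", delta, start)
            assert cs.estimate_substitution(fa, q) == pytest.approx(
                cs.estimate_substitution(fb, q), abs=1e-8
            )

    def test_closed_form_contrasts_all_parametric_families(
        self, fixed_data, variable_data, fixed_truths, variable_truths, rng
    ):
        """Prediction contrasts equal hand-derived coefficient expressions."""
        y_f = rng.normal(5.5, 1.0, len(fixed_data))
        y_v = rng.normal(5.5, 1.0, len(variable_data))
        start_f = fixed_truths["linear"].start
        start_v = variable_truths["linear"].start

        def check(family, data, y, start, delta, expected_fn):
            fitted = cs.fit(ModelSpec(family), data, y)
            got = cs.estimate_substitution(
                fitted, query(FAMILIES[family].scenario, delta, start)
            )
            assert got == pytest.approx(expected_fn(fitted.params), abs=1e-10), family

        m, l = start_f["MVPA"], start_f["LPA"]
        check("1A", fixed_data, y_f, start_f, 10.0, lambda p: 10.0 * p["MVPA"])
        check("1B", fixed_data, y_f, start_f, 10.0,
              lambda p: p["MVPA_over_Total"] * 10.0 / 1440.0)
        check("1C", fixed_data, y_f, start_f, 10.0,
              lambda p: p["log2_MVPA"] * (np.log2(m + 10) - np.log2(m)))

        c, pr, tot = start_v["Carbs"], start_v["Protein"], start_v.total
        check("2A", variable_data, y_v, start_v, 100.0, lambda p: 100.0 * p["Carbs"])
        check("2B", variable_data, y_v, start_v, 100.0,
              lambda p: p["Carbs_over_Total"] * 100.0 / tot)
        check("2Bprime", variable_data, y_v, start_v, 100.0,
              lambda p: p["Carbs_over_Total"] * 100.0 / tot)
        check("2C", variable_data, y_v, start_v, 100.0,
              lambda p: p["log2_Carbs"] * (np.log2(c + 100) - np.log2(c)))
        check("2Cprime", variable_data, y_v, start_v, 100.0,
              lambda p: p["log2_Carbs"] * (np.log2(c + 100) - np.log2(c))
              + p["log2_Protein"] * (np.log2(pr - 100) - np.log2(pr)))

        # ILR families: contrast equals coefficient . (z(end) - z(start))
        for family, start, scenario, delta in (
            ("1E", start_f, "fixed", 10.0),
            ("2E", start_v, "variable", 100.0),
        ):
            data, y = (fixed_data, y_f) if scenario == "fixed" else (variable_data, y_v)
            fitted = cs.fit(ModelSpec(family), data, y)
            scen = SCENARIOS[scenario]
            q = query(scenario, delta, start)
            dz = cs.ilr_pivot(q.endpoint(), scen.ilr_order) - cs.ilr_pivot(
                start, scen.ilr_order
            )
            expected = sum(
                fitted.params[f"z{j+1}"] * dz[j] for j in range(3)
            )
            assert cs.estimate_substitution(fitted, q) == pytest.approx(
                expected, abs=1e-10
            )

    def test_ilr_model_with_truth_coefficients_returns_true_effect(self, variable_truths):
        """A 2E fit forced to the ILR truth's coefficients reproduces it."""
        spec = variable_truths["ilr"]
        data = cs.simulate_variable_total(n=500, seed=17)
        y = cs.simulate_outcome(data, spec, seed=18)
        fitted = cs.fit(ModelSpec("2E"), data, y)
        forced = [spec.intercept] + [spec.coefficients[f"z{j}"] for j in (1, 2, 3)]
        fitted.ols_result.params = pd.Series(forced, index=["const", "z1", "z2", "z3"])
        fitted.ols_result._results.params = np.asarray(forced)
        for delta in (1.0, 100.0):
            q = query("variable", delta, spec.start)
            assert cs.estimate_substitution(fitted, q) == pytest.approx(
                cs.true_effect(spec, q), abs=1e-10
            )

    def test_nonlinear_estimates_depend_on_start_point(self, fixed_data, fixed_truths):
        y = cs.simulate_outcome(fixed_data, fixed_truths["log2"], seed=21)
        fitted = cs.fit(ModelSpec("1C"), fixed_data, y)
        other = cs.close([40.0, 541.0, 564.0, 295.0], ["MVPA", "SB", "Sleep", "LPA"])
        e1 = cs.estimate_substitution(fitted, query("fixed", 10.0, fixed_truths["log2"].start))
        e2 = cs.estimate_substitution(fitted, query("fixed", 10.0, other))
        assert abs(e1 - e2) > 1e-4


class TestGamBasisSelection:
    def test_single_candidate_returned(self, variable_data, variable_truths):
        y = cs.simulate_outcome(variable_data, variable_truths["linear"], seed=8)
        assert cs.select_gam_basis(ModelSpec("2Dprime"), variable_data, y, [5]) == 5

    def test_selection_deterministic(self, variable_data, variable_truths):
        y = cs.simulate_outcome(variable_data, variable_truths["log2"], seed=8)
        k1 = cs.select_gam_basis(ModelSpec("2Dprime"), variable_data, y)
        k2 = cs.select_gam_basis(ModelSpec("2Dprime"), variable_data, y)
        assert k1 == k2

    def test_linear_truth_prefers_smallest_basis(self, variable_truths):
        # AIC should not reward unneeded wiggliness under a linear truth
        data = cs.simulate_variable_total(n=1000, seed=44)
        y = cs.simulate_outcome(data, variable_truths["linear"], seed=45)
        assert cs.select_gam_basis(ModelSpec("2D"), data, y) == 5

    def test_non_gam_family_rejected(self, variable_data):
        with pytest.raises(ValueError):
            cs.select_gam_basis(ModelSpec("2A"), variable_data, np.zeros(len(variable_data)))
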