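"""Truth mechanisms: coefficient solving, calibration, closed-form effects."""

import numpy as np
import pytest
from scipy.optimize import brentq

import codasub as cs
from codasub.composition import close, reallocate
from codasub.truth import (
    DEFAULT_BIG_EFFECTS,
    SCENARIOS,
    SubstitutionQuery,
    TruthSpec,
    solve_focal_coefficients,
    solve_twopoint_coefficients,
)

START_FIXED = close([20.17, 541.0, 564.0, 308.61], ["MVPA", "SB", "Sleep", "LPA"])
START_VARIABLE = close([927.12, 600.0, 100.0, 280.28], ["Carbs", "Fat", "Alcohol", "Protein"])


def effect(spec, delta):
    scen = SCENARIOS[spec.scenario]
    return cs.true_effect(
        spec, SubstitutionQuery(scen.exposure, scen.reference, delta, spec.start)
    )


class TestSolver:
    def test_linear_fixed_focal_is_unit_effect(self):
        coefs = solve_focal_coefficients("linear", "fixed", START_FIXED, -0.020)
        assert coefs["MVPA"] == pytest.approx(-0.020, abs=1e-12)

    def test_log2_fixed_focal_matches_independent_root_finder(self):
        coefs = solve_focal_coefficients("log2", "fixed", START_FIXED, -0.020)
        # independent oracle: root of g1 * (log2(21.17) - log2(20.17)) + 0.020
        oracle = brentq(
            lambda g1: g1 * (np.log2(21.17) - np.log2(20.17)) + 0.020, -10, 10,
            xtol=1e-14,
        )
        assert coefs["MVPA"] == pytest.approx(oracle, abs=1e-10)
        assert coefs["MVPA"] == pytest.approx(-0.2865, abs=5e-4)

    def test_zero_unit_effect_gives_zero_focal(self):
        coefs = solve_focal_coefficients(
            "linear", "fixed", START_FIXED, 0.0, presets={"SB": 0.0, "Sleep": 0.0}
        )
        assert coefs["MVPA"] == 0.0

    @pytest.mark.parametrize("kind", ["linear", "log2", "ilr"])
    @pytest.mark.parametrize("scenario", ["fixed", "variable"])
    def test_solved_spec_reproduces_unit_effect(self, kind, scenario):
        start = START_FIXED if scenario == "fixed" else START_VARIABLE
        coefs = solve_focal_coefficients(kind, scenario, start)
        spec = TruthSpec(kind, scenario, coefs, 0.0, 0.5, start)
        assert effect(spec, 1.0) == pytest.approx(
            SCENARIOS[scenario].unit_effect, abs=1e-10
        )

    @pytest.mark.parametrize("kind,scenario", list(DEFAULT_BIG_EFFECTS))
    def test_twopoint_solver_hits_both_targets(self, kind, scenario):
        start = START_FIXED if scenario == "fixed" else START_VARIABLE
        coefs = solve_twopoint_coefficients(kind, scenario, start)
        spec = TruthSpec(kind, scenario, coefs, 0.0, 0.5, start)
        scen = SCENARIOS[scenario]
        assert effect(spec, 1.0) == pytest.approx(scen.unit_effect, abs=1e-10)
        assert effect(spec, scen.big_delta) == pytest.approx(
            DEFAULT_BIG_EFFECTS[(kind, scenario)], abs=1e-10
        )


class TestTrueEffect:
    def test_linear_fixed_ten_minutes(self):
        coefs = solve_focal_coefficients("linear", "fixed", START_FIXED)
        spec = TruthSpec("linear", "fixed", coefs, 0.0, 0.5, START_FIXED)
        assert effect(spec, 10.0) == pytest.approx(-0.200, abs=1e-12)

    def test_log2_fixed_ten_minutes_to_3dp(self):
        coefs = solve_focal_coefficients("log2", "fixed", START_FIXED)
        spec = TruthSpec("log2", "fixed", coefs, 0.0, 0.5, START_FIXED)
        assert round(effect(spec, 10.0), 3) == -0.166

    def test_linear_variable_hundred_kcal(self):
        coefs = solve_focal_coefficients("linear", "variable", START_VARIABLE)
        spec = TruthSpec("linear", "variable", coefs, 0.0, 0.5, START_VARIABLE)
        assert effect(spec, 100.0) == pytest.approx(0.400, abs=1e-12)

    def test_zero_delta_zero_effect(self, fixed_truths):
        for spec in fixed_truths.values():
            assert effect(spec, 0.0) == 0.0

    def test_linear_truths_proportional_in_delta(self, fixed_truths, variable_truths):
        for spec, d in ((fixed_truths["linear"], 10), (variable_truths["linear"], 100)):
            assert effect(spec, d) == pytest.approx(d * effect(spec, 1.0), rel=1e-9)

    def test_nonlinear_truths_not_proportional(self, fixed_truths, variable_truths):
        for truths, d in ((fixed_truths, 10.0), (variable_truths, 100.0)):
            for kind in ("log2", "ilr"):
                spec = truths[kind]
                assert abs(effect(spec, d)) != pytest.approx(
                    d * abs(effect(spec, 1.0)), rel=1e-4
                )
        # diminishing returns: the log2 10-min effect is smaller than 10x 1-min
        assert abs(effect(fixed_truths["log2"], 10.0)) < 10 * abs(
            effect(fixed_truths["log2"], 1.0)
        )

    def test_cross_mechanism_unit_effects_agree(self, fixed_truths, variable_truths):
        for truths, target in ((fixed_truths, -0.020), (variable_truths, 0.004)):
            for spec in truths.values():
                assert effect(spec, 1.0) == pytest.approx(target, abs=1e-9)

    def test_brute_force_formula_oracle(self, rng):
        """Rebuild each mechanism's formula symbol by symbol and compare."""
        for scenario, start in (("fixed", START_FIXED), ("variable", START_VARIABLE)):
            scen = SCENARIOS[scenario]
            for kind in ("linear", "log2", "ilr"):
                terms = cs.truth.TRUTH_TERMS[(kind, scenario)]
                coefs = {t: rng.normal(0, 1) for t in terms}
                spec = TruthSpec(kind, scenario, coefs, rng.normal(5, 1), 0.5, start)
                delta = rng.uniform(-10, 10)
                end = reallocate(start, scen.exposure, scen.reference, delta)

                def predictor(c):
                    vals = c.as_dict()
                    if kind == "linear":
                        tv = {
                            t: (c.total if t == "Total" else vals[t]) for t in terms
                        }
                    elif kind == "log2":
                        tv = {t: np.log2(vals[t]) for t in terms}
                    else:
                        p = [vals[n] for n in scen.ilr_order]
                        tv = {
                            f"z{j+1}": np.log(
                                p[j]
                                / np.prod(p[j + 1 :]) ** (1.0 / len(p[j + 1 :]))
                            )
                            for j in range(3)
                        }
                    return spec.intercept + sum(
                        coefs[t] * tv[t] for t in terms
                    )

                brute = predictor(end) - predictor(start)
                assert cs.true_effect(
                    spec, SubstitutionQuery(scen.exposure, scen.reference, delta, start)
                ) == pytest.approx(brute, abs=1e-9)


class TestCalibration:
    def test_all_coefficients_zero_gives_target_intercept(self):
        spec = TruthSpec(
            "linear", "fixed", {"MVPA": 0.0, "SB": 0.0, "Sleep": 0.0}, 0.0, 0.5,
            START_FIXED,
        )
        out = cs.calibrate_intercept(spec, calibration_n=1000, seed=0)
        assert out.intercept == pytest.approx(5.5, abs=1e-12)

    def test_grand_mean_fpg_near_target(self, variable_truths):
        spec = variable_truths["log2"]
        data = cs.simulate_variable_total(n=100_000, seed=123)
        y = cs.simulate_outcome(data, spec, seed=124)
        assert y.mean() == pytest.approx(5.5, abs=0.02)

    def test_calibration_idempotent(self, fixed_truths):
        spec = fixed_truths["ilr"]
        again = cs.calibrate_intercept(spec)
        assert again.intercept == pytest.approx(spec.intercept, abs=1e-9)


class TestSerialization:
    def test_yaml_roundtrip(self, fixed_truths):
        spec = fixed_truths["log2"]
        back = cs.TruthSpec.from_yaml(spec.to_yaml())
        assert back.kind == spec.kind and back.scenario == spec.scenario
        assert back.coefficients == pytest.approx(spec.coefficients, rel=1e-12)
        assert back.intercept == pytest.approx(spec.intercept, rel=1e-12)
        assert back.start.values == pytest.approx(spec.start.values, rel=1e-12)
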