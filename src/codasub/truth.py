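"""Ground-truth outcome mechanisms and closed-form substitution effects.

Three parametric data-generating mechanisms link the compositional exposures
to fasting plasma glucose (FPG, mmol/l):

* ``linear``  — FPG is linear in the raw component amounts;
* ``log2``    — FPG is linear in log2-transformed amounts (diminishing
  returns: a unit change matters more at low values);
* ``ilr``     — FPG is linear in the isometric log-ratio pivot coordinates
  of the full composition.

The focal coefficient of each mechanism is solved so that a *one-unit*
substitution (1 min of MVPA for LPA; 1 kcal of carbohydrate for protein),
taken from a common start composition, has the same effect under all three
mechanisms.  Larger substitutions then disagree across mechanisms — the
disagreement is exactly what the simulation study measures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .composition import Composition, close, geometric_mean_composition, ilr_pivot, reallocate
from .generate import (
    FIXED_TIME_USE,
    VARIABLE_ENERGY,
    FixedTotalConfig,
    VariableTotalConfig,
    simulate_fixed_total,
    simulate_variable_total,
)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "TruthSpec",
    "SubstitutionQuery",
    "composition_frame",
    "solve_focal_coefficients",
    "solve_twopoint_coefficients",
    "calibrate_intercept",
    "true_effect",
    "default_truth",
    "default_start",
    "DEFAULT_PRESETS",
    "CALIBRATION_SEED",
    "CALIBRATION_N",
]

#: fixed seed defining the calibration "population" (start composition and
#: intercepts); deliberately independent of study master seeds.
CALIBRATION_SEED = 20240117
CALIBRATION_N = 1_000_000

TRUTH_KINDS = ("linear", "log2", "ilr")


@dataclass(frozen=True)
class Scenario:
    """One of the two study settings: fixed-total time use or variable-total diet."""

    name: str
    components: tuple[str, ...]
    exposure: str
    reference: str
    ilr_order: tuple[str, ...]
    unit_effect: float  # mmol/l per 1-unit exposure-for-reference substitution
    big_delta: float    # the study's larger reallocation (10 min / 100 kcal)
    total_name: str | None

    @property
    def generator_config(self) -> FixedTotalConfig | VariableTotalConfig:
        return FIXED_TIME_USE if self.name == "fixed" else VARIABLE_ENERGY

    def simulate(self, n: int, seed) -> pd.DataFrame:
        if self.name == "fixed":
            return simulate_fixed_total(FIXED_TIME_USE, n, seed)
        return simulate_variable_total(VARIABLE_ENERGY, n, seed)


SCENARIOS: dict[str, Scenario] = {
    "fixed": Scenario(
        name="fixed",
        components=("Sleep", "SB", "LPA", "MVPA"),
        exposure="MVPA",
        reference="LPA",
        ilr_order=("MVPA", "SB", "Sleep", "LPA"),
        unit_effect=-0.020,
        big_delta=10.0,
        total_name=None,
    ),
    "variable": Scenario(
        name="variable",
        components=("Carbs", "Fat", "Alcohol", "Protein"),
        exposure="Carbs",
        reference="Protein",
        ilr_order=("Carbs", "Fat", "Alcohol", "Protein"),
        unit_effect=0.004,
        big_delta=100.0,
        total_name="Total",
    ),
}

# Terms entering each truth mechanism.  Note which component is absent:
# the reference (LPA; Protein) is left out of the linear and log2 fixed-total
# truths, and protein enters the variable-total linear truth only through the
# total.  "z1..z3" are ILR pivot coordinates in the scenario's pivot order.
TRUTH_TERMS: dict[tuple[str, str], tuple[str, ...]] = {
    ("linear", "fixed"): ("MVPA", "SB", "Sleep"),
    ("log2", "fixed"): ("MVPA", "SB", "Sleep"),
    ("ilr", "fixed"): ("z1", "z2", "z3"),
    ("linear", "variable"): ("Carbs", "Fat", "Alcohol", "Total"),
    ("log2", "variable"): ("Carbs", "Fat", "Alcohol", "Protein"),
    ("ilr", "variable"): ("z1", "z2", "z3"),
}

FOCAL_TERM: dict[tuple[str, str], str] = {
    ("linear", "fixed"): "MVPA",
    ("log2", "fixed"): "MVPA",
    ("ilr", "fixed"): "z1",
    ("linear", "variable"): "Carbs",
    ("log2", "variable"): "Carbs",
    ("ilr", "variable"): "z1",
}

# Non-focal coefficient presets.  The printed constraints pin down only the
# focal coefficient; the remaining effects are free study conditions, chosen
# once with realistic sign and modest magnitude (e.g. a small adverse
# sedentary-behaviour effect, a small protective sleep effect).  Every
# closed-form target checked in this package is invariant to these values.
DEFAULT_PRESETS: dict[tuple[str, str], dict[str, float]] = {
    ("linear", "fixed"): {"SB": 0.0005, "Sleep": -0.0005},
    ("log2", "fixed"): {"SB": 0.15, "Sleep": -0.10},
    ("ilr", "fixed"): {"z2": 0.10, "z3": -0.05},
    ("linear", "variable"): {"Fat": 0.0006, "Alcohol": 0.001, "Total": 0.0005},
    ("log2", "variable"): {"Fat": 0.15, "Alcohol": 0.05, "Protein": -0.20},
    ("ilr", "variable"): {"z2": 0.10, "z3": 0.05},
}

# Where the substitution contrast touches two free coefficients (the log2
# variable-total truth moves both the carbohydrate and protein terms; the ILR
# truths move every pivot coordinate), the single 1-unit constraint leaves the
# mechanism underdetermined.  The larger reallocation's ground-truth effect is
# an additional stated constraint, so the default mechanisms solve a second
# coefficient from it; these are the targets used (mmol/l at the default
# start; the linear and log2-fixed entries are implied by the 1-unit target
# and listed for reference only).
DEFAULT_BIG_EFFECTS: dict[tuple[str, str], float] = {
    ("ilr", "fixed"): -0.157,
    ("log2", "variable"): 0.284,
    ("ilr", "variable"): 0.510,
}

#: the second coefficient solved from the big-reallocation constraint
SECONDARY_TERM: dict[tuple[str, str], str] = {
    ("ilr", "fixed"): "z2",
    ("log2", "variable"): "Protein",
    ("ilr", "variable"): "z2",
}

DEFAULT_NOISE_SD = 0.5  # mmol/l residual FPG spread
TARGET_MEAN_FPG = 5.5   # mmol/l


@dataclass(frozen=True)
class SubstitutionQuery:
    """The estimand: move ``delta`` units from ``reference`` into ``exposure``,
    starting from ``start``, holding everything else (and the total) fixed."""

    exposure: str
    reference: str
    delta: float
    start: Composition

    def endpoint(self) -> Composition:
        return reallocate(self.start, self.exposure, self.reference, self.delta)


@dataclass(frozen=True)
class TruthSpec:
    """A fully specified outcome mechanism.

    ``coefficients`` maps term names (component names, ``Total``, or ILR
    coordinates ``z1..z{D-1}``) to mmol/l-per-term-unit effects.
    """

    kind: str
    scenario: str
    coefficients: Mapping[str, float]
    intercept: float
    noise_sd: float
    start: Composition

    def __post_init__(self) -> None:
        if self.kind not in TRUTH_KINDS:
            raise ValueError(f"unknown truth kind {self.kind!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        expected = TRUTH_TERMS[(self.kind, self.scenario)]
        if set(self.coefficients) != set(expected):
            raise ValueError(
                f"{self.kind}/{self.scenario} truth needs terms {expected}, "
                f"got {tuple(self.coefficients)}"
            )
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    # -- linear predictor ------------------------------------------------
    def term_values(self, dataset: pd.DataFrame) -> pd.DataFrame:
        """Evaluate the mechanism's transformed terms for each row."""
        scen = SCENARIOS[self.scenario]
        missing = [c for c in scen.components if c not in dataset.columns]
        if missing:
            raise ValueError(f"dataset lacks components {missing}")
        terms = TRUTH_TERMS[(self.kind, self.scenario)]
        if self.kind == "ilr":
            z = ilr_pivot(dataset, scen.ilr_order)
            return pd.DataFrame(z, columns=list(terms), index=dataset.index)
        out = {}
        for term in terms:
            if term == "Total":
                col = (
                    dataset["Total"]
                    if "Total" in dataset.columns
                    else dataset[list(scen.components)].sum(axis=1)
                )
            else:
                col = dataset[term]
            col = col.astype(float)
            if self.kind == "log2":
                if (col <= 0).any():
                    raise ValueError(f"non-positive value under log2({term})")
                col = np.log2(col)
            out[term] = col
        return pd.DataFrame(out, index=dataset.index)

    def linear_predictor(self, dataset: pd.DataFrame) -> np.ndarray:
        terms = self.term_values(dataset)
        beta = np.array([self.coefficients[t] for t in terms.columns])
        return self.intercept + terms.to_numpy(dtype=float) @ beta

    def predictor_at(self, c: Composition) -> float:
        return float(self.linear_predictor(composition_frame(c, self.scenario))[0])

    # -- serialization ---------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "kind": self.kind,
                "scenario": self.scenario,
                "coefficients": dict(self.coefficients),
                "intercept": float(self.intercept),
                "noise_sd": float(self.noise_sd),
                "start": {
                    "names": list(self.start.names),
                    "values": [float(v) for v in self.start.values],
                },
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "TruthSpec":
        data = yaml.safe_load(text)
        start = close(data["start"]["values"], data["start"]["names"])
        return cls(
            kind=data["kind"],
            scenario=data["scenario"],
            coefficients=data["coefficients"],
            intercept=data["intercept"],
            noise_sd=data["noise_sd"],
            start=start,
        )


def composition_frame(c: Composition, scenario: str) -> pd.DataFrame:
    """One-row dataset for a composition, with a Total column when the
    scenario has a variable total."""
    scen = SCENARIOS[scenario]
    row = {name: [c[name]] for name in scen.components}
    if scen.total_name is not None:
        row[scen.total_name] = [c.total]
    return pd.DataFrame(row)


def solve_focal_coefficients(
    kind: str,
    scenario: str,
    start: Composition,
    unit_effect: float | None = None,
    presets: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Solve the focal coefficient so a 1-unit substitution has ``unit_effect``.

    The substitution contrast is linear in every coefficient, so given preset
    values for the non-focal terms the focal coefficient has the closed form

        focal = (unit_effect - sum_k preset_k * dt_k) / dt_focal,

    where ``dt`` is the change in each transformed term under a 1-unit
    exposure-for-reference reallocation from ``start``.  For the linear
    mechanisms ``dt_focal`` is 1 and no other term moves, so the focal
    coefficient *is* the unit effect; for log2 and ILR mechanisms the
    reference component's movement feeds other terms and the presets enter.
    """
    scen = SCENARIOS[scenario]
    if unit_effect is None:
        unit_effect = scen.unit_effect
    presets = dict(DEFAULT_PRESETS[(kind, scenario)] if presets is None else presets)
    focal = FOCAL_TERM[(kind, scenario)]
    terms = TRUTH_TERMS[(kind, scenario)]
    missing = [t for t in terms if t != focal and t not in presets]
    if missing:
        raise ValueError(f"presets must supply non-focal terms {missing}")

    dt = _term_deltas(kind, scenario, start, 1.0)

    if abs(dt[focal]) < 1e-14:
        raise ArithmeticError(
            f"1-unit substitution does not move the focal term {focal!r}"
        )
    coefficients = {t: float(presets[t]) for t in terms if t != focal}
    coefficients[focal] = float(
        (unit_effect - sum(coefficients[t] * dt[t] for t in coefficients)) / dt[focal]
    )
    return {t: coefficients[t] for t in terms}


def _term_deltas(kind: str, scenario: str, start: Composition, delta: float) -> pd.Series:
    """Change in each transformed term under the scenario's substitution."""
    scen = SCENARIOS[scenario]
    terms = TRUTH_TERMS[(kind, scenario)]
    probe = TruthSpec(kind, scenario, {t: 0.0 for t in terms}, 0.0, 1.0, start)
    t_start = probe.term_values(composition_frame(start, scenario)).iloc[0]
    endpoint = reallocate(start, scen.exposure, scen.reference, delta)
    t_end = probe.term_values(composition_frame(endpoint, scenario)).iloc[0]
    return t_end - t_start


def solve_twopoint_coefficients(
    kind: str,
    scenario: str,
    start: Composition,
    unit_effect: float | None = None,
    big_effect: float | None = None,
    presets: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Solve two coefficients from the 1-unit *and* big-reallocation targets.

    For mechanisms where the substitution moves two or more terms, the pair
    of stated ground-truth effects (e.g. 0.004 mmol/l per kcal and
    0.284 mmol/l per 100 kcal for the variable-total log2 mechanism) pins
    down the focal coefficient and one secondary coefficient jointly; any
    remaining terms keep their preset values.  Mechanisms whose contrast is
    determined by the focal coefficient alone fall back to
    :func:`solve_focal_coefficients` (their big-reallocation effect is then
    implied and cannot be chosen independently).
    """
    scen = SCENARIOS[scenario]
    if unit_effect is None:
        unit_effect = scen.unit_effect
    key = (kind, scenario)
    if key not in SECONDARY_TERM:
        return solve_focal_coefficients(kind, scenario, start, unit_effect, presets)
    if big_effect is None:
        big_effect = DEFAULT_BIG_EFFECTS[key]
    presets = dict(DEFAULT_PRESETS[key] if presets is None else presets)
    focal, secondary = FOCAL_TERM[key], SECONDARY_TERM[key]
    terms = TRUTH_TERMS[key]
    fixed = {t: float(presets[t]) for t in terms if t not in (focal, secondary)}

    dt1 = _term_deltas(kind, scenario, start, 1.0)
    dtb = _term_deltas(kind, scenario, start, scen.big_delta)
    a = np.array([[dt1[focal], dt1[secondary]], [dtb[focal], dtb[secondary]]])
    rhs = np.array(
        [
            unit_effect - sum(fixed[t] * dt1[t] for t in fixed),
            big_effect - sum(fixed[t] * dtb[t] for t in fixed),
        ]
    )
    if abs(np.linalg.det(a)) < 1e-14:
        raise ArithmeticError(
            "the two substitution constraints are collinear; cannot solve "
            f"{focal!r} and {secondary!r} jointly"
        )
    c_focal, c_secondary = np.linalg.solve(a, rhs)
    out = dict(fixed)
    out[focal] = float(c_focal)
    out[secondary] = float(c_secondary)
    return {t: out[t] for t in terms}


def true_effect(spec: TruthSpec, query: SubstitutionQuery) -> float:
    """Noise-free outcome change for the substitution, in mmol/l."""
    return spec.predictor_at(query.endpoint()) - spec.predictor_at(query.start)


def calibrate_intercept(
    spec: TruthSpec,
    calibration_sample: pd.DataFrame | None = None,
    target_mean: float = TARGET_MEAN_FPG,
    calibration_n: int = CALIBRATION_N,
    seed: int = CALIBRATION_SEED,
) -> TruthSpec:
    """Set the intercept so the population mean outcome equals ``target_mean``.

    The noise-free linear predictor is averaged over a large calibration
    sample (generated here if not supplied); additive Gaussian noise does not
    shift the mean, so the population mean outcome matches the target up to
    Monte Carlo error of order ``sd / sqrt(calibration_n)``.
    """
    if calibration_sample is None:
        calibration_sample = SCENARIOS[spec.scenario].simulate(calibration_n, seed)
    eta = spec.linear_predictor(calibration_sample)
    return replace(spec, intercept=spec.intercept + (target_mean - float(np.mean(eta))))


@lru_cache(maxsize=8)
def _calibration_sample_cached(scenario: str, n: int, seed: int) -> pd.DataFrame:
    return SCENARIOS[scenario].simulate(n, seed)


def default_start(
    scenario: str, calibration_n: int = CALIBRATION_N, seed: int = CALIBRATION_SEED
) -> Composition:
    """Population start composition: the component-wise geometric mean of a
    large calibration sample (fixed seed), frozen for all truth definitions."""
    scen = SCENARIOS[scenario]
    sample = _calibration_sample_cached(scenario, calibration_n, seed)
    return geometric_mean_composition(sample, scen.components)


def default_truth(
    kind: str,
    scenario: str,
    start: Composition | None = None,
    unit_effect: float | None = None,
    big_effect: float | None = None,
    presets: Mapping[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    calibration_n: int = CALIBRATION_N,
    calibration_seed: int = CALIBRATION_SEED,
    calibrate: bool = True,
) -> TruthSpec:
    """Build the study's default truth mechanism for (kind, scenario).

    Solves the focal coefficient from the common 1-unit target (and, for
    mechanisms the 1-unit constraint leaves underdetermined, a secondary
    coefficient from the big-reallocation target), then calibrates the
    intercept to a 5.5 mmol/l population mean FPG.
    """
    if start is None:
        start = default_start(scenario, calibration_n, calibration_seed)
    coefficients = solve_twopoint_coefficients(
        kind, scenario, start, unit_effect, big_effect, presets
    )
    spec = TruthSpec(kind, scenario, coefficients, 0.0, noise_sd, start)
    if calibrate:
        sample = _calibration_sample_cached(scenario, calibration_n, calibration_seed)
        spec = calibrate_intercept(spec, calibration_sample=sample)
    return spec
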