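"""The analytical model battery and prediction-contrast substitution estimates.

Thirteen model families are benchmarked, five for fixed-total (time-use)
data and eight for variable-total (dietary) data:

========  =====================================================
family    formula (outcome FPG on the left throughout)
========  =====================================================
``1A``    MVPA + SB + Sleep                       (linear leave-one-out)
``1B``    MVPA/Total + SB/Total + Sleep/Total     (ratio leave-one-out)
``1C``    log2 MVPA + log2 SB + log2 Sleep        (log2 leave-one-out)
``1D``    s(MVPA) + s(SB) + s(Sleep)              (GAM leave-one-out)
``1E``    ILR pivot coordinates of (MVPA, SB, Sleep, LPA)
``2A``    Carbs + Fat + Alcohol + Total           (linear leave-one-out)
``2B``    Carbs/Total + Fat/Total + Alcohol/Total (nutrient density)
``2B'``   2B + Total              (multivariable nutrient density)
``2C``    log2 Carbs + log2 Fat + log2 Alcohol + log2 Total
``2C'``   log2 of all four components             (all-components)
``2D``    s(Carbs) + s(Fat) + s(Alcohol) + s(Total)
``2D'``   s(Carbs) + s(Fat) + s(Alcohol) + s(Protein)
``2E``    ILR pivot coordinates of (Carbs, Fat, Alcohol, Protein)
========  =====================================================

The reference (left-out) component is LPA for time use and protein for
diet.  Parametric families are fitted by ordinary least squares; GAM
families by penalized regression splines (:mod:`codasub.pspline`).  Every
family reports its substitution estimate the same way: predict the outcome
at a reallocated copy of the start composition, predict it at the start,
and difference the two.  For fixed-total data ``Total`` is the constant
1440 min; for variable-total data the per-row total is used in ratios and
the contrast holds the total fixed (the +delta/-delta reallocation
conserves it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import ilr_pivot
from .pspline import AdditiveFit, fit_additive
from .truth import SCENARIOS, SubstitutionQuery, composition_frame

__all__ = [
    "ModelSpec",
    "FittedModel",
    "FAMILIES",
    "build_design",
    "fit",
    "select_gam_basis",
    "estimate_substitution",
    "GAM_K_CANDIDATES",
]

GAM_K_CANDIDATES = (5, 10, 15, 20, 25, 30)

FIXED_TOTAL_MINUTES = 1440.0


@dataclass(frozen=True)
class _Family:
    label: str
    scenario: str
    kind: str  # "ols" or "gam"
    design: Callable[[pd.DataFrame], pd.DataFrame]
    description: str


def _cols(dataset: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    missing = [n for n in names if n not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks columns {missing}")
    return dataset[list(names)].astype(float)


def _log2_cols(dataset: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    frame = _cols(dataset, names)
    bad = (frame <= 0)
    if bad.to_numpy().any():
        col = bad.any().idxmax()
        row = bad[col].idxmax()
        raise ValueError(f"non-positive value under log2 in {col!r} (row {row})")
    return np.log2(frame).add_prefix("log2_")


def _ratio_cols(
    dataset: pd.DataFrame, names: Sequence[str], total: pd.Series | float
) -> pd.DataFrame:
    frame = _cols(dataset, names)
    return frame.div(total, axis=0).add_suffix("_over_Total")


def _total_series(dataset: pd.DataFrame, scenario: str) -> pd.Series | float:
    scen = SCENARIOS[scenario]
    if scen.total_name is None:
        return FIXED_TOTAL_MINUTES
    if scen.total_name in dataset.columns:
        return dataset[scen.total_name].astype(float)
    return dataset[list(scen.components)].sum(axis=1)


def _ilr_cols(dataset: pd.DataFrame, scenario: str) -> pd.DataFrame:
    scen = SCENARIOS[scenario]
    z = ilr_pivot(dataset, scen.ilr_order)
    return pd.DataFrame(
        z, columns=[f"z{j+1}" for j in range(z.shape[1])], index=dataset.index
    )


def _with_total(dataset: pd.DataFrame, scenario: str, names: Sequence[str]) -> pd.DataFrame:
    frame = _cols(dataset, names)
    frame["Total"] = _total_series(dataset, scenario)
    return frame


_F = _Family
FAMILIES: dict[str, _Family] = {
    f.label: f
    for f in [
        _F("1A", "fixed", "ols", lambda d: _cols(d, ("MVPA", "SB", "Sleep")),
           "linear leave-one-out (isotemporal)"),
        _F("1B", "fixed", "ols",
           lambda d: _ratio_cols(d, ("MVPA", "SB", "Sleep"), FIXED_TOTAL_MINUTES),
           "ratio leave-one-out"),
        _F("1C", "fixed", "ols", lambda d: _log2_cols(d, ("MVPA", "SB", "Sleep")),
           "log2 leave-one-out"),
        _F("1D", "fixed", "gam", lambda d: _cols(d, ("MVPA", "SB", "Sleep")),
           "GAM leave-one-out"),
        _F("1E", "fixed", "ols", lambda d: _ilr_cols(d, "fixed"),
           "CoDA isometric log-ratio"),
        _F("2A", "variable", "ols",
           lambda d: _with_total(d, "variable", ("Carbs", "Fat", "Alcohol")),
           "linear leave-one-out (isocaloric)"),
        _F("2B", "variable", "ols",
           lambda d: _ratio_cols(d, ("Carbs", "Fat", "Alcohol"),
                                 _total_series(d, "variable")),
           "nutrient density"),
        _F("2Bprime", "variable", "ols",
           lambda d: _ratio_cols(d, ("Carbs", "Fat", "Alcohol"),
                                 _total_series(d, "variable"))
                     .assign(Total=_total_series(d, "variable")),
           "multivariable nutrient density"),
        _F("2C", "variable", "ols",
           lambda d: _log2_cols(d.assign(Total=_total_series(d, "variable")),
                                ("Carbs", "Fat", "Alcohol", "Total")),
           "log2 leave-one-out"),
        _F("2Cprime", "variable", "ols",
           lambda d: _log2_cols(d, ("Carbs", "Fat", "Alcohol", "Protein")),
           "log2 all-components"),
        _F("2D", "variable", "gam",
           lambda d: _with_total(d, "variable", ("Carbs", "Fat", "Alcohol")),
           "GAM leave-one-out"),
        _F("2Dprime", "variable", "gam",
           lambda d: _cols(d, ("Carbs", "Fat", "Alcohol", "Protein")),
           "GAM all-components"),
        _F("2E", "variable", "ols", lambda d: _ilr_cols(d, "variable"),
           "CoDA isometric log-ratio"),
    ]
}


@dataclass(frozen=True)
class ModelSpec:
    """One analytical model family, plus GAM settings where relevant."""

    family: str
    smooth_k: int = 10

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}"
            )

    @property
    def scenario(self) -> str:
        return FAMILIES[self.family].scenario

    @property
    def is_gam(self) -> bool:
        return FAMILIES[self.family].kind == "gam"

    @property
    def description(self) -> str:
        return FAMILIES[self.family].description


@dataclass
class FittedModel:
    """A fitted family; exposes prediction and metadata uniformly."""

    spec: ModelSpec
    ols_result: "sm.regression.linear_model.RegressionResults | None" = None
    gam_fit: AdditiveFit | None = None

    @property
    def aic(self) -> float:
        return self.gam_fit.aic if self.spec.is_gam else float(self.ols_result.aic)

    @property
    def params(self) -> pd.Series:
        if self.spec.is_gam:
            raise AttributeError("GAM fits expose smooths, not named coefficients")
        return self.ols_result.params

    def predict(self, dataset: pd.DataFrame) -> np.ndarray:
        design = build_design(self.spec, dataset)
        if self.spec.is_gam:
            return self.gam_fit.predict(design)
        X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
        return self.ols_result.predict(X)

    def summary_dict(self) -> dict:
        """JSON-ready summary: family, settings, coefficients/edf, AIC."""
        out = {
            "family": self.spec.family,
            "description": self.spec.description,
            "aic": float(self.aic),
        }
        if self.spec.is_gam:
            out.update(
                smooth_k=self.spec.smooth_k,
                edf=float(self.gam_fit.edf),
                smoothing_lambda=float(self.gam_fit.lam),
            )
        else:
            out["coefficients"] = {
                name: float(v) for name, v in self.ols_result.params.items()
            }
        return out


def build_design(spec: ModelSpec, dataset: pd.DataFrame) -> pd.DataFrame:
    """Transformed regressor table for the family (no intercept column).

    For GAM families the returned columns are the raw smooth-term inputs.
    """
    return FAMILIES[spec.family].design(dataset)


def fit(spec: ModelSpec, dataset: pd.DataFrame, outcome) -> FittedModel:
    """Fit the family to a dataset with its outcome vector."""
    y = np.asarray(
        dataset[outcome] if isinstance(outcome, str) else outcome, dtype=float
    )
    design = build_design(spec, dataset)
    if len(design) <= design.shape[1] + 1:
        raise ValueError("need more rows than parameters")
    if spec.is_gam:
        gam = fit_additive(design, y, k=spec.smooth_k)
        return FittedModel(spec=spec, gam_fit=gam)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design for family {spec.family} is rank deficient ({rank} < "
            f"{X.shape[1]}); with a fixed total, all components plus the total "
            "cannot be included together"
        )
    result = sm.OLS(y, X).fit()
    result = _name_params(result, ["const", *design.columns])
    return FittedModel(spec=spec, ols_result=result)


def _name_params(result, names):
    result.params = pd.Series(np.asarray(result.params), index=names)
    return result


def select_gam_basis(
    spec: ModelSpec,
    dataset: pd.DataFrame,
    outcome,
    candidates: Sequence[int] = GAM_K_CANDIDATES,
) -> int:
    """Pick the smooth basis dimension minimising AIC over ``candidates``.

    Ties break toward the smallest dimension; candidates whose fit fails are
    skipped with a warning.
    """
    if not ModelSpec(spec.family).is_gam:
        raise ValueError(f"family {spec.family} has no smooth terms")
    best_k, best_aic = None, np.inf
    for k in sorted(candidates):
        try:
            fitted = fit(ModelSpec(spec.family, smooth_k=k), dataset, outcome)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"k={k} failed for family {spec.family}: {err}")
            continue
        if fitted.aic < best_aic - 1e-12:
            best_k, best_aic = k, fitted.aic
    if best_k is None:
        raise RuntimeError(f"every candidate basis failed for family {spec.family}")
    return best_k


def estimate_substitution(fitted: FittedModel, query: SubstitutionQuery) -> float:
    """Prediction-contrast substitution estimate, in mmol/l.

    Predicts the outcome at ``reallocate(start, exposure, reference, delta)``
    and at ``start`` and differences the two.  Non-focal components are held
    at their start values and the total is conserved by the contrast.
    """
    scenario = fitted.spec.scenario
    at_start = composition_frame(query.start, scenario)
    at_end = composition_frame(query.endpoint(), scenario)
    frame = pd.concat([at_start, at_end], ignore_index=True)
    pred = fitted.predict(frame)
    return float(pred[1] - pred[0])
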