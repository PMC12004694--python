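"""Seeded generators for compositional exposure data and the glucose outcome.

Two families of exposure data are emulated:

* **Fixed totals** — 24-hour time use.  Sleep, sedentary behaviour (SB),
  light physical activity (LPA) and moderate-to-vigorous physical activity
  (MVPA) must sum to exactly 1440 min/day for every person, so the
  components are *jointly* dependent: each is drawn iteratively as its
  target share of the time still unallocated, plus noise, and the last
  component takes the exact remainder.

* **Variable totals** — daily energy intake.  Carbohydrate, fat, alcohol
  and protein kilocalories are drawn independently and the total is simply
  their row sum, so the total varies between people and changing one
  component does not force a change in any other.

The outcome, fasting plasma glucose (FPG, mmol/l), is generated from a
:class:`~codasub.truth.TruthSpec` linear predictor plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .truth import TruthSpec

__all__ = [
    "FixedTotalConfig",
    "VariableTotalConfig",
    "simulate_fixed_total",
    "simulate_variable_total",
    "simulate_outcome",
    "dataset_seed",
    "FIXED_TIME_USE",
    "VARIABLE_ENERGY",
]

#: abort if more than this fraction of candidate rows violate positivity
MAX_REJECTION_RATE = 0.5


class RejectionRateError(RuntimeError):
    """Raised when the noise configuration makes positivity violations common."""


@dataclass(frozen=True)
class FixedTotalConfig:
    """Generator settings for fixed-total (time-use) compositions.

    ``order`` is the generation order; the last label receives the exact
    unallocated remainder and is generated without its own noise term.
    ``noise_sd`` therefore has one entry per label *except* the last.
    """

    order: tuple[str, ...]
    target_means: Mapping[str, float]
    noise_sd: Mapping[str, float]
    fixed_total: float = 1440.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "order", tuple(self.order))
        object.__setattr__(self, "target_means", dict(self.target_means))
        object.__setattr__(self, "noise_sd", dict(self.noise_sd))
        if set(self.target_means) != set(self.order):
            raise ValueError("target_means keys must match order")
        if set(self.noise_sd) != set(self.order[:-1]):
            raise ValueError("noise_sd needs one entry per label except the last")
        total = sum(self.target_means.values())
        if abs(total - self.fixed_total) > 1e-9 * self.fixed_total:
            raise ValueError(
                f"target means sum to {total}, not the fixed total {self.fixed_total}"
            )
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sds must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "order": list(self.order),
                "target_means": dict(self.target_means),
                "noise_sd": dict(self.noise_sd),
                "fixed_total": self.fixed_total,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "FixedTotalConfig":
        return cls(**yaml.safe_load(text))


@dataclass(frozen=True)
class VariableTotalConfig:
    """Generator settings for variable-total (energy intake) compositions."""

    labels: tuple[str, ...]
    target_means: Mapping[str, float]
    noise_sd: Mapping[str, float]
    total_name: str = "Total"

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "target_means", dict(self.target_means))
        object.__setattr__(self, "noise_sd", dict(self.noise_sd))
        if set(self.target_means) != set(self.labels) or set(self.noise_sd) != set(
            self.labels
        ):
            raise ValueError("target_means and noise_sd keys must match labels")
        if any(m <= 0 for m in self.target_means.values()):
            raise ValueError("target means must be positive")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sds must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "labels": list(self.labels),
                "target_means": dict(self.target_means),
                "noise_sd": dict(self.noise_sd),
                "total_name": self.total_name,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "VariableTotalConfig":
        return cls(**yaml.safe_load(text))


# Default study conditions.  Time-use noise sds are 10% of the target mean,
# except LPA: its noise feeds almost directly into the MVPA remainder
# (22 min/day mean), so it is capped at 7 min/day to keep MVPA positive in
# all but ~0.1% of draws.
FIXED_TIME_USE = FixedTotalConfig(
    order=("Sleep", "SB", "LPA", "MVPA"),
    target_means={"Sleep": 564.0, "SB": 541.0, "LPA": 313.0, "MVPA": 22.0},
    noise_sd={"Sleep": 56.4, "SB": 54.1, "LPA": 7.0},
    fixed_total=1440.0,
)

# Macronutrient noise sds are 10% of the target mean throughout.
VARIABLE_ENERGY = VariableTotalConfig(
    labels=("Carbs", "Fat", "Alcohol", "Protein"),
    target_means={"Carbs": 1000.0, "Fat": 600.0, "Alcohol": 100.0, "Protein": 300.0},
    noise_sd={"Carbs": 100.0, "Fat": 60.0, "Alcohol": 10.0, "Protein": 30.0},
)


def dataset_seed(master_seed: int, replicate: int, stream: int = 0) -> np.random.SeedSequence:
    """Deterministic per-replicate seed stream.

    Replicate ``r`` of a study with a given master seed is reproducible in
    isolation; ``stream`` separates independent uses (exposures vs outcome
    noise) within a replicate.
    """
    return np.random.SeedSequence([int(master_seed), int(replicate), int(stream)])


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _reject_and_refill(
    draw: "callable", n: int, labels: Sequence[str]
) -> np.ndarray:
    """Whole-row rejection sampling: redraw rows with any non-positive part.

    Redrawing the full row (rather than truncating single draws) preserves
    the dependence structure of the iterative allocation.  A sustained
    rejection rate above :data:`MAX_REJECTION_RATE` signals that the noise
    is too wide for the target means and raises instead of looping.
    """
    rows = draw(n)
    bad = np.any(rows <= 0, axis=1)
    attempts = n
    rejected = int(bad.sum())
    while bad.any():
        if attempts >= 1000 and rejected / attempts > MAX_REJECTION_RATE:
            worst = labels[int(np.argmax((rows <= 0).sum(axis=0)))]
            raise RejectionRateError(
                f"rejection rate {rejected/attempts:.0%} exceeds "
                f"{MAX_REJECTION_RATE:.0%}; noise too wide for the target means "
                f"(most violations in {worst!r})"
            )
        refill = draw(int(bad.sum()))
        rows[bad] = refill
        attempts += int(bad.sum())
        bad2 = np.any(rows <= 0, axis=1)
        rejected += int(bad2.sum())
        bad = bad2
    return rows


def simulate_fixed_total(
    config: FixedTotalConfig = FIXED_TIME_USE,
    n: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate ``n`` days of time use summing exactly to the fixed total.

    The first component is its target mean plus noise; each subsequent
    component takes its target share of the remaining unallocated time plus
    noise; the final component is the exact remainder, so every row closes
    to ``config.fixed_total`` by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    order = config.order
    means = config.target_means
    total = config.fixed_total

    # target share of the remaining unallocated time for components 2..D-1
    shares = {}
    allocated = 0.0
    for j, name in enumerate(order):
        if 0 < j < len(order) - 1:
            shares[name] = means[name] / (total - allocated)
        allocated += means[name]

    def draw(k: int) -> np.ndarray:
        columns = np.empty((k, len(order)))
        first = order[0]
        columns[:, 0] = means[first] + rng.normal(0.0, config.noise_sd[first], k)
        remaining = total - columns[:, 0]
        for j, name in enumerate(order[1:-1], start=1):
            x = shares[name] * remaining + rng.normal(0.0, config.noise_sd[name], k)
            columns[:, j] = x
            remaining = remaining - x
        columns[:, -1] = remaining
        return columns

    rows = _reject_and_refill(draw, n, order)
    frame = pd.DataFrame(rows, columns=list(order))
    # re-impose exact closure (guards against accumulated rounding)
    frame[order[-1]] = total - frame[list(order[:-1])].sum(axis=1)
    return frame


def simulate_variable_total(
    config: VariableTotalConfig = VARIABLE_ENERGY,
    n: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate ``n`` days of macronutrient intake with a variable total.

    Components are independent normals (rows with any non-positive value are
    redrawn); the total column is the exact row sum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    labels = config.labels
    mu = np.array([config.target_means[l] for l in labels])
    sd = np.array([config.noise_sd[l] for l in labels])

    def draw(k: int) -> np.ndarray:
        return mu + rng.normal(0.0, 1.0, (k, len(labels))) * sd

    rows = _reject_and_refill(draw, n, labels)
    frame = pd.DataFrame(rows, columns=list(labels))
    frame[config.total_name] = frame[list(labels)].sum(axis=1)
    return frame


def simulate_outcome(
    dataset: pd.DataFrame,
    truth: "TruthSpec",
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate the FPG outcome (mmol/l) under a truth mechanism.

    Returns the truth's noise-free linear predictor per row plus
    ``N(0, noise_sd**2)`` residuals.
    """
    rng = _rng(seed)
    eta = truth.linear_predictor(dataset)
    return eta + rng.normal(0.0, truth.noise_sd, len(eta))
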