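"""Compositional arithmetic: closure, geometric means, reallocation and ILR pivot coordinates.

A composition is a vector of strictly positive parts (minutes of daily
activities, kilocalories of macronutrients, ...) together with its total.
For time-use data the total is fixed by nature (1440 min/day); for dietary
data it varies between observations.  All substitution estimands in this
package are phrased as moving ``delta`` units from one part to another while
holding every other part — and hence the total — constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Composition",
    "close",
    "geometric_mean_composition",
    "reallocate",
    "ilr_pivot",
    "ilr_pivot_inverse",
    "ilr_pivot_matrix",
]

#: relative tolerance on ``total == sum(values)``; pure floating-point slack.
TOTAL_RTOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """An ordered, strictly positive composition and its total.

    Parameters
    ----------
    names
        Ordered component labels, e.g. ``("Sleep", "SB", "LPA", "MVPA")``.
    values
        Positive amounts, one per label, in minutes/day or kcal/day.
    """

    names: tuple[str, ...]
    values: tuple[float, ...]
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        values = tuple(float(v) for v in self.values)
        if len(names) != len(values):
            raise ValueError(
                f"{len(names)} names but {len(values)} values"
            )
        if len(names) < 2:
            raise ValueError("a composition needs at least 2 components")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate component names in {names}")
        for name, value in zip(names, values):
            if not value > 0:
                raise ValueError(
                    f"component {name!r} must be strictly positive, got {value}"
                )
        total = sum(values) if self.total is None else float(self.total)
        if abs(total - sum(values)) > TOTAL_RTOL * max(1.0, abs(total)):
            raise ValueError(
                f"total {total} does not match component sum {sum(values)}"
            )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "total", total)

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no component named {name!r}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), dtype=float)

    def replace(self, **changes: float) -> "Composition":
        """Return a copy with the named components set to new values."""
        mapping = self.as_dict()
        for name, value in changes.items():
            if name not in mapping:
                raise KeyError(f"no component named {name!r}")
            mapping[name] = value
        return close(list(mapping.values()), list(mapping.keys()))


def close(values: Sequence[float], names: Sequence[str]) -> Composition:
    """Build a :class:`Composition`, setting the total to the component sum."""
    return Composition(tuple(names), tuple(values), None)


def _as_frame(dataset: pd.DataFrame | Mapping[str, Iterable[float]]) -> pd.DataFrame:
    frame = pd.DataFrame(dataset)
    if frame.shape[0] < 1:
        raise ValueError("dataset must contain at least one row")
    return frame


def geometric_mean_composition(
    dataset: pd.DataFrame | Mapping[str, Iterable[float]],
    names: Sequence[str] | None = None,
) -> Composition:
    """Component-wise geometric mean of a compositional dataset.

    This is the conventional start point for prediction contrasts: predictions
    are compared between the geometric-mean composition and a reallocated copy
    of it.  The result is *not* re-closed to a fixed total — the sum of
    component geometric means is generally below the fixed total — because the
    contrast is defined at the raw geometric-mean point.
    """
    frame = _as_frame(dataset)
    if names is not None:
        frame = frame[list(names)]
    array = frame.to_numpy(dtype=float)
    if np.any(array <= 0):
        rows, cols = np.nonzero(array <= 0)
        raise ValueError(
            f"non-positive value in component {frame.columns[cols[0]]!r} "
            f"(row {rows[0]}); geometric means need strictly positive data"
        )
    gm = np.exp(np.mean(np.log(array), axis=0))
    return close(gm.tolist(), list(frame.columns))


def reallocate(
    c: Composition, exposure: str, reference: str, delta: float
) -> Composition:
    """Move ``delta`` units from ``reference`` into ``exposure``.

    All other components — and therefore the total — are unchanged, which is
    exactly the isotemporal / isocaloric substitution contrast.
    """
    if exposure == reference:
        raise ValueError("exposure and reference must differ")
    new_exposure = c[exposure] + delta
    new_reference = c[reference] - delta
    if new_exposure <= 0:
        raise ValueError(
            f"reallocating {delta} drives {exposure!r} to {new_exposure} <= 0; "
            "the substitution effect is undefined there"
        )
    if new_reference <= 0:
        raise ValueError(
            f"reallocating {delta} drives {reference!r} to {new_reference} <= 0; "
            "the substitution effect is undefined there"
        )
    return c.replace(**{exposure: new_exposure, reference: new_reference})


def _pivot_coordinates(parts: np.ndarray) -> np.ndarray:
    # z_j = ln( p_j / geometric-mean(p_{j+1} ... p_D) ), unscaled pivot form
    logs = np.log(parts)
    d = logs.shape[-1]
    out = np.empty(logs.shape[:-1] + (d - 1,), dtype=float)
    for j in range(d - 1):
        out[..., j] = logs[..., j] - logs[..., j + 1 :].mean(axis=-1)
    return out


def ilr_pivot(
    c: Composition | pd.DataFrame | Mapping[str, Iterable[float]],
    order: Sequence[str],
) -> np.ndarray:
    """Isometric log-ratio pivot coordinates in the unscaled ratio form.

    For parts ``(p_1 ... p_D)`` taken in ``order``, coordinate ``j`` is
    ``ln(p_j / gm(p_{j+1} ... p_D))``, e.g. ``ln(MVPA / (SB*Sleep*LPA)**(1/3))``
    for four time-use parts.  The orthonormal ILR convention multiplies each
    coordinate by ``sqrt((D-j)/(D-j+1))``; the two differ only by a fixed
    per-coordinate rescaling, so regressions on either give identical fitted
    values and identical prediction contrasts.  The unscaled form is kept
    because its coordinates read directly as log-ratios of named parts.

    Accepts a single :class:`Composition` (returns a 1-D vector of length
    ``D - 1``) or a dataset (returns an ``n x (D-1)`` array).
    """
    order = list(order)
    if isinstance(c, Composition):
        if sorted(order) != sorted(c.names):
            raise ValueError(
                f"order {order} is not a permutation of components {list(c.names)}"
            )
        parts = np.array([c[name] for name in order], dtype=float)
        return _pivot_coordinates(parts)
    frame = _as_frame(c)
    missing = [name for name in order if name not in frame.columns]
    if missing:
        raise ValueError(f"dataset lacks components {missing}")
    array = frame[order].to_numpy(dtype=float)
    if np.any(array <= 0):
        raise ValueError("ILR coordinates need strictly positive parts")
    return _pivot_coordinates(array)


def ilr_pivot_inverse(z: np.ndarray, order: Sequence[str]) -> Composition:
    """Invert unscaled pivot coordinates up to closure (unit total).

    Recovers the composition on the unit simplex; the absolute scale is lost
    by construction (log-ratios are scale invariant).
    """
    z = np.asarray(z, dtype=float)
    d = z.shape[-1] + 1
    if len(order) != d:
        raise ValueError(f"{len(order)} labels for {d} parts")
    logs = np.zeros(d)
    for j in range(d - 2, -1, -1):
        logs[j] = z[j] + logs[j + 1 :].mean()
    parts = np.exp(logs)
    parts /= parts.sum()
    return close(parts.tolist(), list(order))


def ilr_pivot_matrix(order: Sequence[str], names: Sequence[str]) -> np.ndarray:
    """Contrast matrix M with ilr_pivot(x) = M @ log(x[names]).

    Useful for closed-form reasoning about ILR regressions; column order
    follows ``names``.
    """
    order = list(order)
    names = list(names)
    d = len(order)
    m = np.zeros((d - 1, d))
    for j in range(d - 1):
        m[j, j] = 1.0
        m[j, j + 1 :] = -1.0 / (d - 1 - j)
    return m[:, [order.index(n) for n in names]]
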