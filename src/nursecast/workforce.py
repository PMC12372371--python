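"""Age/gender/origin-structured workforce stocks and the annual step.

The supply side of the model is four stocks — {female, male} ×
{domestically educated, foreign educated} — each disaggregated by single
year of age and measured in whole-time equivalents (WTE).  Each annual
step applies three competing outflows (retirement, emigration, net
attrition) as additive annual fractions of the start-of-year stock, ages
the survivors by one year, and leaves entrant allocation to the caller.

Net attrition is exits from the register net of re-entries; a negative
per-cell attrition rate (re-entry exceeding exits) is permitted, though
the default synthetic schedules keep it non-negative.  At the maximum
working age the whole remaining cohort retires (rate forced to 1), which
prevents immortal cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GENDERS",
    "ORIGINS",
    "CohortGrid",
    "RateSchedule",
    "OutflowLedger",
    "advance_year",
    "allocate_entrants",
    "total_stock",
    "grid_to_frame",
    "grid_from_frame",
    "rates_to_frame",
    "rates_from_frame",
]

GENDERS = ("female", "male")
ORIGINS = ("domestic", "foreign")

_SUM_TOL = 1e-9


def _axis_index(value: str, axis: tuple[str, ...], name: str) -> int:
    try:
        return axis.index(value)
    except ValueError:
        raise ValueError(
            f"unknown {name} {value!r}; expected one of {axis}"
        ) from None


@dataclass
class CohortGrid:
    """WTE stocks indexed by (age, gender, origin).

    ``wte`` has shape ``(n_ages, 2, 2)`` with axes (age, gender, origin);
    ages run from ``age_min`` to ``age_min + n_ages - 1`` inclusive, the
    last being the maximum working age.  ``year`` stamps the calendar
    year the stocks refer to (start of year).
    """

    wte: np.ndarray
    age_min: int = 20
    year: int = 2021

    def __post_init__(self) -> None:
        self.wte = np.asarray(self.wte, dtype=float)
        if self.wte.ndim != 3 or self.wte.shape[1:] != (len(GENDERS), len(ORIGINS)):
            raise ValueError(
                f"wte must have shape (n_ages, {len(GENDERS)}, {len(ORIGINS)}), "
                f"got {self.wte.shape}"
            )
        if not np.all(np.isfinite(self.wte)):
            raise ValueError("wte contains non-finite values")
        if np.any(self.wte < -_SUM_TOL):
            raise ValueError("wte contains negative cells")
        np.clip(self.wte, 0.0, None, out=self.wte)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_min + self.wte.shape[0])

    @property
    def age_max(self) -> int:
        return self.age_min + self.wte.shape[0] - 1

    def copy(self) -> "CohortGrid":
        return CohortGrid(self.wte.copy(), age_min=self.age_min, year=self.year)

    def total(self, origin: str | None = None, gender: str | None = None) -> float:
        return total_stock(self, origin=origin, gender=gender)


@dataclass
class RateSchedule:
    """Annual exit fractions by (age, gender, origin).

    Three components: ``retirement``, ``emigration``, ``attrition`` (net
    attrition), each an array matching the cohort grid's shape.
    Validated at construction: retirement and emigration in [0, 1],
    attrition in [-1, 1], per-cell component sum ≤ 1 (never silently
    clipped), and full forced retirement at the top age.
    """

    retirement: np.ndarray
    emigration: np.ndarray
    attrition: np.ndarray
    age_min: int = 20

    def __post_init__(self) -> None:
        self.retirement = np.asarray(self.retirement, dtype=float)
        self.emigration = np.asarray(self.emigration, dtype=float)
        self.attrition = np.asarray(self.attrition, dtype=float)
        shape = self.retirement.shape
        if self.emigration.shape != shape or self.attrition.shape != shape:
            raise ValueError("rate components must share one (age, gender, origin) shape")
        if len(shape) != 3 or shape[1:] != (len(GENDERS), len(ORIGINS)):
            raise ValueError(
                f"rates must have shape (n_ages, {len(GENDERS)}, {len(ORIGINS)}), "
                f"got {shape}"
            )
        for name, arr in (("retirement", self.retirement), ("emigration", self.emigration)):
            if np.any(arr < -_SUM_TOL) or np.any(arr > 1 + _SUM_TOL):
                raise ValueError(f"{name} rates must lie in [0, 1]")
        if np.any(self.attrition < -1 - _SUM_TOL) or np.any(self.attrition > 1 + _SUM_TOL):
            raise ValueError("attrition rates must lie in [-1, 1]")
        total = self.retirement + self.emigration + self.attrition
        if np.any(total > 1 + _SUM_TOL):
            bad = np.argwhere(total > 1 + _SUM_TOL)[0]
            raise ValueError(
                "per-cell outflow rates sum to more than 1 (first offending cell: "
                f"age {self.age_min + bad[0]}, {GENDERS[bad[1]]}, {ORIGINS[bad[2]]})"
            )
        # Forced full retirement of the oldest cohort.
        if not np.allclose(self.retirement[-1], 1.0, atol=_SUM_TOL):
            raise ValueError(
                "retirement rate at the maximum working age must be 1 (forced exit)"
            )
        if not (
            np.allclose(self.emigration[-1], 0.0, atol=_SUM_TOL)
            and np.allclose(self.attrition[-1], 0.0, atol=_SUM_TOL)
        ):
            raise ValueError(
                "emigration and attrition at the maximum working age must be 0"
            )

    @property
    def total_rate(self) -> np.ndarray:
        return self.retirement + self.emigration + self.attrition


@dataclass
class OutflowLedger:
    """One year's outflows, broken down by gender × origin.

    Each component is a ``(2, 2)`` array (gender, origin) in WTE.
    """

    retirement: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    emigration: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    attrition: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    @property
    def retirement_wte(self) -> float:
        return float(self.retirement.sum())

    @property
    def emigration_wte(self) -> float:
        return float(self.emigration.sum())

    @property
    def attrition_wte(self) -> float:
        return float(self.attrition.sum())

    @property
    def total(self) -> float:
        return self.retirement_wte + self.emigration_wte + self.attrition_wte


def advance_year(grid: CohortGrid, rates: RateSchedule) -> tuple[CohortGrid, OutflowLedger]:
    """Apply one year of outflows and ageing (no entrants).

    Outflows are computed on the start-of-year stock; survivors shift up
    one year of age.  WTE is conserved exactly: total(in) =
    total(survivors) + total(outflows).
    """
    if rates.retirement.shape != grid.wte.shape or rates.age_min != grid.age_min:
        raise ValueError("grid and rate schedule must share the age/gender/origin index")
    ret = grid.wte * rates.retirement
    emi = grid.wte * rates.emigration
    att = grid.wte * rates.attrition
    survivors = grid.wte - ret - emi - att
    new = np.zeros_like(grid.wte)
    new[1:] = survivors[:-1]  # top-age survivors are zero by forced retirement
    out = OutflowLedger(
        retirement=ret.sum(axis=0),
        emigration=emi.sum(axis=0),
        attrition=att.sum(axis=0),
    )
    return CohortGrid(new, age_min=grid.age_min, year=grid.year + 1), out


def allocate_entrants(
    grid: CohortGrid,
    count: float,
    origin: str,
    entrant_distribution: np.ndarray,
) -> CohortGrid:
    """Add ``count`` WTE of entrants of the given origin to the grid.

    ``entrant_distribution`` is an (age, gender) probability mass array
    (shape ``(n_ages, 2)``) summing to 1.  Returns a new grid whose total
    rises by exactly ``count``.
    """
    if count < 0:
        raise ValueError(f"entrant count must be non-negative, got {count}")
    dist = np.asarray(entrant_distribution, dtype=float)
    if dist.shape != grid.wte.shape[:2]:
        raise ValueError(
            f"entrant distribution must have shape {grid.wte.shape[:2]}, got {dist.shape}"
        )
    if np.any(dist < -_SUM_TOL) or abs(dist.sum() - 1.0) > 1e-8:
        raise ValueError("entrant distribution must be non-negative and sum to 1")
    k = _axis_index(origin, ORIGINS, "origin")
    new = grid.wte.copy()
    new[:, :, k] += count * dist
    return CohortGrid(new, age_min=grid.age_min, year=grid.year)


def total_stock(
    grid: CohortGrid, origin: str | None = None, gender: str | None = None
) -> float:
    """Total WTE in the grid, optionally filtered by origin and/or gender."""
    sel = grid.wte
    if gender is not None:
        sel = sel[:, [_axis_index(gender, GENDERS, "gender")], :]
    if origin is not None:
        sel = sel[:, :, [_axis_index(origin, ORIGINS, "origin")]]
    return float(sel.sum())


# -- register-style CSV interchange -------------------------------------

def grid_to_frame(grid: CohortGrid) -> pd.DataFrame:
    """Long-format frame with columns age, gender, origin, wte."""
    rows = []
    for i, age in enumerate(grid.ages):
        for g, gender in enumerate(GENDERS):
            for k, origin in enumerate(ORIGINS):
                rows.append((int(age), gender, origin, grid.wte[i, g, k]))
    return pd.DataFrame(rows, columns=["age", "gender", "origin", "wte"])


def grid_from_frame(frame: pd.DataFrame, year: int = 2021) -> CohortGrid:
    """Rebuild a cohort grid from a long-format stocks frame."""
    required = {"age", "gender", "origin", "wte"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"stocks table is missing columns: {sorted(missing)}")
    ages = np.sort(frame["age"].unique())
    age_min = int(ages[0])
    n = int(ages[-1]) - age_min + 1
    wte = np.zeros((n, len(GENDERS), len(ORIGINS)))
    for _, row in frame.iterrows():
        i = int(row["age"]) - age_min
        g = _axis_index(str(row["gender"]), GENDERS, "gender")
        k = _axis_index(str(row["origin"]), ORIGINS, "origin")
        wte[i, g, k] += float(row["wte"])
    return CohortGrid(wte, age_min=age_min, year=year)


def rates_to_frame(rates: RateSchedule) -> pd.DataFrame:
    """Long-format frame with one row per (age, gender, origin) cell."""
    n = rates.retirement.shape[0]
    rows = []
    for i in range(n):
        for g, gender in enumerate(GENDERS):
            for k, origin in enumerate(ORIGINS):
                rows.append(
                    (
                        rates.age_min + i,
                        gender,
                        origin,
                        rates.retirement[i, g, k],
                        rates.emigration[i, g, k],
                        rates.attrition[i, g, k],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "age",
            "gender",
            "origin",
            "retirement_rate",
            "emigration_rate",
            "attrition_rate",
        ],
    )


def rates_from_frame(frame: pd.DataFrame) -> RateSchedule:
    """Rebuild a rate schedule from a long-format rates frame."""
    required = {
        "age",
        "gender",
        "origin",
        "retirement_rate",
        "emigration_rate",
        "attrition_rate",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"rates table is missing columns: {sorted(missing)}")
    ages = np.sort(frame["age"].unique())
    age_min = int(ages[0])
    n = int(ages[-1]) - age_min + 1
    shape = (n, len(GENDERS), len(ORIGINS))
    ret = np.zeros(shape)
    emi = np.zeros(shape)
    att = np.zeros(shape)
    for _, row in frame.iterrows():
        i = int(row["age"]) - age_min
        g = _axis_index(str(row["gender"]), GENDERS, "gender")
        k = _axis_index(str(row["origin"]), ORIGINS, "origin")
        ret[i, g, k] = float(row["retirement_rate"])
        emi[i, g, k] = float(row["emigration_rate"])
        att[i, g, k] = float(row["attrition_rate"])
    return RateSchedule(ret, emi, att, age_min=age_min)
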