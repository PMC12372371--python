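"""Recruitment requirement and the gap-filling foreign-recruitment rule.

The recruitment requirement in a year is *expansion demand* (the growth
in aggregate demand realised over that year) plus *replacement demand*
(the sum of all outflows — retirement, emigration, net attrition — from
the start-of-year stock).  Whatever part of the requirement the domestic
education pipeline does not supply is filled by foreign-educated
recruits; if domestic inflow exceeds the requirement, nobody is forced
out and the surplus is retained (logged as ``surplus_wte``).

An annual ledger row is labelled by its start year t: it records the
start-of-year stocks and demand, the flows during year t, and the
requirement toward next year's demand (expansion = D_{t+1} − D_t), so
that in gap-filling years the end-of-year stock equals D_{t+1} exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .demand import DemandParams, expansion_demand, project_demand
from .education import PipelineParams, inflow_series
from .workforce import (
    CohortGrid,
    RateSchedule,
    advance_year,
    allocate_entrants,
    total_stock,
)

__all__ = [
    "ModelParams",
    "recruitment_requirement",
    "foreign_recruitment",
    "run_year",
    "simulate",
    "LEDGER_COLUMNS",
    "validate_ledger",
]

LEDGER_COLUMNS = [
    "demand_wte",
    "stock_total_wte",
    "stock_domestic_wte",
    "stock_foreign_wte",
    "expansion_wte",
    "replacement_wte",
    "retirement_wte",
    "emigration_wte",
    "attrition_wte",
    "domestic_inflow_wte",
    "foreign_recruits_wte",
    "recruitment_requirement_wte",
    "surplus_wte",
]


@dataclass
class ModelParams:
    """Everything a scenario run needs: demand, stocks, rates, pipeline."""

    demand: DemandParams
    grid: CohortGrid
    rates: RateSchedule
    pipeline: PipelineParams
    foreign_entrant_distribution: np.ndarray

    def copy(self) -> "ModelParams":
        return ModelParams(
            demand=self.demand,
            grid=self.grid.copy(),
            rates=RateSchedule(
                self.rates.retirement.copy(),
                self.rates.emigration.copy(),
                self.rates.attrition.copy(),
                age_min=self.rates.age_min,
            ),
            pipeline=replace(self.pipeline),
            foreign_entrant_distribution=self.foreign_entrant_distribution.copy(),
        )

    def demand_series_extended(self) -> pd.Series:
        """Demand projected one year past the horizon (for the final row's expansion)."""
        ext = replace(self.demand, horizon_years=self.demand.horizon_years + 1)
        return project_demand(ext)


def recruitment_requirement(expansion: float, replacement: float) -> float:
    """Expansion demand plus replacement demand.

    Expansion may be negative (shrinking demand offsets replacement);
    replacement, as a sum of outflows under valid schedules, may not.
    """
    if replacement < 0:
        raise ValueError(f"replacement demand must be non-negative, got {replacement}")
    return expansion + replacement


def foreign_recruitment(requirement: float, domestic_inflow: float) -> float:
    """Gap rule: foreign recruits fill the requirement left by domestic inflow.

    Never negative — a domestic surplus is retained, not offset by
    forced exits.
    """
    if not (np.isfinite(requirement) and np.isfinite(domestic_inflow)):
        raise ValueError("requirement and domestic_inflow must be finite")
    return max(0.0, requirement - domestic_inflow)


def run_year(
    grid: CohortGrid,
    rates: RateSchedule,
    demand: pd.Series,
    inflow: pd.Series | float,
    year: int,
    *,
    domestic_distribution: np.ndarray,
    foreign_distribution: np.ndarray,
) -> tuple[CohortGrid, dict]:
    """Advance the model through one calendar year.

    Composes: outflows/ageing → expansion + replacement → requirement →
    gap-filling foreign recruitment → entrant allocation (domestic
    inflow, then foreign recruits).  Returns the start-of-next-year grid
    and the ledger row for ``year``.
    """
    if year not in demand.index or year + 1 not in demand.index:
        raise KeyError(
            f"simulating year {year} requires demand for {year} and {year + 1}"
        )
    inflow_t = float(inflow.loc[year]) if isinstance(inflow, pd.Series) else float(inflow)

    aged, outflows = advance_year(grid, rates)
    expansion = expansion_demand(demand, year + 1)
    replacement = outflows.total
    requirement = recruitment_requirement(expansion, replacement)
    foreign = foreign_recruitment(requirement, inflow_t)
    surplus = max(0.0, inflow_t - requirement)

    nxt = allocate_entrants(aged, inflow_t, "domestic", domestic_distribution)
    nxt = allocate_entrants(nxt, foreign, "foreign", foreign_distribution)

    row = {
        "year": year,
        "demand_wte": float(demand.loc[year]),
        "stock_total_wte": total_stock(grid),
        "stock_domestic_wte": total_stock(grid, origin="domestic"),
        "stock_foreign_wte": total_stock(grid, origin="foreign"),
        "expansion_wte": expansion,
        "replacement_wte": replacement,
        "retirement_wte": outflows.retirement_wte,
        "emigration_wte": outflows.emigration_wte,
        "attrition_wte": outflows.attrition_wte,
        "domestic_inflow_wte": inflow_t,
        "foreign_recruits_wte": foreign,
        "recruitment_requirement_wte": requirement,
        "surplus_wte": surplus,
    }
    return nxt, row


def simulate(params: ModelParams, intake_schedule: dict[int, float]) -> pd.DataFrame:
    """Run the full horizon with a fixed intake schedule.

    Returns the annual ledger: one row per year from the base year to
    the end of the horizon, indexed by year, including the intake and
    graduate columns implied by the schedule.
    """
    demand = params.demand_series_extended()
    base = params.demand.base_year
    years = list(range(base, base + params.demand.horizon_years + 1))
    inflow = inflow_series(intake_schedule, params.pipeline, years)

    grid = params.grid.copy()
    rows = []
    for year in years:
        grid, row = run_year(
            grid,
            params.rates,
            demand,
            inflow,
            year,
            domestic_distribution=params.pipeline.entrant_distribution,
            foreign_distribution=params.foreign_entrant_distribution,
        )
        rows.append(row)
    ledger = pd.DataFrame(rows).set_index("year")
    ledger["intake_places"] = [
        intake_schedule.get(y, np.nan) for y in ledger.index
    ]
    ledger["graduates"] = [
        params.pipeline.places_to_graduates(
            intake_schedule[y - params.pipeline.course_length]
        )
        for y in ledger.index
    ]
    return ledger


def validate_ledger(ledger: pd.DataFrame, rtol: float = 1e-9) -> None:
    """Assert the ledger's accounting identities (raises AssertionError)."""
    lhs = ledger["recruitment_requirement_wte"]
    rhs = ledger["expansion_wte"] + ledger["replacement_wte"]
    assert np.allclose(lhs, rhs, rtol=rtol), "requirement != expansion + replacement"
    assert (ledger["foreign_recruits_wte"] >= 0).all(), "negative foreign recruitment"
    assert np.allclose(
        ledger["stock_total_wte"],
        ledger["stock_domestic_wte"] + ledger["stock_foreign_wte"],
        rtol=rtol,
    ), "stock split does not add up"
    assert np.allclose(
        ledger["replacement_wte"],
        ledger[["retirement_wte", "emigration_wte", "attrition_wte"]].sum(axis=1),
        rtol=rtol,
    ), "replacement != sum of outflow components"
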