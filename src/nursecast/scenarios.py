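"""Policy scenarios: intake trajectories and full-horizon runs.

Three named scenarios:

* **A** — baseline: student intake stays at its historical level for the
  whole horizon; demand growth is met by foreign recruitment.
* **B** — rapid reform: intake ramps up from 2024 so that the domestic
  graduate inflow (in WTE) equals the recruitment requirement by the
  2030 intake year; with the four-year course lag, inflow parity — and
  hence the end of foreign recruitment — arrives in 2034.
* **C** — slow reform: as B but reaching the self-sufficiency intake by
  2040, giving inflow parity in 2044.

The ramp is linear in places.  Interior ramp years use a provisional
self-sufficiency level taken from a constant-intake reference run; from
the target year onwards, each intake year's places are set by an exact
course-length-ahead forecast of the recruitment requirement, obtained by
simulating forward from the current state with already-planned inflows
and the gap rule.  Because every inflow in the forecast window is already
fixed by earlier intakes, the forecast coincides with the realised run
and domestic inflow matches the requirement exactly from
``intake_target_year + course_length`` onwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recruitment import ModelParams, run_year, simulate

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "scenario",
    "build_intake_schedule",
    "run_scenario",
    "self_sufficiency_year",
]

INTAKE_RULES = ("constant", "ramp_to_self_sufficiency")


@dataclass
class ScenarioSpec:
    """A scenario's intake trajectory rule plus optional overrides."""

    name: str
    intake_rule: str = "constant"
    ramp_start_year: int = 2024
    intake_target_year: int | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intake_rule not in INTAKE_RULES:
            raise ValueError(
                f"unknown intake_rule {self.intake_rule!r}; expected one of {INTAKE_RULES}"
            )
        if self.intake_rule == "ramp_to_self_sufficiency":
            if self.intake_target_year is None:
                raise ValueError("ramp_to_self_sufficiency requires intake_target_year")
            if not self.ramp_start_year < self.intake_target_year:
                raise ValueError(
                    f"ramp_start_year ({self.ramp_start_year}) must precede "
                    f"intake_target_year ({self.intake_target_year})"
                )


SCENARIOS = {
    "A": ScenarioSpec(name="A", intake_rule="constant"),
    "B": ScenarioSpec(
        name="B",
        intake_rule="ramp_to_self_sufficiency",
        ramp_start_year=2024,
        intake_target_year=2030,
    ),
    "C": ScenarioSpec(
        name="C",
        intake_rule="ramp_to_self_sufficiency",
        ramp_start_year=2024,
        intake_target_year=2040,
    ),
}


def scenario(name: str) -> ScenarioSpec:
    """Look up one of the named scenarios A/B/C."""
    try:
        return SCENARIOS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


def _forecast_requirement(
    grid, params: ModelParams, demand: pd.Series, schedule: dict[int, float],
    start_year: int, target_year: int,
) -> float:
    """Recruitment requirement at ``target_year``, forecast from the state at ``start_year``.

    Simulates ``start_year .. target_year`` with planned inflows and the
    gap rule; requirement at the target year does not depend on that
    year's own inflow, so a placeholder of zero is passed for it.
    """
    pipe = params.pipeline
    g = grid.copy()
    for y in range(start_year, target_year):
        inflow = pipe.graduates_to_wte(
            pipe.places_to_graduates(schedule[y - pipe.course_length])
        )
        g, _ = run_year(
            g, params.rates, demand, inflow, y,
            domestic_distribution=pipe.entrant_distribution,
            foreign_distribution=params.foreign_entrant_distribution,
        )
    _, row = run_year(
        g, params.rates, demand, 0.0, target_year,
        domestic_distribution=pipe.entrant_distribution,
        foreign_distribution=params.foreign_entrant_distribution,
    )
    return row["recruitment_requirement_wte"]


def build_intake_schedule(spec: ScenarioSpec, params: ModelParams) -> dict[int, float]:
    """Places per intake year, from ``base - course_length`` to the horizon end.

    Constant rule: the historical intake level everywhere.  Ramp rule:
    historical level up to ``ramp_start_year - 1``, a linear ramp in
    places reaching a provisional self-sufficiency level at the target
    year, then exact forecast-tracking intakes (see module docstring).
    Intake years too late to affect the horizon hold the last decided
    level.
    """
    pipe = params.pipeline
    base = params.demand.base_year
    horizon_end = base + params.demand.horizon_years
    lag = pipe.course_length
    years = list(range(base - lag, horizon_end + 1))
    schedule = {y: pipe.intake_at(y) for y in years}
    if spec.intake_rule == "constant":
        return schedule

    target = spec.intake_target_year
    if target + lag > horizon_end:
        raise ValueError(
            f"intake_target_year + course_length ({target + lag}) exceeds the "
            f"horizon end ({horizon_end}); the scenario cannot converge in view"
        )
    if spec.ramp_start_year < base:
        raise ValueError(
            f"ramp_start_year ({spec.ramp_start_year}) precedes the base year ({base})"
        )

    demand = params.demand_series_extended()

    # Provisional self-sufficiency level from a constant-intake reference
    # run; only shapes the interior of the ramp.
    reference = simulate(params, dict(schedule))
    level = pipe.required_places(
        reference.loc[target + lag, "recruitment_requirement_wte"]
    )

    # Linear ramp anchored one year before ramp_start so that places
    # already rise in the ramp_start year itself.
    anchor = spec.ramp_start_year - 1
    baseline_level = pipe.intake_at(anchor)
    for t in range(spec.ramp_start_year, target):
        frac = (t - anchor) / (target - anchor)
        schedule[t] = baseline_level + (level - baseline_level) * frac

    # Exact forecast-tracking decisions from the target year onward,
    # taken sequentially while replaying the model.
    last_decision_year = horizon_end - lag
    grid = params.grid.copy()
    for y in range(base, horizon_end + 1):
        if target <= y <= last_decision_year:
            schedule[y] = pipe.required_places(
                _forecast_requirement(grid, params, demand, schedule, y, y + lag)
            )
        elif y > last_decision_year and y >= target:
            schedule[y] = schedule[last_decision_year]
        inflow = pipe.graduates_to_wte(
            pipe.places_to_graduates(schedule[y - lag])
        )
        grid, _ = run_year(
            grid, params.rates, demand, inflow, y,
            domestic_distribution=pipe.entrant_distribution,
            foreign_distribution=params.foreign_entrant_distribution,
        )
    return schedule


def run_scenario(spec: ScenarioSpec, params: ModelParams) -> pd.DataFrame:
    """Full-horizon annual ledger for a scenario."""
    schedule = build_intake_schedule(spec, params)
    return simulate(params, schedule)


def self_sufficiency_year(ledger: pd.DataFrame, atol: float = 1e-6) -> int | None:
    """First year with no foreign recruitment and domestic inflow ≥ requirement.

    Returns ``None`` if the ledger never reaches self-sufficiency.
    """
    hit = (ledger["foreign_recruits_wte"] <= atol) & (
        ledger["domestic_inflow_wte"]
        >= ledger["recruitment_requirement_wte"] - atol
    )
    if not hit.any():
        return None
    return int(ledger.index[hit][0])
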