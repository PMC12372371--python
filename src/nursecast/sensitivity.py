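"""One-at-a-time ±15 % sensitivity analysis.

Two parameters carry the most uncertainty and are perturbed one at a
time by ±15 %: the demand growth rate and the net attrition schedule
(every age/gender/origin cell scaled by the same factor).  Outputs are
end-of-horizon demand and recruitment requirement, with percent changes
against the unperturbed baseline run.

Demand is structurally independent of attrition, so the attrition rows
leave the demand column unchanged by construction.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .recruitment import ModelParams
from .scenarios import run_scenario, scenario
from .workforce import RateSchedule

__all__ = ["PARAMETERS", "perturb", "sensitivity_table"]

PARAMETERS = ("demand_growth_rate", "net_attrition_rate")


def perturb(params: ModelParams, parameter: str, multiplier: float) -> ModelParams:
    """Return a copy of ``params`` with one parameter scaled; all else untouched."""
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    if parameter not in PARAMETERS:
        raise ValueError(
            f"unknown sensitivity parameter {parameter!r}; valid names: {list(PARAMETERS)}"
        )
    out = params.copy()
    if parameter == "demand_growth_rate":
        out.demand = replace(out.demand, growth_rate=out.demand.growth_rate * multiplier)
    else:
        att = out.rates.attrition * multiplier
        att[-1] = 0.0  # forced-retirement row carries no attrition
        # Reconstruct so the scaled schedule is revalidated (sum ≤ 1 etc.).
        out.rates = RateSchedule(
            out.rates.retirement.copy(),
            out.rates.emigration.copy(),
            att,
            age_min=out.rates.age_min,
        )
    return out


def sensitivity_table(params: ModelParams) -> pd.DataFrame:
    """Replicate the one-at-a-time sensitivity table on the baseline scenario.

    Rows: baseline, then growth ±15 % and attrition ±15 %.  Columns give
    end-of-horizon (2051 under defaults) demand and recruitment
    requirement, their raw percent changes against baseline, and the
    end-year expansion demand (a diagnostic: attrition rows must leave
    it untouched).
    """
    end_year = params.demand.base_year + params.demand.horizon_years
    spec = scenario("A")

    def _run(p: ModelParams) -> pd.Series:
        return run_scenario(spec, p).loc[end_year]

    base = _run(params)
    rows = [
        {
            "parameter": "baseline",
            "multiplier": 1.0,
            "demand_end_wte": base["demand_wte"],
            "demand_pct_change": 0.0,
            "rr_end_wte": base["recruitment_requirement_wte"],
            "rr_pct_change": 0.0,
            "expansion_end_wte": base["expansion_wte"],
        }
    ]
    for parameter in PARAMETERS:
        for multiplier in (1.15, 0.85):
            end = _run(perturb(params, parameter, multiplier))
            rows.append(
                {
                    "parameter": parameter,
                    "multiplier": multiplier,
                    "demand_end_wte": end["demand_wte"],
                    "demand_pct_change": 100.0
                    * (end["demand_wte"] / base["demand_wte"] - 1.0),
                    "rr_end_wte": end["recruitment_requirement_wte"],
                    "rr_pct_change": 100.0
                    * (
                        end["recruitment_requirement_wte"]
                        / base["recruitment_requirement_wte"]
                        - 1.0
                    ),
                    "expansion_end_wte": end["expansion_wte"],
                }
            )
    return pd.DataFrame(rows)
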