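"""Aggregate demand projection.

Demand for professionally active nurses and midwives is modelled in the
aggregate, in whole-time equivalents (WTE), growing at a compound annual
rate from a base-year level.  The year-on-year increase in demand is the
*expansion demand*: the number of additional WTEs the workforce must gain
in a year purely because demand has grown.

Demand is structurally independent of every supply-side parameter
(attrition, emigration, retirement, student intake); the sensitivity
analysis relies on this invariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DemandParams", "project_demand", "expansion_demand"]


@dataclass(frozen=True)
class DemandParams:
    """Parameters of the compound-growth demand projection.

    Attributes
    ----------
    base_year : int
        First calendar year of the projection (stock anchor year).
    base_demand : float
        Demand in the base year, in WTE.
    growth_rate : float
        Compound annual growth rate as a dimensionless fraction
        (0.014 means 1.4 % per year).
    horizon_years : int
        Number of years projected beyond the base year.
    """

    base_year: int = 2021
    base_demand: float = 64_383.0
    growth_rate: float = 0.014
    horizon_years: int = 30

    def __post_init__(self) -> None:
        if not self.base_demand > 0:
            raise ValueError(f"base_demand must be positive, got {self.base_demand}")
        if not self.growth_rate > -1:
            raise ValueError(f"growth_rate must exceed -1, got {self.growth_rate}")
        if self.horizon_years < 0:
            raise ValueError(
                f"horizon_years must be non-negative, got {self.horizon_years}"
            )


def project_demand(params: DemandParams) -> pd.Series:
    """Project aggregate WTE demand over the horizon.

    Returns a series indexed by calendar year, ``base_year`` through
    ``base_year + horizon_years`` inclusive, with
    ``D_t = base_demand * (1 + growth_rate) ** (t - base_year)``.
    """
    years = np.arange(params.base_year, params.base_year + params.horizon_years + 1)
    values = params.base_demand * (1.0 + params.growth_rate) ** (
        years - params.base_year
    )
    return pd.Series(values, index=years, name="demand_wte")


def expansion_demand(demand: pd.Series, year: int) -> float:
    """Year-on-year demand increase attributed to ``year``.

    Backward difference ``D_year - D_{year-1}``: the recruitment made
    during the run-up to ``year`` fills the demand growth realised in
    ``year``.  Negative when demand shrinks.
    """
    # Convention: backward difference D_t - D_{t-1} attributed to year t.
    # A forward-difference convention would shift every expansion figure
    # by one year; the backward form makes year-t recruits fill year-t
    # demand growth.
    if year - 1 not in demand.index or year not in demand.index:
        raise KeyError(
            f"expansion demand for {year} requires demand values for both "
            f"{year - 1} and {year}; series covers "
            f"{demand.index.min()}..{demand.index.max()}"
        )
    return float(demand.loc[year] - demand.loc[year - 1])
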