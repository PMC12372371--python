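"""Domestic education pipeline: student places → graduates → WTE inflow.

The pipeline is a fixed multiplicative chain with a course-length lag:
places admitted in year t yield ``places × completion_rate`` graduates in
year ``t + course_length``, of whom ``× wte_conversion`` become
professionally active domestic WTE inflow that same year.  The chain is
exactly invertible, which is how the required number of student places is
recovered from a target WTE inflow.

Default ratios are calibrated to the anchored chain
3,019 WTE ← 3,495 graduates ← 3,965 places
(completion ≈ 0.8815, WTE conversion ≈ 0.8638).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["PipelineParams", "inflow_series"]

# Anchored calibration chain: WTE target, graduates, places.
CHAIN_WTE = 3_019.0
CHAIN_GRADUATES = 3_495.0
CHAIN_PLACES = 3_965.0

DEFAULT_COMPLETION_RATE = CHAIN_GRADUATES / CHAIN_PLACES
DEFAULT_WTE_CONVERSION = CHAIN_WTE / CHAIN_GRADUATES

# Constant annual domestic WTE inflow under the no-reform baseline.
BASELINE_DOMESTIC_INFLOW = 1_469.0


@dataclass
class PipelineParams:
    """Education pipeline parameters.

    Attributes
    ----------
    course_length : int
        Degree duration in years (lag between intake and inflow).
    completion_rate : float
        Fraction of admitted places that yield graduates, in (0, 1].
    wte_conversion : float
        Fraction of graduates converting to professionally active WTE
        inflow, in (0, 1].
    entrant_distribution : ndarray or None
        (age, gender) probability mass over which new domestic WTEs are
        spread when entering the stocks; supplied by the fixture
        generator or the config.
    historical_intake : float or mapping year → places
        Intake in years before (and, for the constant rule, during) the
        projection; a scalar means the same intake every year.  The
        default reproduces the baseline inflow of 1,469 WTE/yr.
    """

    course_length: int = 4
    completion_rate: float = DEFAULT_COMPLETION_RATE
    wte_conversion: float = DEFAULT_WTE_CONVERSION
    entrant_distribution: np.ndarray | None = None
    historical_intake: float | Mapping[int, float] = field(
        default_factory=lambda: BASELINE_DOMESTIC_INFLOW
        / (DEFAULT_COMPLETION_RATE * DEFAULT_WTE_CONVERSION)
    )

    def __post_init__(self) -> None:
        if not (isinstance(self.course_length, (int, np.integer)) and self.course_length >= 1):
            raise ValueError(f"course_length must be an integer ≥ 1, got {self.course_length}")
        if not 0 < self.completion_rate <= 1:
            raise ValueError(f"completion_rate must lie in (0, 1], got {self.completion_rate}")
        if not 0 < self.wte_conversion <= 1:
            raise ValueError(f"wte_conversion must lie in (0, 1], got {self.wte_conversion}")

    # -- the forward chain -------------------------------------------------

    def places_to_graduates(self, places: float) -> float:
        """Graduates produced by an intake of ``places`` (realised after the lag)."""
        if places < 0:
            raise ValueError(f"places must be non-negative, got {places}")
        return places * self.completion_rate

    def graduates_to_wte(self, graduates: float) -> float:
        """Professionally active WTE inflow from a graduating class."""
        if graduates < 0:
            raise ValueError(f"graduates must be non-negative, got {graduates}")
        return graduates * self.wte_conversion

    def overall_conversion(self) -> float:
        """Places → WTE conversion of the whole chain."""
        return self.completion_rate * self.wte_conversion

    # -- the inverse chain -------------------------------------------------

    def required_places(self, target_wte: float) -> float:
        """Student places needed (course_length years earlier) for a WTE inflow target.

        Exact inverse of the forward chain.
        """
        if target_wte < 0:
            raise ValueError(f"target_wte must be non-negative, got {target_wte}")
        return target_wte / self.overall_conversion()

    def intake_at(self, year: int) -> float:
        """Historical/default intake (places) in a given year."""
        if isinstance(self.historical_intake, Mapping):
            if year in self.historical_intake:
                return float(self.historical_intake[year])
            # extend the latest recorded intake forward
            known = sorted(self.historical_intake)
            if known and year > known[-1]:
                return float(self.historical_intake[known[-1]])
            raise KeyError(
                f"no historical intake recorded for year {year}; "
                f"known years: {known}"
            )
        return float(self.historical_intake)


def inflow_series(
    intake_schedule: Mapping[int, float],
    pipeline: PipelineParams,
    years: Iterable[int],
) -> pd.Series:
    """Domestic WTE inflow per year from an intake schedule.

    ``inflow_t = intake_{t - course_length} × completion × conversion``.
    Raises if the schedule is missing any needed intake year, listing
    them all.
    """
    years = list(years)
    missing = [y - pipeline.course_length for y in years if y - pipeline.course_length not in intake_schedule]
    if missing:
        raise KeyError(
            f"intake schedule is missing years {missing} "
            f"(needed for inflow in {[y + pipeline.course_length for y in missing]})"
        )
    values = [
        pipeline.graduates_to_wte(
            pipeline.places_to_graduates(intake_schedule[y - pipeline.course_length])
        )
        for y in years
    ]
    return pd.Series(values, index=pd.Index(years, name="year"), name="domestic_inflow_wte")
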