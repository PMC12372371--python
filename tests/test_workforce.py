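"""Cohort stocks, exit schedules, and the annual ageing/outflow step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nursecast.workforce import (
    CohortGrid,
    RateSchedule,
    advance_year,
    allocate_entrants,
    grid_from_frame,
    grid_to_frame,
    rates_from_frame,
    rates_to_frame,
    total_stock,
)

N_AGES = 51  # ages 20..70


def make_grid(cells=None, age_min=20):
    wte = np.zeros((N_AGES, 2, 2))
    for (age, g, k), value in (cells or {}).items():
        wte[age - age_min, g, k] = value
    return CohortGrid(wte, age_min=age_min, year=2021)


def uniform_rates(ret=0.0, emi=0.0, att=0.0):
    shape = (N_AGES, 2, 2)
    r, e, a = np.full(shape, ret), np.full(shape, emi), np.full(shape, att)
    r[-1], e[-1], a[-1] = 1.0, 0.0, 0.0
    return RateSchedule(r, e, a)


class TestAdvanceYear:
    def test_single_cell_arithmetic(self):
        grid = make_grid({(40, 0, 0): 100.0})
        nxt, out = advance_year(grid, uniform_rates(0.02, 0.01, 0.01))
        assert nxt.wte[41 - 20, 0, 0] == pytest.approx(96.0)
        assert (out.retirement_wte, out.emigration_wte, out.attrition_wte) == (
            pytest.approx(2.0),
            pytest.approx(1.0),
            pytest.approx(1.0),
        )
        assert nxt.year == 2022

    def test_zero_rates_pure_ageing_shift(self):
        rng = np.random.default_rng(7)
        wte = np.zeros((N_AGES, 2, 2))
        wte[:30] = rng.uniform(0, 50, size=(30, 2, 2))
        grid = CohortGrid(wte, year=2021)
        nxt, out = advance_year(grid, uniform_rates())
        assert out.total == 0.0
        assert np.array_equal(nxt.wte[1:31], wte[:30])
        assert nxt.wte[0].sum() == 0.0

    def test_forced_exit_at_maximum_working_age(self):
        grid = make_grid({(70, 1, 1): 10.0})
        nxt, out = advance_year(grid, uniform_rates())
        assert total_stock(nxt) == 0.0
        assert out.retirement_wte == pytest.approx(10.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_identity(self, seed):
        """in = survivors + retirement + emigration + attrition, any valid inputs."""
        rng = np.random.default_rng(seed)
        grid = CohortGrid(rng.uniform(0, 1000, size=(N_AGES, 2, 2)), year=2021)
        parts = rng.dirichlet([1, 1, 1, 5], size=(N_AGES, 2, 2))
        r, e, a = parts[..., 0], parts[..., 1], parts[..., 2]
        r[-1], e[-1], a[-1] = 1.0, 0.0, 0.0
        rates = RateSchedule(r, e, a)
        nxt, out = advance_year(grid, rates)
        assert total_stock(nxt) + out.total == pytest.approx(
            total_stock(grid), rel=1e-9
        )
        assert (nxt.wte >= 0).all()

    def test_scalar_recursion_oracle_under_age_uniform_rates(self):
        """Age-structured totals equal S' = S(1-r) + inflow when rates are age-uniform."""
        rng = np.random.default_rng(3)
        wte = np.zeros((N_AGES, 2, 2))
        wte[:20] = rng.uniform(0, 100, size=(20, 2, 2))  # nobody near the top age
        grid = CohortGrid(wte, year=2021)
        rates = uniform_rates(0.015, 0.01, 0.015)
        dist = np.zeros((N_AGES, 2))
        dist[2, 0] = 1.0  # entrants at age 22
        inflow = 321.5
        expected = total_stock(grid)
        for _ in range(10):
            grid, _ = advance_year(grid, rates)
            grid = allocate_entrants(grid, inflow, "domestic", dist)
            expected = expected * (1 - 0.04) + inflow
            assert total_stock(grid) == pytest.approx(expected, rel=1e-12)

    def test_mismatched_index_rejected(self):
        grid = make_grid({(40, 0, 0): 1.0}, age_min=20)
        rates = uniform_rates()
        rates.age_min = 25
        with pytest.raises(ValueError, match="index"):
            advance_year(grid, rates)


class TestRateScheduleValidation:
    def test_rate_sum_above_one_rejected_not_clipped(self):
        shape = (N_AGES, 2, 2)
        r, e, a = np.full(shape, 0.5), np.full(shape, 0.4), np.full(shape, 0.2)
        r[-1], e[-1], a[-1] = 1.0, 0.0, 0.0
        with pytest.raises(ValueError, match="sum"):
            RateSchedule(r, e, a)

    def test_missing_forced_retirement_rejected(self):
        shape = (N_AGES, 2, 2)
        with pytest.raises(ValueError, match="maximum working age"):
            RateSchedule(np.zeros(shape), np.zeros(shape), np.zeros(shape))

    def test_negative_attrition_allowed_reentry(self):
        """Net attrition may be negative (re-entries exceeding exits)."""
        shape = (N_AGES, 2, 2)
        a = np.full(shape, -0.02)
        a[-1] = 0.0
        r = np.zeros(shape)
        r[-1] = 1.0
        rates = RateSchedule(r, np.zeros(shape), a)
        grid = make_grid({(40, 0, 0): 100.0})
        nxt, out = advance_year(grid, rates)
        assert total_stock(nxt) == pytest.approx(102.0)
        assert total_stock(nxt) + out.total == pytest.approx(total_stock(grid))


class TestEntrantsAndTotals:
    def test_zero_count_is_identity(self):
        grid = make_grid({(30, 0, 0): 5.0})
        dist = np.zeros((N_AGES, 2))
        dist[0, 0] = 1.0
        assert np.array_equal(
            allocate_entrants(grid, 0.0, "foreign", dist).wte, grid.wte
        )

    def test_point_mass_allocation(self):
        grid = make_grid()
        dist = np.zeros((N_AGES, 2))
        dist[25 - 20, 0] = 1.0
        out = allocate_entrants(grid, 1_469.0, "domestic", dist)
        assert out.wte[25 - 20, 0, 0] == pytest.approx(1_469.0)
        assert total_stock(out) == pytest.approx(1_469.0)

    def test_distribution_shares_respected(self):
        grid = make_grid()
        dist = np.zeros((N_AGES, 2))
        dist[3, 0], dist[5, 1] = 0.75, 0.25
        out = allocate_entrants(grid, 1_550.0, "foreign", dist)
        assert total_stock(out, origin="foreign") == pytest.approx(1_550.0)
        assert out.wte[3, 0, 1] == pytest.approx(0.75 * 1_550.0)
        assert total_stock(out, origin="domestic") == 0.0

    def test_negative_count_rejected(self):
        grid = make_grid()
        dist = np.zeros((N_AGES, 2))
        dist[0, 0] = 1.0
        with pytest.raises(ValueError, match="non-negative"):
            allocate_entrants(grid, -1.0, "domestic", dist)

    def test_empty_grid_total_is_zero(self):
        assert total_stock(make_grid()) == 0.0

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            total_stock(make_grid(), origin="elsewhere")

    def test_filters_partition_total(self, model):
        grid = model.grid
        by_origin = sum(total_stock(grid, origin=o) for o in ("domestic", "foreign"))
        by_gender = sum(total_stock(grid, gender=g) for g in ("female", "male"))
        assert by_origin == pytest.approx(total_stock(grid), rel=1e-12)
        assert by_gender == pytest.approx(total_stock(grid), rel=1e-12)


class TestRegisterRoundTrip:
    def test_grid_frame_round_trip(self, model):
        frame = grid_to_frame(model.grid)
        back = grid_from_frame(frame, year=model.grid.year)
        assert np.allclose(back.wte, model.grid.wte, rtol=1e-12)
        assert back.age_min == model.grid.age_min

    def test_rates_frame_round_trip(self, model):
        frame = rates_to_frame(model.rates)
        back = rates_from_frame(frame)
        for name in ("retirement", "emigration", "attrition"):
            assert np.allclose(
                getattr(back, name), getattr(model.rates, name), rtol=1e-12
            )

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            grid_from_frame(pd.DataFrame({"age": [20]}))
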