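"""Synthetic register generator: anchors, calibration, determinism."""

import numpy as np
import pytest

from nursecast.synthetic_data import (
    AnchorSet,
    ShapeSpec,
    calibrate,
    generate_parameters,
    make_model,
)


@pytest.fixture(scope="module")
def generated():
    return generate_parameters(ShapeSpec(seed=0))


class TestAnchors:
    def test_grid_totals_match_anchors_exactly(self, generated):
        anchors = AnchorSet()
        assert generated.grid.total() == pytest.approx(anchors.total_wte, abs=1e-6)
        assert generated.grid.total(origin="foreign") == pytest.approx(
            anchors.foreign_wte, abs=1e-6
        )

    def test_base_year_outflow_matches_replacement_anchor(self, generated):
        outflow = sum(generated.provenance["base_year_outflow_wte"].values())
        assert outflow == pytest.approx(2_118.0, rel=1e-3)
        assert outflow == pytest.approx(AnchorSet().replacement_wte, rel=1e-9)

    def test_component_split_matches_shape_spec(self, generated):
        split = ShapeSpec().outflow_split
        outflow = generated.provenance["base_year_outflow_wte"]
        total = sum(outflow.values())
        for name, share in split.items():
            assert outflow[name] / total == pytest.approx(share, rel=1e-9)

    def test_pipeline_reproduces_published_chain(self, generated):
        pipe = generated.pipeline
        assert pipe.required_places(3_019.0) == pytest.approx(3_965.0, abs=0.5)
        assert pipe.graduates_to_wte(pipe.places_to_graduates(pipe.intake_at(2017))) == (
            pytest.approx(1_469.0, abs=1e-6)
        )

    def test_anchor_residuals_negligible(self, generated):
        for value in generated.provenance["anchor_residuals"].values():
            assert abs(value) < 1e-6


class TestStructure:
    def test_schedules_satisfy_rate_invariants(self, generated):
        rates = generated.rates
        total = rates.total_rate
        assert (total[:-1] <= 1.0 + 1e-9).all()
        assert np.allclose(rates.retirement[-1], 1.0)
        assert (rates.retirement >= 0).all() and (rates.emigration >= 0).all()
        assert (rates.attrition >= 0).all()  # defaults keep net attrition non-negative

    def test_emigration_declines_and_retirement_ramps_with_age(self, generated):
        # compare age-profile means across cells
        emi = generated.rates.emigration[:-1].mean(axis=(1, 2))
        ret = generated.rates.retirement[:-1].mean(axis=(1, 2))
        assert emi[0] > emi[25] > emi[-1]
        assert ret[:25].max() == 0.0
        assert ret[-1] > ret[-10] > 0.0

    def test_entrant_distributions_are_probability_masses(self, generated):
        for dist in (
            generated.pipeline.entrant_distribution,
            generated.foreign_entrant_distribution,
        ):
            assert dist.sum() == pytest.approx(1.0)
            assert (dist >= 0).all()


class TestDeterminismAndSeeds:
    def test_same_seed_bit_identical(self):
        a = generate_parameters(ShapeSpec(seed=11))
        b = generate_parameters(ShapeSpec(seed=11))
        assert np.array_equal(a.grid.wte, b.grid.wte)
        assert np.array_equal(a.rates.attrition, b.rates.attrition)
        assert np.array_equal(a.rates.retirement, b.rates.retirement)

    def test_different_seeds_differ_but_stay_anchored(self):
        a = generate_parameters(ShapeSpec(seed=1))
        b = generate_parameters(ShapeSpec(seed=2))
        assert not np.array_equal(a.grid.wte, b.grid.wte)
        assert a.grid.total() == pytest.approx(b.grid.total(), abs=1e-6)

    def test_make_model_is_ready_to_run(self):
        params = make_model(seed=5)
        assert params.demand.base_demand == pytest.approx(64_383.0)
        assert params.grid.total() == pytest.approx(64_383.0, abs=1e-6)


class TestCalibrate:
    def test_round_trip_recovers_known_factors(self, generated):
        """Scaling calibrated schedules by 1/k must recalibrate to factors k."""
        grid, rates = generated.grid, generated.rates
        for k in (2.0, 0.5):
            schedule, factors = calibrate(
                grid,
                rates.retirement / k,
                rates.emigration / k,
                rates.attrition / k,
                AnchorSet(),
                ShapeSpec().outflow_split,
            )
            for name in ("retirement", "emigration", "attrition"):
                assert factors[name] == pytest.approx(k, rel=1e-6)
                assert np.allclose(
                    getattr(schedule, name), getattr(rates, name), rtol=1e-9
                )

    def test_idempotence_on_calibrated_schedules(self, generated):
        _, factors = calibrate(
            generated.grid,
            generated.rates.retirement,
            generated.rates.emigration,
            generated.rates.attrition,
            AnchorSet(),
            ShapeSpec().outflow_split,
        )
        for value in factors.values():
            assert value == pytest.approx(1.0, rel=1e-9)

    def test_unreachable_anchor_rejected_naming_binding_constraint(self, generated):
        # a tiny replacement target is below the structural forced top-age exits
        anchors = AnchorSet(recruitment_requirement_wte=AnchorSet().expansion_wte + 50.0)
        with pytest.raises(ValueError, match="forced top-age exits"):
            calibrate(
                generated.grid,
                generated.rates.retirement,
                generated.rates.emigration,
                generated.rates.attrition,
                anchors,
                ShapeSpec().outflow_split,
            )

    def test_excessive_outflow_target_rejected(self, generated):
        # an outflow anchor requiring per-cell rates above 1 must be refused
        anchors = AnchorSet(recruitment_requirement_wte=60_000.0)
        with pytest.raises(ValueError, match="exceed 1"):
            calibrate(
                generated.grid,
                generated.rates.retirement,
                generated.rates.emigration,
                generated.rates.attrition,
                anchors,
                ShapeSpec().outflow_split,
            )


class TestShapeSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, message",
        [
            ({"female_share": 1.0}, "female_share"),
            ({"outflow_split": {"attrition": 0.5, "emigration": 0.5, "retirement": 0.5}}, "sum"),
            ({"retirement_onset_age": 80}, "onset"),
            ({"age_min": 70, "age_max": 70}, "age_min"),
        ],
    )
    def test_invalid_shapes_rejected(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            ShapeSpec(**kwargs)
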