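import numpy as np
import pytest

from skitakeoff.aero import (
    ANGLE_ORDER,
    PART_NAMES,
    AeroDatabase,
    apply_aero_loads,
    build_reference_grid,
    grid_blocks,
    scale_aero,
)
from skitakeoff.kinematics import PostureAngles
from skitakeoff.synthetic import generate_aero_db

from conftest import affine_force


def q(d1=30.0, d2=150.0, d3=80.0, d4=0.0, t1=0.0, t2=0.0, al=0.0):
    return PostureAngles(delta1=d1, delta2=d2, delta3=d3, delta4=d4,
                         theta1=t1, theta2=t2, alpha=al)


class TestReferenceGrid:
    def test_total_cardinality_is_278(self):
        assert len(build_reference_grid()) == 278

    def test_block_cardinalities(self):
        blocks = grid_blocks()
        assert [b.n_postures for b in blocks] == [8, 10, 4, 128, 128]
        # take-off delta2=90: 4 trunk-thigh values x 2 ankle values
        assert blocks[0].delta2 == 90 and blocks[0].n_postures == 8
        # early flight delta2=180: full product of the six varied axes
        assert blocks[-1].delta2 == 180 and blocks[-1].n_postures == 128

    def test_enumeration_is_deterministic_and_lexicographic(self):
        g1 = build_reference_grid()
        g2 = build_reference_grid()
        assert [p.as_dict() for p in g1] == [p.as_dict() for p in g2]
        first = g1[0]
        assert (first.delta2, first.delta3, first.delta1) == (90, 20, 30)
        assert g1[1].delta1 == 90  # innermost-but-alpha axis varies first

    def test_no_duplicate_postures(self):
        seen = {tuple(sorted(p.as_dict().items())) for p in build_reference_grid()}
        assert len(seen) == 278


class TestInterpolation:
    def test_grid_nodes_return_stored_values_bitwise(self, aero_db):
        for rec in aero_db.records()[::17]:
            out = aero_db.interpolate(rec.posture)
            assert np.array_equal(out.as_array(), rec.as_array())

    def test_affine_database_interpolates_exactly(self, aero_db_affine):
        # interior queries consistent with the block structure
        queries = [
            q(d1=47.3, d2=103.7, d3=64.2),  # between take-off blocks
            q(d1=80.0, d2=166.0, d3=123.4, d4=12.0, t1=31.0, t2=7.5, al=18.0),
            q(d1=30.0, d2=150.0, d3=35.0),  # inside the take-off 150 block
        ]
        for p in queries:
            out = aero_db_affine.interpolate(p)
            np.testing.assert_allclose(
                out.total_force, affine_force(p), rtol=1e-12, atol=1e-10
            )

    def test_midway_query_is_arithmetic_mean_of_neighbors(self, aero_db):
        lo = q(d1=30.0, d2=90.0, d3=20.0)
        hi = q(d1=30.0, d2=90.0, d3=50.0)
        mid = q(d1=30.0, d2=90.0, d3=35.0)
        a = aero_db.interpolate(lo).as_array()
        b = aero_db.interpolate(hi).as_array()
        m = aero_db.interpolate(mid).as_array()
        np.testing.assert_allclose(m, 0.5 * (a + b), rtol=1e-13)

    def test_out_of_range_query_clamps_with_warning(self, aero_db):
        with pytest.warns(UserWarning, match="clamped"):
            out = aero_db.interpolate(q(d2=250.0))
        edge = aero_db.interpolate(q(d2=180.0))
        np.testing.assert_array_equal(out.as_array(), edge.as_array())

    def test_continuity_across_delta2_levels(self, aero_db):
        # dense sweep through the 120 -> 150 -> 180 transitions
        line = np.linspace(120.0, 180.0, 241)
        vals = np.array([
            aero_db.interpolate(q(d1=60.0, d2=d2, d3=50.0)).total_force
            for d2 in line
        ])
        steps = np.abs(np.diff(vals, axis=0)).max(axis=1)
        assert steps.max() < 0.2  # no jumps on a 0.25-degree grid

    def test_duplicate_level_block_selected_by_least_clamping(self, aero_db):
        # delta2=150 exists in both phases with disjoint delta3 ranges
        take = aero_db.interpolate(q(d1=30.0, d2=150.0, d3=20.0))
        flight = aero_db.interpolate(q(d1=30.0, d2=150.0, d3=180.0))
        stored = {((r.posture.delta2, r.posture.delta3)): r
                  for r in aero_db.records()
                  if r.posture.delta2 == 150.0 and r.posture.delta1 == 30.0
                  and r.posture.theta2 == 0 and r.posture.theta1 == 0
                  and r.posture.delta4 == 0 and r.posture.alpha == 0}
        np.testing.assert_array_equal(
            take.as_array(), stored[(150.0, 20.0)].as_array()
        )
        np.testing.assert_array_equal(
            flight.as_array(), stored[(150.0, 180.0)].as_array()
        )

    def test_nonfinite_query_rejected(self, aero_db):
        with pytest.raises(ValueError, match="finite"):
            aero_db.interpolate(q(d2=np.nan))


class TestScaling:
    def test_reference_conditions_are_identity(self, aero_db):
        rec = aero_db.records()[0]
        out = scale_aero(rec, 1.70, 23.0)
        np.testing.assert_array_equal(out.as_array(), rec.as_array())

    def test_speed_doubling_quadruples_everything(self, aero_db):
        rec = aero_db.records()[3]
        out = scale_aero(rec, 1.70, 46.0)
        np.testing.assert_allclose(out.as_array(), 4.0 * rec.as_array(),
                                   rtol=1e-14)

    def test_height_scales_linearly(self, aero_db):
        rec = aero_db.records()[3]
        out = scale_aero(rec, 1.87, 23.0)
        np.testing.assert_allclose(out.as_array(), (1.87 / 1.70) * rec.as_array(),
                                   rtol=1e-14)

    def test_zero_speed_zeroes_all_forces(self, aero_db):
        out = scale_aero(aero_db.records()[5], 1.70, 0.0)
        np.testing.assert_array_equal(out.as_array(), 0.0)

    def test_rescaling_to_reference_is_a_round_trip(self, aero_db):
        rec = aero_db.records()[7]
        once = scale_aero(rec, 1.80, 30.0)
        twice = scale_aero(once, 1.70, 23.0)
        np.testing.assert_allclose(twice.as_array(), once.as_array(), rtol=1e-14)

    def test_invalid_density_rejected(self, aero_db):
        with pytest.raises(ValueError, match="density"):
            scale_aero(aero_db.records()[0], 1.70, 23.0, rho=-1.0)


class TestPartSumInvariant:
    def test_parts_sum_to_whole_after_interpolation_and_scaling(self, aero_db):
        rec = aero_db.interpolate(q(d1=55.0, d2=141.0, d3=77.0))
        rec = scale_aero(rec, 1.82, 26.0)
        total = sum(rec.forces[p] for p in PART_NAMES)
        np.testing.assert_allclose(total, rec.total_force, rtol=1e-12)


class TestApplyLoads:
    def test_zero_speed_motion_gives_zero_loads(self, takeoff, aero_db):
        al = apply_aero_loads(takeoff.scenario.model, takeoff.motion, aero_db,
                              speed=0.0)
        for ld in al.loads:
            np.testing.assert_array_equal(ld.force, 0.0)

    def test_constant_posture_and_speed_give_constant_loads(self, static_trial,
                                                            aero_db):
        model = static_trial.scenario.model
        al = apply_aero_loads(model, static_trial.motion, aero_db, speed=23.0)
        for ld in al.loads:
            np.testing.assert_allclose(ld.force - ld.force[0], 0.0, atol=1e-12)
        # composition: equals scale_aero(interpolate(posture))
        rec = scale_aero(aero_db.interpolate(al.postures[0]),
                         model.generic_height, 23.0)
        np.testing.assert_allclose(al.whole_body_force[0], rec.total_force,
                                   rtol=1e-12)

    def test_per_part_forces_sum_to_whole_body(self, takeoff, aero_db):
        al = apply_aero_loads(takeoff.scenario.model, takeoff.motion, aero_db,
                              speed=23.0)
        total = sum(ld.force for ld in al.loads)
        np.testing.assert_allclose(total, al.whole_body_force, rtol=1e-10,
                                   atol=1e-12)

    def test_unmapped_part_with_force_is_a_configuration_error(self, takeoff,
                                                               aero_db):
        from skitakeoff.aero import DEFAULT_PART_MAP

        pm = {k: v for k, v in DEFAULT_PART_MAP.items() if k != "trunk"}
        with pytest.raises(ValueError, match="maps to no segment"):
            apply_aero_loads(takeoff.scenario.model, takeoff.motion, aero_db,
                             speed=23.0, part_map=pm)


class TestDatabaseConstruction:
    def test_incomplete_block_rejected(self, aero_db):
        recs = aero_db.records()
        with pytest.raises(ValueError, match="Cartesian"):
            AeroDatabase.from_records(recs[:-1])

    def test_round_trip_through_records(self, aero_db):
        rebuilt = AeroDatabase.from_records(aero_db.records())
        assert rebuilt.n_records == aero_db.n_records
        p = q(d1=41.0, d2=132.0, d3=66.0)
        np.testing.assert_allclose(
            rebuilt.interpolate(p).as_array(),
            aero_db.interpolate(p).as_array(), rtol=1e-14,
        )

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            AeroDatabase([])

    def test_record_must_cover_all_ten_parts(self):
        from skitakeoff.aero import AeroRecord

        with pytest.raises(ValueError, match="parts"):
            AeroRecord(posture=q(), forces={"trunk": np.zeros(3)})
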