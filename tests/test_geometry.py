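"""Street sets, scheduling, transfer reflections and distance metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streetnav import geometry as G
from streetnav.errors import InvalidParameterError, SchedulingInfeasibleError


class TestTrainingAngles:
    @pytest.mark.parametrize("delta, expected", [
        (22.5, [0.0, 22.5, 45.0, 67.5, 90.0]),
        (90.0, [0.0, 90.0]),
        (18.0, [0.0, 18.0, 36.0, 54.0, 72.0, 90.0]),
    ])
    def test_grids(self, delta, expected):
        assert G.build_training_angles(delta) == pytest.approx(expected)

    def test_most_variable_task_has_46_streets(self):
        angles = G.build_training_angles(2.0)
        assert len(angles) == 46
        assert angles == pytest.approx(list(np.arange(0.0, 92.0, 2.0)))

    def test_non_divisor_spacing_snaps_to_even_grid(self):
        # 6.425 does not divide 90; nearest even grid is 14 intervals
        angles = G.build_training_angles(6.425)
        assert len(angles) == 15
        assert np.allclose(np.diff(angles), 90.0 / 14.0)

    @pytest.mark.parametrize("bad", [0.0, -5.0, 90.5])
    def test_invalid_delta(self, bad):
        with pytest.raises(InvalidParameterError):
            G.build_training_angles(bad)

    @given(st.floats(min_value=0.5, max_value=90.0))
    @settings(max_examples=50, deadline=None)
    def test_grid_invariants(self, delta):
        angles = np.asarray(G.build_training_angles(delta))
        assert angles[0] == 0.0 and angles[-1] == 90.0
        assert np.all(np.diff(angles) > 0)
        assert len(set(angles.tolist())) == len(angles)


class TestNeighbourSpacing:
    def test_study_deltas(self):
        out = G.neighbour_spacing_summary([22.5, 18.0, 11.25, 6.425, 2.0])
        assert out.mean == pytest.approx(5.13, abs=0.005)
        assert out.se == pytest.approx(0.55, abs=0.005)

    def test_single_gap_warns_and_returns_zero_se(self):
        with pytest.warns(UserWarning):
            out = G.neighbour_spacing_summary([10.0, 5.0])
        assert out == G.SpacingSummary(5.0, 0.0, 1)

    def test_equal_spacing_has_zero_se(self):
        out = G.neighbour_spacing_summary([9.0, 6.0, 3.0])
        assert out.mean == pytest.approx(3.0)
        assert out.se == pytest.approx(0.0)

    def test_too_few_values(self):
        with pytest.raises(InvalidParameterError):
            G.neighbour_spacing_summary([5.0])


class TestScheduling:
    @pytest.mark.parametrize("task", G.TRAINING_TASKS)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_balance_and_consecutive_constraint(self, task, seed):
        spec = G.training_task_spec(task)
        seq = G.schedule_angles(spec, seed)
        assert seq.size == 600
        _, counts = np.unique(seq, return_counts=True)
        assert counts.max() - counts.min() <= 1
        assert np.abs(np.diff(seq)).min() >= 22.5 - 1e-9

    def test_least_variable_task_repeats_each_street_120_times(self):
        seq = G.schedule_angles(G.training_task_spec("Train-I"), 3)
        _, counts = np.unique(seq, return_counts=True)
        assert counts.tolist() == [120] * 5

    def test_most_variable_task_counts_13_or_14(self):
        seq = G.schedule_angles(G.training_task_spec("Train-V"), 3)
        _, counts = np.unique(seq, return_counts=True)
        assert set(counts.tolist()) <= {13, 14}
        assert counts.sum() == 600

    def test_deterministic_given_seed(self):
        spec = G.training_task_spec("Train-III")
        assert np.array_equal(G.schedule_angles(spec, 11), G.schedule_angles(spec, 11))

    def test_infeasible_constraint_raises(self):
        spec = G.TrainingTaskSpec(
            name="impossible", min_angular_difference=22.5,
            n_trials=2, min_consecutive_difference=91.0)
        with pytest.raises(SchedulingInfeasibleError):
            G.schedule_angles(spec, 0)

    def test_session_object_layout(self):
        trials = G.schedule_training_session(G.training_task_spec("Train-I"), 0)
        assert len(trials) == 100
        assert all(len(t.streets) == 6 for t in trials)
        assert trials[0].index == 1

    def test_trial_compositions_vary(self):
        # six angles, six streets per trial must not lock every trial
        # into the same full-grid permutation
        spec = G.training_task_spec("Train-II")
        seq = G.schedule_angles(spec, 5).reshape(100, 6)
        sums = seq.sum(axis=1)
        assert np.ptp(sums) > 0


class TestTransferStreets:
    def test_six_slightly_different_curves(self):
        streets = G.build_transfer_streets("S")
        assert len(streets) == 6
        lengths = [s.length for s in streets]
        assert len(set(np.round(lengths, 6))) == 6  # distinct shapes

    def test_vertical_flip_maps_x_to_minus_x(self):
        s = G.build_transfer_streets("S")
        m = G.build_transfer_streets("M")
        for a, b in zip(s, m):
            assert np.array_equal(b.centreline[:, 0], -a.centreline[:, 0])
            assert np.array_equal(b.centreline[:, 1], a.centreline[:, 1])

    def test_window_coordinates_reflection(self):
        # in bottom-left window coordinates the M curve contains (W - x, y)
        s = G.to_window_coords(G.build_transfer_streets("S")[0].centreline)
        m = G.to_window_coords(G.build_transfer_streets("M")[0].centreline)
        assert np.allclose(m[:, 0], 1.0 - s[:, 0], atol=1e-12)
        assert np.allclose(m[:, 1], s[:, 1], atol=1e-12)

    def test_double_reflection_is_bit_identical(self):
        for street in G.build_transfer_streets("S"):
            twice = street.reflected(True, False).reflected(True, False)
            assert np.array_equal(twice.centreline, street.centreline)
            both = street.reflected(True, True).reflected(True, True)
            assert np.array_equal(both.centreline, street.centreline)

    def test_reflections_preserve_arc_length(self):
        for variant in ("M", "L"):
            for a, b in zip(G.build_transfer_streets("S"),
                            G.build_transfer_streets(variant)):
                assert b.length == pytest.approx(a.length, abs=1e-15)

    def test_variant_direction_conventions(self):
        assert G.TRANSFER_VARIANTS["S"].movement_directions == (1, 1)
        assert G.TRANSFER_VARIANTS["M"].movement_directions == (-1, 1)
        assert G.TRANSFER_VARIANTS["L"].movement_directions == (-1, -1)
        assert G.TRANSFER_VARIANTS["L"].n_flips == 2


class TestIdealDistance:
    def test_point_on_ideal_line_is_zero(self):
        st_ = G.StraightStreet(37.0)
        c, s = math.cos(math.radians(37.0)), math.sin(math.radians(37.0))
        p = (0.3 * c, 0.3 * s)
        assert G.point_to_ideal_distance(p, st_) == pytest.approx(0.0, abs=1e-12)

    def test_axis_aligned_offset(self):
        st_ = G.StraightStreet(0.0)
        assert G.point_to_ideal_distance((0.1, 0.05), st_) == pytest.approx(0.05)

    def test_degenerate_street_rejected(self):
        with pytest.raises(InvalidParameterError):
            G.StraightStreet(10.0, length=0.0)

    @given(
        angle=st.floats(min_value=0.0, max_value=90.0),
        along=st.floats(min_value=0.0, max_value=0.5),
        lateral=st.floats(min_value=-0.1, max_value=0.1),
    )
    @settings(max_examples=60, deadline=None)
    def test_heron_matches_nearest_neighbour_oracle(self, angle, along, lateral):
        """Heron's formula equals dense nearest-neighbour on the same line."""
        street = G.StraightStreet(angle)
        rad = math.radians(angle)
        u = (math.cos(rad), math.sin(rad))
        p = (along * u[0] - lateral * u[1], along * u[1] + lateral * u[0])
        heron = G.point_to_ideal_distance(p, street)
        poly = G.CurvedStreet(np.array([street.start, street.end]), width=street.width)
        nn = G.point_to_ideal_distance(p, poly, resample_step=1e-4)
        assert abs(heron - nn) < 1e-4
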