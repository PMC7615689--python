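"""Movement time, RMS error and the performance index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streetnav import scoring as S
from streetnav.errors import InvalidParameterError, NotScorableError, UndefinedPIError
from streetnav.geometry import StraightStreet
from streetnav.kinematics import KinematicsConfig, Trajectory, advance_street

CFG = KinematicsConfig()


def _traj(frames, positions, velocities, outcome="completed", street=None):
    n = len(frames)
    return Trajectory(
        street=street or StraightStreet(0.0),
        frames=np.asarray(frames),
        positions=np.asarray(positions, dtype=float),
        velocities=np.asarray(velocities, dtype=float),
        keys=np.zeros((n, 2), dtype=bool),
        resets=np.zeros(n, dtype=bool),
        outcome=outcome,
        n_resets=0,
    )


def _moving_traj(n_frames, idle=0, y_offset=0.0):
    frames = np.arange(idle, idle + n_frames + 1)
    x = np.linspace(0.0, 0.5, n_frames + 1)
    positions = np.column_stack([x, np.full(n_frames + 1, y_offset)])
    velocities = np.column_stack([np.full(n_frames + 1, 0.002), np.zeros(n_frames + 1)])
    if idle:
        frames = np.concatenate([np.arange(idle), frames])
        positions = np.vstack([np.zeros((idle, 2)), positions])
        velocities = np.vstack([np.zeros((idle, 2)), velocities])
    return _traj(frames, positions, velocities)


class TestMovementTime:
    def test_onset_at_frame_zero(self):
        assert S.movement_time(_moving_traj(300), CFG) == pytest.approx(5.0)

    def test_onset_anchored_after_idle_frames(self):
        # 60 idle frames, completion at frame 360: still 5 s
        assert S.movement_time(_moving_traj(300, idle=60), CFG) == pytest.approx(5.0)

    def test_aborted_not_scorable(self):
        traj = _moving_traj(100)
        traj.outcome = "aborted"
        with pytest.raises(NotScorableError):
            S.movement_time(traj, CFG)

    def test_full_speed_diagonal_matches_ramp_closed_form(self):
        """Both keys held: time follows the constant-acceleration law."""
        street = StraightStreet(45.0)
        traj = advance_street(lambda s: (True, True), street, CFG)
        assert traj.completed
        # diagonal acceleration sqrt(2)*a per frame covers the street in
        # t = sqrt(2 L_eff / (sqrt(2) a)) frames
        L_eff = (1.0 - CFG.end_zone_fraction) * street.length
        t_pred = np.sqrt(2.0 * L_eff / (np.sqrt(2.0) * CFG.accel_per_frame))
        assert S.movement_time(traj, CFG) == pytest.approx(t_pred / CFG.frame_rate, rel=0.05)


class TestStreetError:
    def test_on_centreline_is_zero(self):
        assert S.street_error(_moving_traj(50)) == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_is_that_offset(self):
        assert S.street_error(_moving_traj(50, y_offset=0.02)) == pytest.approx(0.02)

    def test_zigzag_rms(self):
        # equal mix of distances 0.01 and 0.03 -> sqrt((1e-4 + 9e-4)/2)
        n = 40
        frames = np.arange(n + 1)
        x = np.linspace(0.0, 0.5, n + 1)
        y = np.where(np.arange(n + 1) % 2 == 0, 0.01, 0.03)
        positions = np.column_stack([x, y])
        velocities = np.column_stack([np.full(n + 1, 0.002), np.zeros(n + 1)])
        traj = _traj(frames, positions, velocities)
        # drop one frame to get an exact half/half mix
        traj.frames, traj.positions, traj.velocities = frames[1:], positions[1:], velocities[1:]
        traj.keys, traj.resets = traj.keys[1:], traj.resets[1:]
        assert S.street_error(traj) == pytest.approx(np.sqrt(5e-4), rel=1e-9)
        assert S.street_error(traj) == pytest.approx(0.02236, abs=5e-5)


class TestConstantsAndPI:
    def test_single_score_pilot(self):
        c = S.calibrate_constants([S.StreetScore(movement_time=4.0, error=0.02)])
        assert (c.a, c.b) == (0.02, 4.0)

    def test_constant_error_pilot(self):
        scores = [S.StreetScore(movement_time=t, error=0.01) for t in (2.0, 4.0)]
        assert S.calibrate_constants(scores).a == pytest.approx(0.01)

    def test_empty_pilot_rejected(self):
        with pytest.raises(InvalidParameterError):
            S.calibrate_constants([])

    def test_normalisation_fixed_point(self):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        assert S.performance_index(4.0, 0.02, c) == pytest.approx(1.0)

    def test_halving_error_doubles_pi(self):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        assert S.performance_index(4.0, 0.01, c) == pytest.approx(
            2.0 * S.performance_index(4.0, 0.02, c))

    def test_product_law(self):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        assert S.performance_index(8.0, 0.01, c) == pytest.approx(4.0)

    def test_zero_inputs_undefined(self):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        with pytest.raises(UndefinedPIError):
            S.performance_index(0.0, 0.01, c)

    def test_inverted_pm_rewards_speed(self):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        fast = S.performance_index(2.0, 0.02, c, pm_inverted=True)
        slow = S.performance_index(8.0, 0.02, c, pm_inverted=True)
        assert fast > slow

    @given(
        scale_err=st.floats(min_value=0.1, max_value=10.0),
        scale_mt=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_pi_invariant_to_joint_rescaling(self, scale_err, scale_mt):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        c2 = S.NormalizationConstants(a=0.02 * scale_err, b=4.0 * scale_mt)
        pi1 = S.performance_index(3.0, 0.015, c)
        pi2 = S.performance_index(3.0 * scale_mt, 0.015 * scale_err, c2)
        assert pi2 == pytest.approx(pi1, rel=1e-9)

    def test_trial_aggregation_is_mean_of_streets(self):
        c = S.NormalizationConstants(a=0.02, b=4.0)
        streets = [S.StreetScore(movement_time=mt, error=e)
                   for mt, e in [(3.0, 0.01), (5.0, 0.03), (4.0, 0.02)]]
        ts = S.trial_score(7, streets, c)
        assert ts.movement_time == pytest.approx(4.0)
        assert ts.error == pytest.approx(0.02)
        assert ts.pi == pytest.approx((4.0 / 4.0) * (0.02 / 0.02))
        # order invariance
        ts2 = S.trial_score(7, streets[::-1], c)
        assert ts2.pi == pytest.approx(ts.pi)
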