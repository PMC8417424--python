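"""Geometric primitives, scalar gait variables and cycle normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitval as gv
from gaitval.errors import DegenerateGeometryError, TooShortCycleError, UnreachablePoseError
from gaitval.gait_events import CycleSet
from gaitval.kinematics import (
    N_BINS,
    VARIABLE_COLUMNS,
    angle_trace,
    cycle_traces,
)

from conftest import make_track


class TestJointAngle:
    def test_collinear_is_straight(self):
        assert gv.joint_angle((0, 0), (1, 0), (2, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert gv.joint_angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            gv.joint_angle((1, 1), (1, 1), (2, 0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_law_of_cosines(self, seed):
        """The vector formulation agrees with the law of cosines evaluated
        on the three side lengths."""
        rng = np.random.default_rng(seed)
        p, v, d = rng.normal(0, 10, (3, 2))
        if np.hypot(*(p - v)) < 1e-6 or np.hypot(*(d - v)) < 1e-6:
            return
        a = np.hypot(*(p - v))
        b = np.hypot(*(d - v))
        c = np.hypot(*(p - d))
        oracle = np.degrees(
            np.arccos(np.clip((a**2 + b**2 - c**2) / (2 * a * b), -1, 1))
        )
        assert gv.joint_angle(p, v, d) == pytest.approx(oracle, abs=1e-9)


class TestExtrapolateKnee:
    def test_symmetric_isoceles(self):
        knee = gv.extrapolate_knee((0, 10), (0, 0), 5 * np.sqrt(2), 5 * np.sqrt(2))
        np.testing.assert_allclose(knee, [5.0, 5.0], atol=1e-9)

    def test_collinear_boundary(self):
        knee = gv.extrapolate_knee((0, 10), (0, 0), 6.0, 4.0)
        np.testing.assert_allclose(knee, [0.0, 4.0], atol=1e-9)

    def test_unreachable_pose(self):
        with pytest.raises(UnreachablePoseError):
            gv.extrapolate_knee((0, 30), (0, 0), 5.0, 5.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_distances_honoured(self, seed):
        """The returned point is at femur length from the hip and shank
        length from the ankle, and is the anterior of the two solutions."""
        rng = np.random.default_rng(seed)
        hip = rng.normal(0, 10, 2)
        ankle = rng.normal(0, 10, 2)
        d = np.hypot(*(hip - ankle))
        if d < 0.1:
            return
        femur = d * rng.uniform(0.55, 0.95)
        shank = d * rng.uniform(max(0.1, 1.05 - femur / d), 0.95)
        if not abs(femur - shank) < d < femur + shank:
            return
        knee = gv.extrapolate_knee(hip, ankle, femur, shank)
        assert np.hypot(*(knee - hip)) == pytest.approx(femur, abs=1e-9)
        assert np.hypot(*(knee - ankle)) == pytest.approx(shank, abs=1e-9)
        # anterior solution: no other intersection point has larger x
        axis = (ankle - hip) / d
        mirror = knee - 2 * np.dot(knee - hip, [-axis[1], axis[0]]) \
            * np.array([-axis[1], axis[0]])
        assert knee[0] >= mirror[0] - 1e-9


def _simple_track():
    """Two frames, right toe / left toe / hip markers."""
    xy = np.array([
        [[25.0, 0.0], [5.0, 0.0], [10.0, 20.0]],
        [[8.0, 0.0], [20.0, 0.0], [10.0, 20.0]],
    ])
    return make_track(xy, markers=("toe", "toe_left", "hip"))


def _simple_config(**kw):
    return gv.TrialConfig(
        marker_map={"toe": "toe", "contralateral_toe": "toe_left", "hip": "hip"},
        **kw,
    )


class TestScalarVariables:
    def test_toe_hip_sign_convention(self):
        track, config = _simple_track(), _simple_config()
        assert gv.toe_hip_distance(track, 0, config) == pytest.approx(15.0)
        assert gv.toe_hip_distance(track, 1, config) == pytest.approx(-2.0)

    def test_toe_hip_zero(self):
        track, config = _simple_track(), _simple_config()
        track.xy[0, 0, 0] = 10.0
        assert gv.toe_hip_distance(track, 0, config) == 0.0

    def test_step_length_horizontal(self):
        track, config = _simple_track(), _simple_config()
        assert gv.step_length(track, 0, config) == pytest.approx(20.0)
        track.xy[0, 1, 0] = 25.0
        assert gv.step_length(track, 0, config) == 0.0

    def test_stride_length_formula(self):
        """20 cm of stance displacement + 0.5 s swing at 1 m/s = 70 cm."""
        xy = np.zeros((121, 1, 2))
        xy[0, 0, 0] = 25.0
        xy[60, 0, 0] = 5.0     # liftoff, 20 cm caudal of contact
        track = make_track(xy, markers=("toe",))
        config = gv.TrialConfig(
            belt_speed_left=1.0, belt_speed_right=1.0, frame_rate=60.0,
            marker_map={"toe": "toe"},
        )
        out = gv.stride_length(track, (0, 60, 90), config)
        assert out == pytest.approx(20.0 + 0.5 * 1.0 * 100.0)

    def test_stride_length_zero_belt(self):
        xy = np.zeros((121, 1, 2))
        xy[0, 0, 0] = 25.0
        xy[60, 0, 0] = 5.0
        track = make_track(xy, markers=("toe",))
        config = gv.TrialConfig(belt_speed_left=0.0, belt_speed_right=0.0,
                                marker_map={"toe": "toe"})
        assert gv.stride_length(track, (0, 60, 90), config) == pytest.approx(20.0)

    def test_stride_monotone_in_belt_speed(self):
        xy = np.zeros((121, 1, 2))
        xy[0, 0, 0] = 25.0
        xy[60, 0, 0] = 5.0
        track = make_track(xy, markers=("toe",))
        values = [
            gv.stride_length(track, (0, 60, 90), gv.TrialConfig(
                belt_speed_left=s, belt_speed_right=s, marker_map={"toe": "toe"}))
            for s in (0.4, 0.5, 0.7, 1.0)
        ]
        assert np.all(np.diff(values) > 0)


class TestVariablesAtEvents:
    def test_complete_and_deterministic(self, noiseless_trial, noiseless_model):
        track, events, _ = noiseless_trial
        config = noiseless_model.trial_config()
        cycles = gv.build_cycles(events, track.frame_rate)
        t1 = gv.variables_at_events(track, cycles, config, method="m1")
        t2 = gv.variables_at_events(track, cycles, config, method="m2")
        assert list(t1.columns) == ["cycle", *VARIABLE_COLUMNS, "method"]
        assert len(t1) == len(cycles)
        assert not t1[list(VARIABLE_COLUMNS)].isna().any().any()
        np.testing.assert_array_equal(
            t1[list(VARIABLE_COLUMNS)].to_numpy(),
            t2[list(VARIABLE_COLUMNS)].to_numpy(),
        )

    def test_matches_generator_truth(self, noiseless_trial, noiseless_model):
        track, events, truth = noiseless_trial
        config = noiseless_model.trial_config()
        cycles = gv.build_cycles(events, track.frame_rate)
        table = gv.variables_at_events(track, cycles, config)
        for col in VARIABLE_COLUMNS:
            np.testing.assert_allclose(
                table[col], truth[col], atol=1e-6, err_msg=col
            )

    def test_translation_invariance(self, noiseless_trial, noiseless_model):
        track, events, _ = noiseless_trial
        config = noiseless_model.trial_config()
        cycles = gv.build_cycles(events, track.frame_rate)
        shifted = make_track(track.xy + np.array([13.0, -7.0]),
                             markers=track.markers)
        t0 = gv.variables_at_events(track, cycles, config)
        t1 = gv.variables_at_events(shifted, cycles, config)
        for col in VARIABLE_COLUMNS:
            np.testing.assert_allclose(t1[col], t0[col], atol=1e-8, err_msg=col)

    def test_uniform_scaling(self, noiseless_trial, noiseless_model):
        """With the belt at rest, lengths scale linearly with the track and
        angles are unchanged."""
        track, events, _ = noiseless_trial
        config = noiseless_model.trial_config()
        config.belt_speed_left = config.belt_speed_right = 0.0
        cycles = gv.build_cycles(events, track.frame_rate)
        scaled = make_track(track.xy * 2.0, markers=track.markers)
        t0 = gv.variables_at_events(track, cycles, config)
        t1 = gv.variables_at_events(scaled, cycles, config)
        for col in VARIABLE_COLUMNS:
            factor = 1.0 if "angle" in col else 2.0
            np.testing.assert_allclose(t1[col], factor * t0[col],
                                       rtol=1e-9, err_msg=col)

    def test_extrapolated_knee_matches_tracked_on_consistent_chain(
        self, noiseless_trial, noiseless_model,
    ):
        """The generator's knee lies on the hip/ankle circles, so the
        reference tracker's extrapolation reproduces the tracked marker."""
        track, events, _ = noiseless_trial
        cycles = gv.build_cycles(events, track.frame_rate)
        tracked = gv.variables_at_events(
            track, cycles, noiseless_model.trial_config()
        )
        config = noiseless_model.trial_config()
        config.knee_source = "extrapolated"
        config.femur_length = noiseless_model.femur_cm
        config.shank_length = noiseless_model.shank_cm
        extrap = gv.variables_at_events(track, cycles, config)
        for col in VARIABLE_COLUMNS:
            np.testing.assert_allclose(extrap[col], tracked[col], atol=1e-9)


class TestNormalizeCycle:
    def test_constant_trace(self):
        out = gv.normalize_cycle(np.full(37, 100.0))
        assert out.shape == (N_BINS,)
        np.testing.assert_allclose(out, 100.0)

    def test_ramp_identity(self):
        out = gv.normalize_cycle(np.arange(256.0))
        np.testing.assert_allclose(out, np.arange(256.0), atol=1e-12)

    def test_bin_zero_is_contact(self):
        values = np.random.default_rng(1).normal(size=50)
        assert gv.normalize_cycle(values)[0] == values[0]

    def test_sine_resampling_error_bounded(self):
        """Linear interpolation of a 60 Hz-sampled sinusoid deviates from
        the analytic curve by at most the curvature bound (pi f / rate)^2."""
        f, rate = 1.2, 60.0
        n = 50
        t = np.arange(n) / rate
        trace = np.sin(2 * np.pi * f * t)
        out = gv.normalize_cycle(trace)
        t_bins = np.linspace(0, (n - 1) / rate, N_BINS)
        analytic = np.sin(2 * np.pi * f * t_bins)
        assert np.abs(out - analytic).max() < (np.pi * f / rate) ** 2

    def test_single_frame_rejected(self):
        with pytest.raises(TooShortCycleError):
            gv.normalize_cycle(np.array([1.0]))


class TestAverageCycles:
    def test_single_trace(self):
        trace = np.random.default_rng(0).normal(size=N_BINS)
        series = gv.average_cycles(trace[None, :], joint="hip")
        np.testing.assert_array_equal(series.mean, trace)
        np.testing.assert_array_equal(series.sd, 0.0)

    def test_two_point_sd(self):
        base = np.full(N_BINS, 90.0)
        series = gv.average_cycles(np.stack([base - 1, base + 1]))
        np.testing.assert_allclose(series.mean, 90.0)
        np.testing.assert_allclose(series.sd, np.sqrt(2.0))

    def test_mean_recovers_truth_within_clt_bound(self):
        rng = np.random.default_rng(8)
        sigma, n = 2.0, 14
        truth = 120 + 15 * np.sin(np.linspace(0, 2 * np.pi, N_BINS))
        traces = truth[None, :] + rng.normal(0, sigma, (n, N_BINS))
        series = gv.average_cycles(traces)
        assert np.abs(series.mean - truth).max() < 4 * sigma / np.sqrt(n)

    def test_frame_export_schema(self):
        series = gv.average_cycles(np.zeros((3, N_BINS)), joint="ankle")
        df = series.to_frame()
        assert list(df.columns) == ["joint", "bin", "mean", "sd", "n"]
        assert len(df) == N_BINS

    def test_pipeline_traces_shape(self, noiseless_trial, noiseless_model):
        track, events, _ = noiseless_trial
        config = noiseless_model.trial_config()
        cycles = gv.build_cycles(events, track.frame_rate)
        traces = cycle_traces(track, cycles, config, "knee")
        assert traces.shape == (len(cycles), N_BINS)
        full = angle_trace(track, config, "knee")
        np.testing.assert_allclose(
            traces[:, 0], [full[c] for c, _, _ in cycles.cycles]
        )
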