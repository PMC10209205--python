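"""Stride segmentation, frames, percent-gait normalization, leg length."""

import numpy as np
import pytest

from gaitstab import (
    GaitEvents,
    build_stride_frame,
    compute_leg_length,
    detect_events_kinematic,
    normalize_percent_gait,
    segment_strides,
)
from gaitstab.recordings import LANDMARKS
from gaitstab.strides import StrideError, leg_length_raw

from conftest import rotate_recording


def test_fencepost_stride_count(walker_noisy):
    """n+1 right heel strikes delimit exactly n strides."""
    cfg, kin, _, gt = walker_noisy
    ev = detect_events_kinematic(kin)
    slices = segment_strides(ev)
    assert len(ev.right_heel_strikes) == len(slices) + 1
    assert len(slices) == cfg.n_strides  # warm-up stride is invisible by design


def test_segmentation_requires_two_heel_strikes():
    ev = GaitEvents([5], [], [], [])
    with pytest.raises(StrideError, match="at least 2"):
        segment_strides(ev)


def test_stride_frame_identity_for_straight_walk(walker_noiseless, analysis_noiseless):
    _, kin, _, _ = walker_noiseless
    frame = build_stride_frame(kin, analysis_noiseless.slices[2])
    assert np.allclose(frame.rotation, np.eye(3), atol=1e-9)


def test_stride_frame_round_trip(walker_noiseless, analysis_noiseless):
    _, kin, _, _ = walker_noiseless
    sl = analysis_noiseless.slices[2]
    frame = build_stride_frame(kin, sl)
    pts = kin.landmark("com")[sl.start : sl.end + 1]
    assert np.allclose(frame.invert(frame.apply(pts)), pts, atol=1e-12)


def test_rotated_world_gives_identical_stride_arrays(walker_noiseless):
    """A 90-degree heading change leaves stride-frame trajectories unchanged."""
    _, kin, _, _ = walker_noiseless
    kin_rot = rotate_recording(kin, np.pi / 2)
    sl = segment_strides(detect_events_kinematic(kin))[3]
    sl_rot = segment_strides(detect_events_kinematic(kin_rot))[3]
    s = normalize_percent_gait(kin, sl)
    s_rot = normalize_percent_gait(kin_rot, sl_rot)
    for name in LANDMARKS:
        assert np.allclose(s.landmarks[name], s_rot.landmarks[name], atol=1e-9)
    assert np.allclose(s.com_vel, s_rot.com_vel, atol=1e-9)


def test_reverse_walk_flips_ap_axis(walker_noiseless):
    """Walking along -X still yields positive AP velocity in the stride frame."""
    _, kin, _, _ = walker_noiseless
    kin_neg = rotate_recording(kin, np.pi)
    sl = segment_strides(detect_events_kinematic(kin_neg))[2]
    frame = build_stride_frame(kin_neg, sl)
    assert np.allclose(frame.rotation[0], [-1.0, 0.0, 0.0], atol=1e-9)
    vel = np.gradient(kin_neg.landmark("com")[:, 0], 1 / kin_neg.rate)
    ap_vel = (vel[sl.start : sl.end + 1]) * frame.rotation[0, 0]
    assert np.mean(ap_vel) > 0


def test_standing_slice_cannot_be_oriented(walker_noiseless, analysis_noiseless):
    _, kin, _, _ = walker_noiseless
    import copy

    sl = copy.copy(analysis_noiseless.slices[0])
    sl.end = sl.start  # zero displacement
    with pytest.raises(StrideError, match="displacement"):
        build_stride_frame(kin, sl)


class TestPercentGait:
    def test_boundary_samples_preserved(self, walker_noiseless, analysis_noiseless):
        _, kin, _, _ = walker_noiseless
        sl = analysis_noiseless.slices[1]
        frame = build_stride_frame(kin, sl)
        s = normalize_percent_gait(kin, sl, frame)
        raw = frame.apply(kin.landmark("com"))
        assert np.allclose(s.landmarks["com"][0], raw[sl.start], atol=1e-12)
        assert np.allclose(s.landmarks["com"][-1], raw[sl.end], atol=1e-12)

    def test_linear_ramp_resamples_to_percent_coordinate(
        self, walker_noiseless, analysis_noiseless
    ):
        """PCHIP reproduces affine signals exactly on the percent grid."""
        _, kin, _, _ = walker_noiseless
        sl = analysis_noiseless.slices[1]
        t = kin.time[sl.start : sl.end + 1]
        ramp = (t - t[0]) / (t[-1] - t[0])
        from scipy.interpolate import PchipInterpolator

        grid = np.linspace(t[0], t[-1], 101)
        out = PchipInterpolator(t, ramp)(grid)
        assert np.allclose(out, np.linspace(0, 1, 101), atol=1e-12)

    def test_sine_interpolation_error_small(self):
        """Known-frequency sine resampled with < 1e-3 relative error."""
        rate = 120.0
        t = np.arange(0, 1.1, 1 / rate)
        y = np.sin(2 * np.pi * 3.0 * t)
        from scipy.interpolate import PchipInterpolator

        grid = np.linspace(t[0], t[-1], 101)
        err = np.abs(PchipInterpolator(t, y)(grid) - np.sin(2 * np.pi * 3.0 * grid))
        assert err.max() < 1e-3

    def test_invalid_n_points(self, walker_noiseless, analysis_noiseless):
        _, kin, _, _ = walker_noiseless
        with pytest.raises(ValueError, match="n_points"):
            normalize_percent_gait(kin, analysis_noiseless.slices[0], n_points=1)

    def test_event_phases_inside_stride(self, walker_noiseless, analysis_noiseless):
        _, kin, insole, _ = walker_noiseless
        s = normalize_percent_gait(kin, analysis_noiseless.slices[0], insole=insole)
        assert 0 < s.phases["left_toe_off"] < s.phases["left_heel_strike"]
        assert s.phases["left_heel_strike"] < s.phases["right_toe_off"] < 100
        assert set(s.vgrf) == {"left", "right"}

    def test_resample_and_transform_commute(self, walker_noiseless, analysis_noiseless):
        """Percent-gait resampling commutes with the rigid frame transform.

        PCHIP's monotonicity limiter is not exactly rotation-equivariant, so
        the commutation holds to interpolation accuracy (well below 0.1 mm
        here), not to machine precision.
        """
        _, kin, _, _ = walker_noiseless
        kin_rot = rotate_recording(kin, 0.7)
        sl = segment_strides(detect_events_kinematic(kin_rot))[2]
        frame = build_stride_frame(kin_rot, sl)
        s = normalize_percent_gait(kin_rot, sl, frame)
        # transform after resampling the raw (global) trajectory
        from scipy.interpolate import PchipInterpolator

        t = kin_rot.time
        grid = np.linspace(t[sl.start], t[sl.end], 101)
        raw = kin_rot.landmark("com")
        resampled_global = PchipInterpolator(
            t[sl.start : sl.end + 1], raw[sl.start : sl.end + 1], axis=0
        )(grid)
        assert np.allclose(
            frame.apply(resampled_global), s.landmarks["com"], atol=1e-4
        )


class TestLegLength:
    def test_recovered_within_three_percent(self, walker_noisy, analysis_noisy):
        cfg, _, _, _ = walker_noisy
        L = analysis_noisy.strides["leg_length"].to_numpy()
        assert np.all(np.abs(L - cfg.leg_length) / cfg.leg_length < 0.03)

    def test_vertical_pendulum(self, walker_noiseless, analysis_noiseless):
        """CoM held directly above a stationary foot gives L = height."""
        _, kin, _, _ = walker_noiseless
        s = normalize_percent_gait(kin, analysis_noiseless.slices[0])
        s.landmarks["r_mt5"] = np.zeros_like(s.landmarks["r_mt5"])
        s.landmarks["com"] = np.tile([0.0, 0.0, 0.9], (s.n_points, 1))
        assert compute_leg_length(s) == pytest.approx(0.9, abs=1e-12)

    def test_degenerate_slice_raises(self, walker_noiseless, analysis_noiseless):
        import copy

        _, kin, _, _ = walker_noiseless
        sl = copy.copy(analysis_noiseless.slices[0])
        sl.right_toe_off = sl.start
        with pytest.raises(StrideError, match="stance"):
            leg_length_raw(kin, sl)
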