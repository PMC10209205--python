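"""Event detection, clock synchronization and resampling."""

import numpy as np
import pandas as pd
import pytest

from gaitstab import (
    GaitEvents,
    InsoleRecording,
    detect_events_kinematic,
    detect_heel_strikes_force,
    downsample,
    simulate_walker,
    SimConfig,
    synchronize_jumps,
)
from gaitstab.events import EventDetectionError
from gaitstab.recordings import KinematicRecording, LANDMARKS, make_kinematic_frame


def _flat_recording(n=1200, rate=120.0):
    t = np.arange(n) / rate
    zeros = np.zeros((n, 3))
    landmarks = {name: zeros.copy() for name in LANDMARKS}
    return KinematicRecording(
        make_kinematic_frame(t, landmarks, np.zeros(n)), rate
    )


class TestForceEvents:
    def test_simple_onset(self):
        force = np.array([0, 0, 10, 40, 300, 400, 350, 300], float)
        ev = detect_heel_strikes_force(force, rate=100.0)
        assert list(ev) == [3]

    def test_silent_signal_gives_no_events(self):
        assert len(detect_heel_strikes_force(np.zeros(500), rate=100.0)) == 0

    def test_square_wave_one_event_per_rising_edge(self):
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        force = np.where((t % 1.0) < 0.5, 500.0, 0.0)
        ev = detect_heel_strikes_force(force, rate=rate)
        # independent brute-force scan of admissible crossings
        above = force >= 30.0
        expected = [
            i
            for i in range(1, len(force))
            if above[i]
            and not above[i - 1]
            and not above[max(i - 20, 0) : i].any()
        ]
        assert list(ev) == expected
        assert len(ev) == 9  # one per full period after the first plateau

    def test_refractory_suppresses_chatter(self):
        rate = 100.0
        force = np.zeros(300)
        force[100:200] = 500.0
        force[105] = 0.0  # one-sample dropout inside the stance
        ev = detect_heel_strikes_force(force, rate=rate)
        assert list(ev) == [100]

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            detect_heel_strikes_force(np.zeros(10), threshold=0.0, rate=100.0)
        with pytest.raises(ValueError, match="non-negative"):
            detect_heel_strikes_force(np.array([-5.0, 10.0]), rate=100.0)


class TestKinematicEvents:
    def test_recovers_ground_truth_events(self, walker_noiseless):
        """All detected events lie within one kinematic sample of truth."""
        cfg, kin, insole, gt = walker_noiseless
        ev = detect_events_kinematic(kin)
        t = kin.time
        det_rhs = t[ev.right_heel_strikes]
        # every analyzed heel strike is found at its exact time
        for t_true in gt.rhs_times:
            assert np.min(np.abs(det_rhs - t_true)) <= 1.0 / cfg.sample_rate_kin
        # toe-offs fall a stance-duration after their heel strikes
        det_rto = t[ev.right_toe_offs]
        stance = cfg.stance_fraction * cfg.stride_time
        for t_true in gt.rhs_times[:-1]:
            assert np.min(np.abs(det_rto - (t_true + stance))) <= 1.0 / cfg.sample_rate_kin

    def test_event_counts_per_foot_balanced(self, walker_noisy):
        _, kin, _, _ = walker_noisy
        ev = detect_events_kinematic(kin)
        assert abs(len(ev.right_heel_strikes) - len(ev.left_heel_strikes)) <= 1

    def test_standing_still_raises(self):
        with pytest.raises(EventDetectionError, match="right heel strikes"):
            detect_events_kinematic(_flat_recording())

    def test_ordering_invariant_enforced(self):
        ev = GaitEvents(
            right_heel_strikes=[10, 5],
            right_toe_offs=[7],
            left_heel_strikes=[3],
            left_toe_offs=[1],
        )
        with pytest.raises(EventDetectionError, match="increasing"):
            ev.validate()
        ev2 = GaitEvents(
            right_heel_strikes=[10, 100],
            right_toe_offs=[5],  # outside the stride
            left_heel_strikes=[50],
            left_toe_offs=[30],
        )
        with pytest.raises(EventDetectionError, match="toe-off"):
            ev2.validate()


class TestSynchronization:
    def test_recovers_configured_offset(self):
        cfg = SimConfig(n_strides=6, clock_offset=0.37, seed=7)
        kin, insole, gt = simulate_walker(cfg)
        est = synchronize_jumps(kin, insole)
        assert est == pytest.approx(0.37, abs=0.01)

    def test_zero_offset(self, walker_noiseless):
        _, kin, insole, _ = walker_noiseless
        est = synchronize_jumps(kin, insole)
        assert abs(est) <= 0.01  # within one insole sample

    def test_missing_jumps_raise(self, walker_noiseless):
        _, kin, insole, _ = walker_noiseless
        flat = pd.DataFrame(
            {
                "time": insole.time,
                "vgrf": np.full(len(insole.time), 400.0),
                "cop_ml": 0.0,
            }
        )
        no_jumps = InsoleRecording(flat, flat.copy(), insole.rate)
        with pytest.raises(EventDetectionError, match="flight"):
            synchronize_jumps(kin, no_jumps)

    def test_force_and_kinematic_heel_strikes_agree(self, walker_noiseless):
        """The 30 N insole events match kinematic heel strikes after sync."""
        cfg, kin, insole, gt = walker_noiseless
        offset = synchronize_jumps(kin, insole)
        ev = detect_events_kinematic(kin)
        t_kin = kin.time[ev.right_heel_strikes]
        t_force = insole.time[detect_heel_strikes_force(insole, side="right")] + offset
        dt_ins = 1.0 / cfg.sample_rate_insole
        # the force rises from 0 N at contact, so the 30 N crossing trails the
        # true event by up to one sample; the sync estimate adds at most half
        # a sample more
        for tk in t_kin:
            assert np.min(np.abs(t_force - tk)) <= 2 * dt_ins + 1e-9


class TestDownsample:
    def _sine_recording(self, rate=240.0, f=2.0, dur=10.0):
        t = np.arange(0, dur, 1 / rate)
        wave = np.column_stack([np.sin(2 * np.pi * f * t), np.zeros_like(t), np.zeros_like(t)])
        landmarks = {name: wave for name in LANDMARKS}
        return KinematicRecording(make_kinematic_frame(t, landmarks, np.zeros_like(t)), rate)

    def test_240_to_120_preserves_low_frequency_content(self):
        kin = self._sine_recording()
        out = downsample(kin, 120.0)
        assert out.rate == 120.0
        x = out.landmark("com")[:, 0]
        ref = np.sin(2 * np.pi * 2.0 * out.time)
        rms_err = np.sqrt(np.mean((x - ref) ** 2)) / np.sqrt(np.mean(ref**2))
        assert rms_err < 0.01
        # duration preserved within one target-rate sample
        assert abs(out.time[-1] - kin.time[-1]) <= 1.0 / 120.0

    def test_identity_when_target_equals_source(self):
        kin = self._sine_recording()
        out = downsample(kin, 240.0)
        pd.testing.assert_frame_equal(out.data, kin.data)

    def test_invalid_targets(self):
        kin = self._sine_recording()
        with pytest.raises(ValueError):
            downsample(kin, 0.0)
        with pytest.raises(ValueError, match="upsample"):
            downsample(kin, 480.0)
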