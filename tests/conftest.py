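"""Shared synthetic-walker fixtures (generated in memory, session scoped)."""

import numpy as np
import pytest

from gaitstab import SimConfig, analyze_recording, simulate_walker


@pytest.fixture(scope="session")
def walker_noiseless():
    """Deterministic walker: zero placement and compensation noise."""
    cfg = SimConfig(n_strides=25, fp_noise_sd=0.0, compensation_noise_sd=0.0, seed=1)
    kin, insole, gt = simulate_walker(cfg)
    return cfg, kin, insole, gt


@pytest.fixture(scope="session")
def walker_noisy():
    cfg = SimConfig(n_strides=60, seed=3)
    kin, insole, gt = simulate_walker(cfg)
    return cfg, kin, insole, gt


@pytest.fixture(scope="session")
def analysis_noiseless(walker_noiseless):
    cfg, kin, insole, gt = walker_noiseless
    return analyze_recording(kin, insole)


@pytest.fixture(scope="session")
def analysis_noisy(walker_noisy):
    cfg, kin, insole, gt = walker_noisy
    return analyze_recording(kin, insole)


def rotate_recording(kin, angle):
    """A copy of a kinematic recording rotated about the vertical axis."""
    from gaitstab.recordings import KinematicRecording, LANDMARKS

    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    df = kin.data.copy()
    for name in LANDMARKS:
        arr = kin.landmark(name) @ R.T
        for j, ax in enumerate("xyz"):
            df[f"{name}_{ax}"] = arr[:, j]
    return KinematicRecording(df, kin.rate)
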