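"""Synthetic outdoor-walking generator with known ground-truth control gains.

The walker emulates the signals the analysis pipeline consumes: stride-
periodic CoM trajectories (constant-speed AP ramp, sinusoidal ML sway at
step frequency, double-bump vertical oscillation), heel/toe/sacrum/C7/hip
landmark trajectories, a mediolateral trunk angular-velocity channel, and
per-foot insole streams with two-peak stance vGRF profiles and ML CoP.
Three jumps (flight phases with matching force unloading and free-fall CoM
acceleration) are prepended for clock synchronization, and a configurable
constant offset separates the insole clock from the kinematic clock.

Foot placement follows a linear controller: the deviation of each placement
from its nominal position equals a gain matrix times the CoM-state
deviation at the midstance of the preceding single support, plus Gaussian
noise.  Crucially the controller consumes the state exactly as the analysis
measures it (same differentiation, interpolation, anchoring and mirror-
pooling code), so with zero noise the downstream stepping regression
recovers the gain matrix to machine precision.  The ankle/trunk
compensation channels are likewise built from the generator's own stepping
fit residuals, so the compensation regression is exact when its residual
noise is zero.

Timing is laid out so every gait event falls exactly on both the 120 Hz
kinematic and 100 Hz insole sample grids (stride time 1.1 s, stance
fraction 7/11), which makes event detection reproducible at sample
resolution on noiseless data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .recordings import InsoleRecording, KinematicRecording, make_kinematic_frame
from .regression import (
    ML_STATE_IDX,
    center_by_side,
    fit_stepping,
    compute_fp_error,
    midstance_state_raw,
)
from .strides import kinematic_derivatives

_WALK_START = 8.0  # s, first (warm-up) right heel strike on the kinematic clock
_FLIGHT_STARTS = (1.5, 2.9, 4.3)  # s
_FLIGHT_DUR = 0.35  # s
_SPIKE_DUR = 0.12  # s, landing transient
_ONSET_DUR = 1.0  # s, standing -> walking blend
_FORCE_FADE = 0.3  # s, standing -> gait force crossfade
_TAIL = 0.4  # s of recording after the last right heel strike

#: default stepping-gain matrix (rows: AP, ML placement response; columns in
#: STATE_NAMES order).  Values of order 0.1-1, the regime the recovery
#: contract targets.
DEFAULT_STEPPING_GAINS = np.array(
    [
        [0.50, 0.20, 0.40, 0.35, 0.15, 0.25, 0.12, 0.10, 0.10],
        [0.15, 0.80, 0.20, 0.10, 0.45, 0.15, 0.10, 0.12, 0.10],
    ]
)

#: default midstance-state covariance (diagonal; SI units).  The study data
#: never printed a CoM-state distribution, so these are plausible healthy-
#: adult variability magnitudes, a free modelling choice.
DEFAULT_STATE_SD = np.array(
    [0.02, 0.015, 0.012, 0.06, 0.05, 0.04, 0.12, 0.10, 0.08]
)


def _smootherstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (x * (x * 6.0 - 15.0) + 10.0)


def _bump_window(u: np.ndarray, h: float) -> np.ndarray:
    """C^2 compact window: value 1 and zero 1st/2nd derivative at u=0."""
    s = np.clip(np.abs(u) / h, 0.0, 1.0)
    return (1.0 - s**4) ** 3


@dataclass
class SimConfig:
    """Parameters of the synthetic walker.

    Lengths in m, times in s, rates in Hz, gains dimensionless except
    ``trunk_gain`` (m per deg/s); ``stepping_gains`` maps the 9-element
    midstance CoM-state deviation to the (AP, ML) foot-placement deviation.
    ``seed`` fully determines the output.
    """

    n_strides: int = 50
    stride_time: float = 1.1
    stride_length: float = 1.61
    step_width: float = 0.09
    leg_length: float = 0.91
    gravity: float = 9.806
    body_mass: float = 74.0
    sample_rate_kin: float = 120.0
    sample_rate_insole: float = 100.0
    stance_fraction: float = 7.0 / 11.0
    heel_lead: float = 0.32  # nominal AP heel-to-CoM distance at heel strike
    stepping_gains: np.ndarray = field(
        default_factory=lambda: DEFAULT_STEPPING_GAINS.copy()
    )
    fp_noise_sd: float = 0.01
    ankle_gain: float = 0.30  # beta_ankle, m per m of CoP shift
    trunk_gain: float = 0.01  # beta_trunk, m per deg/s
    compensation_noise_sd: float = 0.003
    cop_dev_sd: float = 0.008
    trunk_fallback_sd: float = 1.0  # deg/s, used when trunk_gain == 0
    com_state_cov: np.ndarray = field(
        default_factory=lambda: np.diag(DEFAULT_STATE_SD**2)
    )
    fw_mos_offset: float = 0.0
    clock_offset: float = 0.0  # kin_time = insole_time + clock_offset
    condition_tags: tuple[str, ...] | None = None
    condition_fw_offsets: dict = field(default_factory=dict)
    ml_sway_amp: float = 0.015
    vt_osc_amp: float = 0.02
    ap_fluct_amp: float = 0.008
    trunk_sway_amp: float = 5.0  # deg/s
    bump_halfwidth: float = 0.16  # s, support of the midstance state bumps
    heel_lift: float = 0.08
    foot_length: float = 0.15  # heel -> mt5 AP offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        for name in (
            "stride_time",
            "stride_length",
            "step_width",
            "leg_length",
            "gravity",
            "body_mass",
            "sample_rate_kin",
            "sample_rate_insole",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.5 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0.5, 1)")
        self.stepping_gains = np.asarray(self.stepping_gains, float)
        if self.stepping_gains.shape != (2, 9):
            raise ValueError("stepping_gains must have shape (2, 9)")
        cov = np.asarray(self.com_state_cov, float)
        if cov.shape != (9, 9):
            raise ValueError("com_state_cov must have shape (9, 9)")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("com_state_cov must be symmetric")
        w = np.linalg.eigvalsh(cov)
        if np.min(w) < -1e-10:
            raise ValueError(
                "com_state_cov is not positive semi-definite "
                f"(smallest eigenvalue {np.min(w):.3e})"
            )
        self.com_state_cov = cov
        if self.condition_tags is not None:
            if len(self.condition_tags) != self.n_strides:
                raise ValueError("condition_tags must have length n_strides")
            self.condition_tags = tuple(self.condition_tags)

    @property
    def speed(self) -> float:
        return self.stride_length / self.stride_time

    def analytic_r2(self, direction: str = "ML") -> float:
        """Population R^2 of the stepping regression implied by the config."""
        b = self.stepping_gains[0 if direction.upper() == "AP" else 1]
        signal = float(b @ self.com_state_cov @ b)
        noise = self.fp_noise_sd**2
        return signal / (signal + noise) if signal + noise > 0 else 0.0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["stepping_gains"] = self.stepping_gains.tolist()
        d["com_state_cov"] = self.com_state_cov.tolist()
        if d["condition_tags"] is not None:
            d["condition_tags"] = list(d["condition_tags"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["stepping_gains"] = np.asarray(d["stepping_gains"], float)
        d["com_state_cov"] = np.asarray(d["com_state_cov"], float)
        if d.get("condition_tags") is not None:
            d["condition_tags"] = tuple(d["condition_tags"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Recovery targets: what the generator actually injected.

    Pooled per-step arrays have 2*n_strides rows ordered (left placement,
    right placement) per stride; :meth:`frame` exposes the spec'd one-row-
    per-stride view.  All mediolateral step quantities are in the pooled
    (mirror) convention: left-placement ML values already negated.
    """

    config: SimConfig
    rhs_times: np.ndarray  # (n+1,) kinematic-clock right heel strikes
    states: np.ndarray  # (2n, 9) per-side-centred measured state deviations
    fp_dev: np.ndarray  # (2n, 2) injected (AP, ML) placement deviations
    sides: np.ndarray  # (2n,) "L"/"R"
    errors: np.ndarray  # (2n,) injected stepping error
    cop_dev: np.ndarray  # (2n,)
    trunk_dev: np.ndarray  # (2n,)
    stepping_gains: np.ndarray
    ankle_gain: float
    trunk_gain: float
    clock_offset: float
    leg_length: float
    conditions: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = self.config.n_strides
        if self.states.shape != (2 * n, 9):
            raise ValueError("ground-truth state rows must equal 2*n_strides")

    @property
    def n_strides(self) -> int:
        return self.config.n_strides

    def frame(self) -> pd.DataFrame:
        """One row per stride carrying both of its placements."""
        n = self.n_strides
        cols: dict[str, np.ndarray] = {"stride": np.arange(n)}
        cols["condition"] = self.conditions
        for j, tag in enumerate(("left", "right")):
            sel = slice(j, 2 * n, 2)
            cols[f"fp_dev_ap_{tag}"] = self.fp_dev[sel, 0]
            cols[f"fp_dev_ml_{tag}"] = self.fp_dev[sel, 1]
            cols[f"error_{tag}"] = self.errors[sel]
            cols[f"cop_dev_{tag}"] = self.cop_dev[sel]
            cols[f"trunk_dev_{tag}"] = self.trunk_dev[sel]
        return pd.DataFrame(cols)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "rhs_times": self.rhs_times.tolist(),
            "states": self.states.tolist(),
            "fp_dev": self.fp_dev.tolist(),
            "sides": self.sides.tolist(),
            "errors": self.errors.tolist(),
            "cop_dev": self.cop_dev.tolist(),
            "trunk_dev": self.trunk_dev.tolist(),
            "stepping_gains": self.stepping_gains.tolist(),
            "ankle_gain": self.ankle_gain,
            "trunk_gain": self.trunk_gain,
            "clock_offset": self.clock_offset,
            "leg_length": self.leg_length,
            "conditions": self.conditions.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            config=SimConfig.from_dict(d["config"]),
            rhs_times=np.asarray(d["rhs_times"]),
            states=np.asarray(d["states"]),
            fp_dev=np.asarray(d["fp_dev"]),
            sides=np.asarray(d["sides"]),
            errors=np.asarray(d["errors"]),
            cop_dev=np.asarray(d["cop_dev"]),
            trunk_dev=np.asarray(d["trunk_dev"]),
            stepping_gains=np.asarray(d["stepping_gains"]),
            ankle_gain=d["ankle_gain"],
            trunk_gain=d["trunk_gain"],
            clock_offset=d["clock_offset"],
            leg_length=d["leg_length"],
            conditions=np.asarray(d["conditions"]),
        )


# ---------------------------------------------------------------------------


def _foot_track(
    t: np.ndarray,
    land_times: np.ndarray,
    placements: np.ndarray,
    stance_dur: float,
    lift: float,
) -> np.ndarray:
    """Heel trajectory through a sequence of placements.

    Constant during stance; AP/ML interpolate with a C^2 smootherstep during
    swing while the height follows a half-sine of amplitude ``lift`` (sharp
    enough near touchdown that contact onsets are unambiguous at sample
    resolution).
    """
    pos = np.tile(placements[0], (len(t), 1))
    for i, s0 in enumerate(land_times):
        s1 = s0 + stance_dur
        a = np.searchsorted(t, s0 - 1e-9)
        b = np.searchsorted(t, s1 + 1e-9)
        pos[a:b] = placements[i]
        if i + 1 < len(land_times):
            e = land_times[i + 1]
            c = np.searchsorted(t, e - 1e-9)
            tau = (t[b:c] - s1) / (e - s1)
            s = _smootherstep(tau)
            pos[b:c, 0] = placements[i, 0] + s * (placements[i + 1, 0] - placements[i, 0])
            pos[b:c, 1] = placements[i, 1] + s * (placements[i + 1, 1] - placements[i, 1])
            pos[b:c, 2] = lift * np.sin(np.pi * tau)
        else:
            pos[b:] = placements[i]
    return pos


def _grf_profile(s: np.ndarray) -> np.ndarray:
    """Two-peak stance profile on normalized stance time s in [0, 1]."""
    out = np.sin(np.pi * s) + 0.2 * np.sin(3 * np.pi * s)
    return np.clip(out, 0.0, None)


#: mean of the stance profile over [0, 1]; scales amplitude so that the
#: per-stride force impulse equals body weight times the stance fraction.
_GRF_PROFILE_MEAN = 2.0 / np.pi + 0.4 / (3.0 * np.pi)


def _solve_com_height(cfg: SimConfig) -> float:
    """CoM height such that the stance mt5->CoM distance averages to L."""
    f, T, v = cfg.stance_fraction, cfg.stride_time, cfg.speed
    tau = np.linspace(0.0, f * T, 60)
    # CoM relative to the stance mt5 marker over one right stance
    dx = (cfg.heel_lead + cfg.foot_length) - v * tau - cfg.ap_fluct_amp * np.sin(
        4 * np.pi * tau / T
    )
    phi = cfg.stance_fraction / 2.0
    p = tau / T
    dy = (-cfg.ml_sway_amp * np.cos(2 * np.pi * (p - phi))) - (
        -cfg.step_width / 2.0 - 0.035
    )
    dz_osc = cfg.vt_osc_amp * np.cos(4 * np.pi * (p - phi))

    def err(z0: float) -> float:
        d = np.sqrt(dx**2 + dy**2 + (z0 + dz_osc) ** 2)
        return float(np.mean(d)) - cfg.leg_length

    return brentq(err, 0.3 * cfg.leg_length, 1.5 * cfg.leg_length)


def simulate_walker(
    config: SimConfig,
) -> tuple[KinematicRecording, InsoleRecording, GroundTruth]:
    """Generate one synthetic walking trial.

    Returns the kinematic recording, the insole recording (on its own,
    possibly offset clock) and the :class:`GroundTruth` sidecar.  One
    warm-up stride precedes the ``n_strides`` ground-truth strides (its
    opening heel strike has no preceding swing, so contact detectors cannot
    see it); ``GroundTruth.rhs_times`` lists the heel strikes delimiting the
    analyzed strides.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_strides
    T, f = cfg.stride_time, cfg.stance_fraction
    v = cfg.speed
    rate = cfg.sample_rate_kin
    dt = 1.0 / rate
    t0 = _WALK_START
    n_gen = n + 1  # one warm-up stride
    t_end = t0 + (n_gen) * T + _TAIL
    t = np.arange(int(round(t_end * rate)) + 1) * dt

    # -- random draws (fixed order: determinism contract) -------------------
    w_cov, v_cov = np.linalg.eigh(cfg.com_state_cov)
    chol = v_cov @ np.diag(np.sqrt(np.clip(w_cov, 0.0, None)))
    z = rng.standard_normal((2 * n, 9))
    d_pooled = z @ chol.T  # drawn midstance-state deviations (pooled signs)
    eps = rng.normal(0.0, cfg.fp_noise_sd, size=(2 * n, 2))
    cop_free = rng.normal(0.0, cfg.cop_dev_sd, size=2 * n)
    comp_noise = rng.normal(0.0, cfg.compensation_noise_sd, size=2 * n)
    trunk_free = rng.normal(0.0, cfg.trunk_fallback_sd, size=2 * n)

    # -- event schedule (kinematic clock; all on both sample grids) ---------
    rhs_gen = t0 + np.arange(n_gen + 1) * T  # T_0 .. T_{n_gen}
    sides = np.array(["L", "R"] * n)
    strides = np.arange(1, n + 1)  # generator indices of analyzed strides
    ms_times = np.empty(2 * n)
    anchors = np.empty(2 * n)
    hs_times = np.empty(2 * n)
    for i, k in enumerate(strides):
        Tk = t0 + k * T
        ms_times[2 * i] = Tk + (f / 2.0) * T  # right-stance midstance
        ms_times[2 * i + 1] = Tk + (f + 1.0) / 2.0 * T  # left-stance midstance
        anchors[2 * i] = anchors[2 * i + 1] = Tk
        hs_times[2 * i] = Tk + T / 2.0  # left placement
        hs_times[2 * i + 1] = Tk + T  # right placement

    # -- continuous CoM / trunk signals -------------------------------------
    p = (t - t0) / T
    env = _smootherstep((t - (t0 - _ONSET_DUR)) / _ONSET_DUR)
    phi = f / 2.0

    x_walk = v * (t - t0) + cfg.ap_fluct_amp * np.sin(4 * np.pi * p)
    x_stand = cfg.heel_lead - cfg.stride_length / 4.0
    com_x = x_stand + (x_walk - x_stand) * env
    com_y = (-cfg.ml_sway_amp * np.cos(2 * np.pi * (p - phi))) * env
    z0 = _solve_com_height(cfg)
    com_z = z0 + (cfg.vt_osc_amp * np.cos(4 * np.pi * (p - phi))) * env

    # jump flights: free-fall parabolas with matching force unloading
    for a in _FLIGHT_STARTS:
        b = a + _FLIGHT_DUR
        m = (t >= a) & (t <= b)
        tau = t[m] - a
        v0 = cfg.gravity * _FLIGHT_DUR / 2.0
        com_z[m] += v0 * tau - 0.5 * cfg.gravity * tau**2

    # midstance state bumps: localized C^2 perturbations carrying the drawn
    # position/velocity/acceleration deviations (physical ML sign flipped
    # for left placements)
    h = cfg.bump_halfwidth
    d_phys = d_pooled.copy()
    left = sides == "L"
    for c in ML_STATE_IDX:
        d_phys[left, c] *= -1.0
    com = np.column_stack([com_x, com_y, com_z])
    for s_idx in range(2 * n):
        m = ms_times[s_idx]
        a = np.searchsorted(t, m - h)
        b = np.searchsorted(t, m + h, side="right")
        u = t[a:b] - m
        w = _bump_window(u, h)
        for axis in range(3):
            pos_d, vel_d, acc_d = (
                d_phys[s_idx, axis],
                d_phys[s_idx, axis + 3],
                d_phys[s_idx, axis + 6],
            )
            com[a:b, axis] += (pos_d + vel_d * u + 0.5 * acc_d * u**2) * w

    # -- measure the states exactly as the analysis does --------------------
    vel, acc = kinematic_derivatives(com, rate)
    states = np.empty((2 * n, 9))
    for s_idx in range(2 * n):
        anchor_idx = int(round(anchors[s_idx] * rate))
        states[s_idx] = midstance_state_raw(
            t, com, vel, acc, anchor_idx, ms_times[s_idx]
        )
    for c in ML_STATE_IDX:  # into the pooled convention
        states[left, c] *= -1.0
    states_c = center_by_side(states, sides)

    # -- controller: placement deviations from the measured states ----------
    fp_dev = states_c @ cfg.stepping_gains.T + eps  # (2n, 2) pooled

    # stepping error (Eq. 3 analogue) from the generator's own ML fit,
    # then compensation channels solved so that
    # error = ankle_gain * cop + trunk_gain * trunk + residual
    try:
        reg = fit_stepping(states, fp_dev, sides, direction="ML", min_steps=2)
        errors = compute_fp_error(reg)
    except Exception:
        errors = -center_by_side(eps[:, 1], sides)
    cop_dev = cop_free
    if cfg.trunk_gain != 0.0:
        trunk_dev = (errors - cfg.ankle_gain * cop_dev - comp_noise) / cfg.trunk_gain
    elif cfg.ankle_gain != 0.0:
        trunk_dev = trunk_free
        cop_dev = (errors - cfg.trunk_gain * trunk_dev - comp_noise) / cfg.ankle_gain
    else:
        trunk_dev = trunk_free  # both gains zero: error is pure residual

    # -- foot placements -----------------------------------------------------
    conditions = (
        np.asarray(cfg.condition_tags)
        if cfg.condition_tags is not None
        else np.array(["S"] * n)
    )
    cond_off = np.array(
        [cfg.condition_fw_offsets.get(c, 0.0) for c in conditions]
    )
    lead = cfg.heel_lead + cfg.fw_mos_offset
    warm_off = cond_off[0] if n else 0.0

    right_land = rhs_gen  # landings at T_0 .. T_{n_gen}
    right_place = np.zeros((len(right_land), 3))
    for j, tj in enumerate(right_land):
        off = warm_off if j < 2 else cond_off[j - 2]
        dev = np.zeros(2) if j < 2 else fp_dev[2 * (j - 2) + 1]
        right_place[j] = [
            v * (tj - t0) + lead + off + dev[0],
            -cfg.step_width / 2.0 + dev[1],  # pooled == physical for right
            0.0,
        ]

    left_land = t0 + np.arange(n_gen) * T + T / 2.0  # LHS_0 .. LHS_{n_gen-1}
    left_place = np.zeros((len(left_land) + 1, 3))
    left_place[0] = [v * (-T / 2.0) + cfg.heel_lead, cfg.step_width / 2.0, 0.0]
    for k, tk in enumerate(left_land):
        off = warm_off if k < 1 else cond_off[k - 1]
        dev = np.zeros(2) if k < 1 else fp_dev[2 * (k - 1)]
        left_place[k + 1] = [
            v * (tk - t0) + lead + off + dev[0],
            cfg.step_width / 2.0 - dev[1],  # mirror: physical = -pooled
            0.0,
        ]

    stance_dur = f * T
    heel_r = _foot_track(t, right_land, right_place, stance_dur, cfg.heel_lift)
    # virtual pre-walk left landing one period before LHS_0 holds the foot
    # through standing and gives it a toe-off at t0 + (f - 1/2) T
    left_land_full = np.concatenate([[left_land[0] - T], left_land])
    heel_l = _foot_track(t, left_land_full, left_place, stance_dur, cfg.heel_lift)

    mt5_r = heel_r + np.array([cfg.foot_length, -0.035, 0.0])
    mt1_r = heel_r + np.array([cfg.foot_length + 0.02, 0.035, 0.0])
    mt5_l = heel_l + np.array([cfg.foot_length, 0.035, 0.0])
    mt1_l = heel_l + np.array([cfg.foot_length + 0.02, -0.035, 0.0])

    landmarks = {
        "com": com,
        "sacrum": com + np.array([-0.03, 0.0, -0.12]),
        "c7": com + np.array([0.0, 0.0, 0.55]),
        "r_heel": heel_r,
        "l_heel": heel_l,
        "r_mt5": mt5_r,
        "l_mt5": mt5_l,
        "r_mt1": mt1_r,
        "l_mt1": mt1_l,
        "r_hip": com + np.array([-0.02, -0.09, -0.15]),
        "l_hip": com + np.array([-0.02, 0.09, -0.15]),
    }

    # -- trunk angular velocity (deg/s) --------------------------------------
    trunk = cfg.trunk_sway_amp * np.sin(4 * np.pi * (p - phi)) * env
    for s_idx in range(2 * n):
        k = strides[s_idx // 2]
        Tk = t0 + k * T
        if sides[s_idx] == "L":  # right-stance single support window
            a, b = Tk + (f - 0.5) * T, Tk + 0.5 * T
            sgn = -1.0
        else:  # left-stance single support window
            a, b = Tk + f * T, Tk + T
            sgn = 1.0
        ia = int(round(a * rate))
        ib = int(round(b * rate))
        trunk[ia : ib + 1] += sgn * trunk_dev[s_idx]

    kin = KinematicRecording(
        make_kinematic_frame(t, landmarks, trunk), rate
    )

    # -- insole streams -------------------------------------------------------
    insole = _build_insoles(
        cfg, t_end, rhs_gen, left_land_full, stance_dur, cop_dev, sides
    )

    gt = GroundTruth(
        config=cfg,
        rhs_times=rhs_gen[1:],
        states=states_c,
        fp_dev=fp_dev,
        sides=sides,
        errors=np.asarray(errors),
        cop_dev=np.asarray(cop_dev),
        trunk_dev=np.asarray(trunk_dev),
        stepping_gains=cfg.stepping_gains.copy(),
        ankle_gain=cfg.ankle_gain,
        trunk_gain=cfg.trunk_gain,
        clock_offset=cfg.clock_offset,
        leg_length=cfg.leg_length,
        conditions=conditions,
    )
    return kin, insole, gt


def _build_insoles(
    cfg: SimConfig,
    t_end: float,
    rhs_gen: np.ndarray,
    left_land_full: np.ndarray,
    stance_dur: float,
    cop_dev: np.ndarray,
    sides: np.ndarray,
) -> InsoleRecording:
    """Per-foot vGRF and CoP on the (possibly offset) insole clock."""
    n = cfg.n_strides
    dt = 1.0 / cfg.sample_rate_insole
    t0 = _WALK_START
    n_samp = int(round((t_end - cfg.clock_offset) / dt)) + 1
    t_ins = np.arange(n_samp) * dt
    tk = t_ins + cfg.clock_offset  # kinematic-clock equivalents

    weight = cfg.body_mass * cfg.gravity
    amp = weight / _GRF_PROFILE_MEAN

    # per-stance CoP offsets (physical sign): a right placement (pooled sign
    # +1) is served by the left-foot stance containing it, a left placement
    # (pooled sign -1) by the right-foot stance
    cop_off_left = {}  # key: index into left stance list
    cop_off_right = {}
    for s_idx in range(2 * n):
        k = s_idx // 2 + 1  # analyzed generator stride
        if sides[s_idx] == "R":
            cop_off_left[k + 1] = cop_dev[s_idx]  # stance landing at LHS_k -> idx k+1
        else:
            cop_off_right[k] = -cop_dev[s_idx]  # stance landing at T_k

    def foot_signals(starts: np.ndarray, cop_offsets: dict) -> tuple[np.ndarray, np.ndarray]:
        force = np.zeros_like(tk)
        cop = np.zeros_like(tk)
        for i, s0 in enumerate(starts):
            s1 = s0 + stance_dur
            a = np.searchsorted(tk, s0 - 1e-9)
            b = np.searchsorted(tk, s1 + 1e-9)
            s = (tk[a:b] - s0) / stance_dur
            force[a:b] = amp * _grf_profile(s)
            cop[a:b] = 0.004 * np.sin(2 * np.pi * s) + cop_offsets.get(i, 0.0)
        return force, cop

    f_gait_r, cop_r = foot_signals(rhs_gen, cop_off_right)
    f_gait_l, cop_l = foot_signals(left_land_full, cop_off_left)

    # standing force with jump unloading and landing spikes
    f_stand = np.full_like(tk, weight / 2.0)
    for a in _FLIGHT_STARTS:
        b = a + _FLIGHT_DUR
        f_stand[(tk >= a) & (tk < b)] = 0.0
        m = (tk >= b) & (tk < b + _SPIKE_DUR)
        f_stand[m] = weight / 2.0 + 1.2 * weight * np.sin(
            np.pi * (tk[m] - b) / _SPIKE_DUR
        )
    fade = _smootherstep((tk - (t0 - _FORCE_FADE)) / _FORCE_FADE)
    force_r = (1.0 - fade) * f_stand + fade * f_gait_r
    force_l = (1.0 - fade) * f_stand + fade * f_gait_l

    cop_r = np.where(force_r >= 1.0, cop_r, np.nan)
    cop_l = np.where(force_l >= 1.0, cop_l, np.nan)

    left_df = pd.DataFrame({"time": t_ins, "vgrf": force_l, "cop_ml": cop_l})
    right_df = pd.DataFrame({"time": t_ins, "vgrf": force_r, "cop_ml": cop_r})
    return InsoleRecording(left_df, right_df, cfg.sample_rate_insole)


# ---------------------------------------------------------------------------


FIXTURE_CONFIGS: dict[str, dict] = {
    "noiseless": dict(fp_noise_sd=0.0, compensation_noise_sd=0.0),
    "noisy": dict(),
    "zero_gain": dict(
        stepping_gains=np.zeros((2, 9)), fp_noise_sd=0.0
    ),
    "offset_clock": dict(clock_offset=0.37),
}


def make_fixture_suite(
    out_dir: str | Path,
    n_strides: int = 40,
    seed: int = 0,
    base: SimConfig | None = None,
) -> dict[str, dict[str, Path]]:
    """Write the named fixture library (CSV streams + JSON sidecars).

    Produces one subdirectory per fixture (noiseless, noisy, zero_gain,
    offset_clock), each holding ``kinematics.csv``, ``insole_left.csv``,
    ``insole_right.csv`` and ``ground_truth.json`` (which embeds the full
    SimConfig).  Returns the path map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base or SimConfig()
    paths: dict[str, dict[str, Path]] = {}
    for name, overrides in FIXTURE_CONFIGS.items():
        cfg = replace(base, n_strides=n_strides, seed=seed, **overrides)
        kin, insole, gt = simulate_walker(cfg)
        d = out_dir / name
        d.mkdir(exist_ok=True)
        files = {
            "kinematics": d / "kinematics.csv",
            "insole_left": d / "insole_left.csv",
            "insole_right": d / "insole_right.csv",
            "ground_truth": d / "ground_truth.json",
        }
        kin.to_csv(files["kinematics"])
        insole.to_csv(files["insole_left"], files["insole_right"])
        gt.to_json(files["ground_truth"])
        paths[name] = files
    return paths
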