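"""Gait-event detection, kinematic/insole clock synchronization, resampling.

A stride runs from one right heel strike to the next.  Heel strikes and toe
offs are detected independently from the insole forces (threshold crossing,
30 N by default) and from the heel/toe marker kinematics (contact-height
scheme).  The two streams are aligned with a constant clock offset estimated
from the jump events subjects perform at the start of a trial: during flight
the insoles unload (< 30 N) while the centre of mass is in free fall
(vertical acceleration ~ -g), and cross-correlating the two flight masks
recovers the offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .recordings import InsoleRecording, KinematicRecording

DEFAULT_FORCE_THRESHOLD = 30.0  # N
DEFAULT_REFRACTORY = 0.2  # s, minimum unloaded interval before a new contact
CONTACT_TOL = 0.002  # m, marker height band counted as ground contact


class EventDetectionError(RuntimeError):
    """Raised when a recording does not contain a usable gait pattern."""


@dataclass
class GaitEvents:
    """Sample indices of gait events on the kinematic clock.

    ``clock_offset`` is the constant to ADD to insole timestamps to express
    them on the kinematic clock (kin_time = insole_time + clock_offset).
    """

    right_heel_strikes: np.ndarray
    right_toe_offs: np.ndarray
    left_heel_strikes: np.ndarray
    left_toe_offs: np.ndarray
    clock_offset: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "right_heel_strikes",
            "right_toe_offs",
            "left_heel_strikes",
            "left_toe_offs",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))

    def validate(self) -> "GaitEvents":
        """Check ordering/alternation invariants; raise on violation."""
        for name in (
            "right_heel_strikes",
            "right_toe_offs",
            "left_heel_strikes",
            "left_toe_offs",
        ):
            ev = getattr(self, name)
            if len(ev) > 1 and np.any(np.diff(ev) <= 0):
                raise EventDetectionError(f"{name} not strictly increasing")
        rhs, rto = self.right_heel_strikes, self.right_toe_offs
        # each right toe-off must fall between consecutive right heel strikes
        for a, b in zip(rhs[:-1], rhs[1:]):
            inside = rto[(rto > a) & (rto < b)]
            if len(inside) != 1:
                raise EventDetectionError(
                    f"expected exactly one right toe-off in stride [{a}, {b}], "
                    f"found {len(inside)}"
                )
        return self


def detect_heel_strikes_force(
    insole: InsoleRecording | np.ndarray,
    threshold: float = DEFAULT_FORCE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    rate: float | None = None,
    side: str = "right",
) -> np.ndarray:
    """Heel-strike indices from an insole vGRF channel.

    An event is the first sample at which the force exceeds ``threshold``
    after the foot has been unloaded (below threshold) for at least
    ``refractory`` seconds.  A signal that never crosses the threshold yields
    an empty array.
    """
    if threshold <= 0:
        raise ValueError("force threshold must be positive")
    if isinstance(insole, InsoleRecording):
        force = insole.foot(side)["vgrf"].to_numpy()
        rate = insole.rate
    else:
        force = np.asarray(insole, float)
        if rate is None:
            raise ValueError("rate is required when passing a bare array")
    if np.any(force < -1e-9):
        raise ValueError("vertical GRF must be non-negative")

    above = force >= threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    min_gap = int(math.ceil(refractory * rate))
    events = []
    for idx in rising:
        # before the signal starts the foot is assumed unloaded, so an early
        # crossing with an incomplete history still counts
        start = max(idx - min_gap, 0)
        if np.all(~above[start:idx]):
            events.append(idx)
    return np.asarray(events, dtype=int)


def _contact_mask(height: np.ndarray, tol: float = CONTACT_TOL) -> np.ndarray:
    floor = np.min(height)
    return height <= floor + tol


def _contact_transitions(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(entries, exits): first in-contact sample; last in-contact sample."""
    d = np.diff(mask.astype(int))
    entries = np.flatnonzero(d == 1) + 1
    exits = np.flatnonzero(d == -1)
    return entries, exits


def _foot_events(
    heel: np.ndarray,
    toe: np.ndarray,
    rate: float,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Heel strikes and toe offs of one foot from marker heights.

    Heel strike: the heel marker enters its contact band after an airborne
    interval, with the heel's horizontal speed having dropped from its swing
    peak (guards against sliding artefacts).  Toe off: the toe (mt1) marker
    leaves its contact band with sustained upward velocity afterwards.
    """
    heel_z = heel[:, 2]
    toe_z = toe[:, 2]
    hs_candidates, _ = _contact_transitions(_contact_mask(heel_z, tol))
    _, to_candidates = _contact_transitions(_contact_mask(toe_z, tol))

    # forward speed of the heel, sign-free guard
    heel_speed = np.abs(np.gradient(heel[:, 0], 1.0 / rate))
    peak = np.percentile(heel_speed, 95) if len(heel_speed) else 0.0

    win = max(1, int(round(0.05 * rate)))  # +/- 50 ms
    strikes = []
    for idx in hs_candidates:
        lo, hi = max(0, idx - win), min(len(heel_speed), idx + win + 1)
        if peak > 0 and np.min(heel_speed[lo:hi]) > 0.5 * peak:
            continue  # still translating at swing speed: not a contact
        strikes.append(idx)

    hold = max(1, int(round(0.025 * rate)))  # 25 ms of sustained lift
    toe_vz = np.gradient(toe_z, 1.0 / rate)
    toe_offs = []
    for idx in to_candidates:
        seg = toe_vz[idx + 1 : idx + 1 + hold]
        if len(seg) and np.all(seg > 0):
            toe_offs.append(idx)
    return np.asarray(strikes, dtype=int), np.asarray(toe_offs, dtype=int)


def detect_events_kinematic(
    kin: KinematicRecording,
    contact_tol: float = CONTACT_TOL,
) -> GaitEvents:
    """Detect all four gait-event trains from heel and toe markers.

    Raises :class:`EventDetectionError` when fewer than two right heel
    strikes are found (no stride can be delimited, e.g. standing still).
    The returned events satisfy the ordering invariants of
    :class:`GaitEvents` (validated before returning).
    """
    rhs, rto = _foot_events(
        kin.landmark("r_heel"), kin.landmark("r_mt1"), kin.rate, contact_tol
    )
    lhs, lto = _foot_events(
        kin.landmark("l_heel"), kin.landmark("l_mt1"), kin.rate, contact_tol
    )
    if len(rhs) < 2:
        raise EventDetectionError(
            f"found {len(rhs)} right heel strikes; need at least 2 to delimit "
            "a stride (is the subject walking?)"
        )
    return GaitEvents(rhs, rto, lhs, lto).validate()


def _flight_mask_kinematic(
    kin: KinematicRecording, g: float, accel_tol: float
) -> np.ndarray:
    com_z = kin.landmark("com")[:, 2]
    dt = 1.0 / kin.rate
    acc = np.gradient(np.gradient(com_z, dt), dt)
    return np.abs(acc + g) < accel_tol


def synchronize_jumps(
    kin: KinematicRecording,
    insole: InsoleRecording,
    g: float = 9.806,
    force_threshold: float = DEFAULT_FORCE_THRESHOLD,
    accel_tol: float = 3.0,
    window: float = 30.0,
    min_flight: float = 0.1,
) -> float:
    """Estimate the insole->kinematic clock offset from the jump events.

    Both streams are reduced to binary "flight" masks over their first
    ``window`` seconds (insoles: total force < ``force_threshold``;
    kinematics: vertical CoM acceleration within ``accel_tol`` of -g).  The
    offset maximizing the cross-correlation of the masks aligns the landing
    transients; it is returned in seconds such that
    ``kin_time = insole_time + offset``.
    """
    n_kin = min(kin.n_samples, int(window * kin.rate))
    n_ins = min(len(insole.time), int(window * insole.rate))
    kin_mask = _flight_mask_kinematic(kin, g, accel_tol)[:n_kin]
    ins_mask = (insole.total_force() < force_threshold)[:n_ins]

    min_run_kin = int(min_flight * kin.rate)
    min_run_ins = int(min_flight * insole.rate)
    if _longest_run(kin_mask) < min_run_kin:
        raise EventDetectionError("no flight phase found in the kinematic stream")
    if _longest_run(ins_mask) < min_run_ins:
        raise EventDetectionError("no flight phase found in the insole stream")

    # resample the kinematic mask onto the insole rate before correlating
    step = kin.rate / insole.rate
    idx = np.round(np.arange(0, n_kin, step)).astype(int)
    idx = idx[idx < n_kin]
    kin_rs = kin_mask[idx].astype(float)
    ins = ins_mask.astype(float)

    corr = _signal.correlate(kin_rs, ins, mode="full")
    lags = _signal.correlation_lags(len(kin_rs), len(ins), mode="full")
    # rectangular flight masks give a correlation plateau; its centre, not
    # its first sample, is the unbiased alignment
    at_max = lags[corr >= corr.max() - 1e-9]
    lag_seconds = float(np.mean(at_max)) / insole.rate
    # masks are indexed from each stream's own start time
    t0_kin = float(kin.time[0])
    t0_ins = float(insole.time[0])
    return t0_kin - t0_ins + lag_seconds


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def downsample(kin: KinematicRecording, target: float = 120.0) -> KinematicRecording:
    """Resample a kinematic recording to ``target`` Hz (polyphase, zero-phase).

    Duration is preserved to within one target-rate sample and low-frequency
    content passes unchanged; raises if ``target`` exceeds the source rate or
    is not positive.
    """
    if target <= 0:
        raise ValueError("target rate must be positive")
    if target > kin.rate:
        raise ValueError(
            f"cannot upsample: target {target} Hz > source {kin.rate} Hz"
        )
    if math.isclose(target, kin.rate):
        return KinematicRecording(kin.data.copy(), kin.rate)

    frac = _as_fraction(target / kin.rate)
    up, down = frac
    cols = {}
    for c in kin.data.columns:
        if c == "time":
            continue
        cols[c] = _signal.resample_poly(
            kin.data[c].to_numpy(), up, down, padtype="line"
        )
    n_out = len(next(iter(cols.values())))
    t0 = float(kin.time[0])
    time = t0 + np.arange(n_out) / target
    df = pd.DataFrame({"time": time, **cols})
    return KinematicRecording(df, target)


def _as_fraction(ratio: float, max_den: int = 1000) -> tuple[int, int]:
    from fractions import Fraction

    f = Fraction(ratio).limit_denominator(max_den)
    return f.numerator, f.denominator
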