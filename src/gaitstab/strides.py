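"""Stride segmentation, per-stride anatomical frames, percent-gait grids.

Each stride (right heel strike to right heel strike) gets its own coordinate
system: origin at the right heel at the initial heel strike, z the global
up direction, x the horizontal unit vector along the net sacrum displacement
over the stride (so x is the anterior-posterior direction regardless of
heading), and y = z cross x (mediolateral, pointing left).  Channels are
optionally resampled to a 101-point percent-gait grid (0..100 %) with
shape-preserving (PCHIP) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .events import GaitEvents
from .recordings import InsoleRecording, KinematicRecording, LANDMARKS


class StrideError(RuntimeError):
    pass


def kinematic_derivatives(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration by central differences on the sampled data.

    Differentiation is done on the uniformly sampled time series (before any
    percent-gait normalization) so that time warping never leaks into the
    dynamics.  Works on (n,) or (n, k) arrays.
    """
    dt = 1.0 / rate
    vel = np.gradient(x, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    return vel, acc


@dataclass
class StrideSlice:
    """One raw stride: sample range on the kinematic clock plus its events."""

    start: int  # right heel strike opening the stride
    end: int  # next right heel strike (inclusive end of the stride)
    right_toe_off: int
    left_heel_strike: int
    left_toe_off: int
    index: int = 0

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1


@dataclass
class StrideFrame:
    """Rigid transform from global coordinates into the stride frame."""

    rotation: np.ndarray  # (3, 3), rows are the AP/ML/VT unit vectors
    origin: np.ndarray  # (3,) right heel position at initial heel strike

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.rotation.T

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate free vectors (velocities, accelerations): no translation."""
        return np.asarray(vectors) @ self.rotation.T

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation + self.origin


@dataclass
class Stride:
    """A stride expressed in its own frame on the percent-gait grid.

    All arrays share the percent-gait length (101 points by default);
    0 % and 100 % are successive right heel strikes.  Event phases are in
    percent gait.  ``landmarks`` maps landmark name -> (n, 3) array in
    stride-frame coordinates; ``com_vel``/``com_acc`` are stride-frame CoM
    derivatives computed on the raw 120 Hz data before resampling.
    """

    landmarks: dict[str, np.ndarray]
    com_vel: np.ndarray
    com_acc: np.ndarray
    trunk_angvel_ml: np.ndarray
    phases: dict[str, float]  # right_toe_off, left_heel_strike, left_toe_off
    duration: float
    condition: str = "S"
    leg_length: float = float("nan")
    vgrf: dict[str, np.ndarray] = field(default_factory=dict)
    cop_ml: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = {arr.shape[0] for arr in self.landmarks.values()}
        n |= {self.com_vel.shape[0], self.com_acc.shape[0], len(self.trunk_angvel_ml)}
        if len(n) != 1:
            raise StrideError("percent-gait arrays must share one length")
        if not (0.0 < self.phases["right_toe_off"] < 100.0):
            raise StrideError("right toe-off phase must lie inside the stride")
        if self.duration <= 0:
            raise StrideError("stride duration must be positive")

    @property
    def n_points(self) -> int:
        return next(iter(self.landmarks.values())).shape[0]


def segment_strides(events: GaitEvents) -> list[StrideSlice]:
    """Cut the event trains into per-stride slices.

    Requires at least two right heel strikes; strides missing an interior
    event (contralateral heel strike or either toe-off) are dropped.
    """
    rhs = events.right_heel_strikes
    if len(rhs) < 2:
        raise StrideError(
            f"need at least 2 right heel strikes to segment, got {len(rhs)}"
        )
    slices = []
    for k, (a, b) in enumerate(zip(rhs[:-1], rhs[1:])):
        rto = events.right_toe_offs[
            (events.right_toe_offs > a) & (events.right_toe_offs < b)
        ]
        lhs = events.left_heel_strikes[
            (events.left_heel_strikes > a) & (events.left_heel_strikes < b)
        ]
        lto = events.left_toe_offs[
            (events.left_toe_offs > a) & (events.left_toe_offs < b)
        ]
        if len(rto) != 1 or len(lhs) != 1 or len(lto) != 1:
            continue  # incomplete stride: skipped, caller may log
        slices.append(
            StrideSlice(
                start=int(a),
                end=int(b),
                right_toe_off=int(rto[0]),
                left_heel_strike=int(lhs[0]),
                left_toe_off=int(lto[0]),
                index=k,
            )
        )
    return slices


def build_stride_frame(kin: KinematicRecording, sl: StrideSlice) -> StrideFrame:
    """Anatomical frame of one stride.

    x: horizontal unit vector along the sacrum displacement from stride
    start to stride end (walking direction); z: global up; y = z cross x.
    Origin: right heel position at the opening heel strike.  Raises when the
    sacrum does not translate horizontally (standing in place).
    """
    sacrum = kin.landmark("sacrum")
    disp = sacrum[sl.end] - sacrum[sl.start]
    disp[2] = 0.0
    norm = np.linalg.norm(disp)
    if norm < 1e-6:
        raise StrideError("zero horizontal sacrum displacement: cannot orient stride")
    x = disp / norm
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    origin = kin.landmark("r_heel")[sl.start].copy()
    return StrideFrame(rotation=np.vstack([x, y, z]), origin=origin)


def normalize_percent_gait(
    kin: KinematicRecording,
    sl: StrideSlice,
    frame: StrideFrame | None = None,
    n_points: int = 101,
    condition: str = "S",
    insole: InsoleRecording | None = None,
    clock_offset: float = 0.0,
    force_threshold: float = 30.0,
) -> Stride:
    """Resample one stride to the percent-gait grid in its stride frame.

    Channels are interpolated with shape-preserving PCHIP; boundary samples
    are preserved exactly.  CoM velocity/acceleration are differentiated on
    the raw uniformly-sampled data first, then resampled.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if frame is None:
        frame = build_stride_frame(kin, sl)

    t = kin.time
    t_grid = np.linspace(t[sl.start], t[sl.end], n_points)
    idx = slice(sl.start, sl.end + 1)

    def resample(series: np.ndarray) -> np.ndarray:
        return PchipInterpolator(t[idx], series[idx], axis=0)(t_grid)

    landmarks = {
        name: resample(frame.apply(kin.landmark(name))) for name in LANDMARKS
    }
    com = kin.landmark("com")
    vel, acc = kinematic_derivatives(com, kin.rate)
    com_vel = resample(frame.apply_vector(vel))
    com_acc = resample(frame.apply_vector(acc))
    trunk = resample(kin.trunk_angvel_ml)

    duration = float(t[sl.end] - t[sl.start])
    phases = {
        "right_toe_off": 100.0 * (t[sl.right_toe_off] - t[sl.start]) / duration,
        "left_heel_strike": 100.0 * (t[sl.left_heel_strike] - t[sl.start]) / duration,
        "left_toe_off": 100.0 * (t[sl.left_toe_off] - t[sl.start]) / duration,
    }

    vgrf: dict[str, np.ndarray] = {}
    cop: dict[str, np.ndarray] = {}
    if insole is not None:
        for side in ("left", "right"):
            df = insole.foot(side)
            ti = df["time"].to_numpy() + clock_offset  # onto the kinematic clock
            for col, store in (("vgrf", vgrf), ("cop_ml", cop)):
                y = df[col].to_numpy()
                store[side] = np.interp(t_grid, ti, y)

    stride = Stride(
        landmarks=landmarks,
        com_vel=com_vel,
        com_acc=com_acc,
        trunk_angvel_ml=trunk,
        phases=phases,
        duration=duration,
        condition=condition,
        vgrf=vgrf,
        cop_ml=cop,
    )
    stride.leg_length = compute_leg_length(stride)
    return stride


def compute_leg_length(stride: Stride) -> float:
    """Inverted-pendulum leg length of one stride.

    Mean Euclidean distance from the stance-foot (right) fifth-metatarsal
    marker to the CoM over the right-foot stance phase of the stride.
    """
    mt5 = stride.landmarks.get("r_mt5")
    com = stride.landmarks.get("com")
    if mt5 is None or com is None:
        raise StrideError("missing r_mt5 or com landmark")
    n = stride.n_points
    stance_end = int(round(stride.phases["right_toe_off"] / 100.0 * (n - 1)))
    if stance_end < 1:
        raise StrideError("degenerate stance phase")
    d = np.linalg.norm(com[: stance_end + 1] - mt5[: stance_end + 1], axis=1)
    return float(np.mean(d))


def leg_length_raw(
    kin: KinematicRecording, sl: StrideSlice
) -> float:
    """Leg length from the raw (unnormalized) slice; same definition."""
    com = kin.landmark("com")[sl.start : sl.right_toe_off + 1]
    mt5 = kin.landmark("r_mt5")[sl.start : sl.right_toe_off + 1]
    if len(com) < 2:
        raise StrideError("degenerate stance phase")
    return float(np.mean(np.linalg.norm(com - mt5, axis=1)))
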