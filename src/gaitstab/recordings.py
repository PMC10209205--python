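"""In-memory containers for wearable gait recordings and their CSV schema.

Two streams are carried through the pipeline: a kinematic stream (3-D
landmark positions from IMU-based motion capture plus the mediolateral trunk
angular velocity) and a per-foot insole stream (vertical ground reaction
force and mediolateral centre of pressure).  The two streams run on
independent clocks; jump events recorded at the start of a trial are used to
estimate the constant offset between them (see :mod:`gaitstab.events`).

CSV schema
----------
Kinematics: a ``time`` column (s) followed by one ``<landmark>_<axis>``
column per landmark axis (axes ``x`` = walking direction, ``y`` = left,
``z`` = up) and a ``trunk_angvel_ml`` column in deg/s.

Insoles: one file per foot with columns ``time``, ``vgrf`` (N) and
``cop_ml`` (m, empty while the foot is off the ground).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Landmarks every kinematic recording is expected to carry.
LANDMARKS = (
    "com",
    "sacrum",
    "c7",
    "r_heel",
    "l_heel",
    "r_mt5",
    "l_mt5",
    "r_mt1",
    "l_mt1",
    "r_hip",
    "l_hip",
)

AXES = ("x", "y", "z")

TRUNK_COL = "trunk_angvel_ml"

#: Fixed text float format so that identical data serialize byte-identically.
_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A CSV file does not match the documented recording schema."""


def _landmark_cols(name: str) -> list[str]:
    return [f"{name}_{ax}" for ax in AXES]


@dataclass
class KinematicRecording:
    """Synchronized multi-landmark position time series at a fixed rate.

    Parameters
    ----------
    data
        Frame with a ``time`` column, ``<landmark>_<axis>`` position columns
        in metres and a ``trunk_angvel_ml`` column in deg/s.
    rate
        Sampling rate in Hz.
    """

    data: pd.DataFrame
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        missing = [
            c
            for name in LANDMARKS
            for c in _landmark_cols(name)
            if c not in self.data.columns
        ]
        if "time" not in self.data.columns:
            missing.insert(0, "time")
        if missing:
            raise SchemaError(f"kinematic recording missing columns: {missing}")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def landmark(self, name: str) -> np.ndarray:
        """Return the (n, 3) trajectory of one landmark."""
        try:
            return self.data[_landmark_cols(name)].to_numpy()
        except KeyError as exc:
            raise SchemaError(f"unknown landmark {name!r}") from exc

    @property
    def trunk_angvel_ml(self) -> np.ndarray:
        return self.data[TRUNK_COL].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path: str | Path, rate: float | None = None) -> "KinematicRecording":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise SchemaError(f"{path}: missing required column 'time'")
        if rate is None:
            t = df["time"].to_numpy()
            if len(t) < 2:
                raise SchemaError(f"{path}: cannot infer rate from <2 samples")
            rate = 1.0 / float(np.median(np.diff(t)))
        return cls(df, rate)


@dataclass
class InsoleRecording:
    """Per-foot vertical GRF and mediolateral CoP time series.

    ``left``/``right`` are frames with columns ``time`` (s), ``vgrf`` (N) and
    ``cop_ml`` (m; NaN while the foot is unloaded).  The insole clock is in
    general offset from the kinematic clock.
    """

    left: pd.DataFrame
    right: pd.DataFrame
    rate: float

    _REQUIRED = ("time", "vgrf", "cop_ml")

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        for side, df in (("left", self.left), ("right", self.right)):
            missing = [c for c in self._REQUIRED if c not in df.columns]
            if missing:
                raise SchemaError(f"{side} insole missing columns: {missing}")

    def foot(self, side: str) -> pd.DataFrame:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.left if side == "left" else self.right

    @property
    def time(self) -> np.ndarray:
        return self.left["time"].to_numpy()

    def total_force(self) -> np.ndarray:
        return self.left["vgrf"].to_numpy() + self.right["vgrf"].to_numpy()

    def to_csv(self, left_path: str | Path, right_path: str | Path) -> None:
        self.left.to_csv(left_path, index=False, float_format=_FLOAT_FMT)
        self.right.to_csv(right_path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(
        cls,
        left_path: str | Path,
        right_path: str | Path,
        rate: float | None = None,
    ) -> "InsoleRecording":
        left = pd.read_csv(left_path)
        right = pd.read_csv(right_path)
        for path, df in ((left_path, left), (right_path, right)):
            missing = [c for c in cls._REQUIRED if c not in df.columns]
            if missing:
                raise SchemaError(f"{path}: missing columns {missing}")
        if rate is None:
            t = left["time"].to_numpy()
            if len(t) < 2:
                raise SchemaError(f"{left_path}: cannot infer rate from <2 samples")
            rate = 1.0 / float(np.median(np.diff(t)))
        return cls(left, right, rate)


def make_kinematic_frame(
    time: np.ndarray,
    landmarks: dict[str, np.ndarray],
    trunk_angvel_ml: np.ndarray,
) -> pd.DataFrame:
    """Assemble the schema frame from per-landmark (n, 3) arrays."""
    cols: dict[str, np.ndarray] = {"time": np.asarray(time, float)}
    for name in LANDMARKS:
        arr = np.asarray(landmarks[name], float)
        if arr.shape != (len(time), 3):
            raise ValueError(f"landmark {name!r} must have shape (n, 3)")
        for j, ax in enumerate(AXES):
            cols[f"{name}_{ax}"] = arr[:, j]
    cols[TRUNK_COL] = np.asarray(trunk_angvel_ml, float)
    return pd.DataFrame(cols)
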