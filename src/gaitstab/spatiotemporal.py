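"""The five spatiotemporal gait measures and their RMS variabilities.

Per stride: stride time (between successive right heel strikes), stance
time (right heel strike to right toe off), speed (mean AP CoM velocity),
stride length (AP distance between the right heel positions opening and
closing the stride) and step width (ML distance between the right and left
heel markers at their respective heel strikes, reported as a magnitude).
Per subject: mean and RMS variability (intra-subject sample standard
deviation) of each measure, raw and nondimensional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .strides import Stride

MEASURES = ("stride_time", "stance_time", "speed", "stride_length", "step_width")


def compute_spatiotemporal(stride: Stride) -> dict[str, float]:
    """The five spatiotemporal scalars of one percent-gait stride."""
    n = stride.n_points
    lhs_idx = int(round(stride.phases["left_heel_strike"] / 100.0 * (n - 1)))
    r_heel = stride.landmarks["r_heel"]
    l_heel = stride.landmarks["l_heel"]
    out = {
        "stride_time": stride.duration,
        "stance_time": stride.phases["right_toe_off"] / 100.0 * stride.duration,
        "speed": float(np.mean(stride.com_vel[:, 0])),
        "stride_length": float(r_heel[-1, 0] - r_heel[0, 0]),
        "step_width": float(abs(l_heel[lhs_idx, 1] - r_heel[0, 1])),
    }
    if not out["stance_time"] < out["stride_time"]:
        raise ValueError("stance time must be shorter than stride time")
    return out


def summarize(
    per_stride: pd.DataFrame,
    measures: tuple[str, ...] = MEASURES,
    by: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mean and RMS variability (sample SD) per measure, optionally grouped.

    Rows with fewer than two strides report NaN variability (SD undefined).
    Returns a tidy frame: grouping columns + measure, mean, variability.
    """
    def _rows(df: pd.DataFrame) -> list[dict]:
        rows = []
        for m in measures:
            vals = df[m].dropna().to_numpy()
            rows.append(
                {
                    "measure": m,
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "variability": float(np.std(vals, ddof=1))
                    if len(vals) > 1
                    else np.nan,
                    "n_strides": len(vals),
                }
            )
        return rows

    if not by:
        return pd.DataFrame(_rows(per_stride))
    out = []
    for keys, df in per_stride.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for row in _rows(df):
            out.append(dict(zip(by, keys)) | row)
    return pd.DataFrame(out)


def nondimensionalize_measures(
    df: pd.DataFrame, leg_length: float, gravity: float = 9.806
) -> pd.DataFrame:
    """Scale the per-stride measures by the inverted-pendulum factors.

    Times divide by sqrt(L/g), lengths by L, velocities by sqrt(gL).
    """
    scales = {
        "stride_time": np.sqrt(leg_length / gravity),
        "stance_time": np.sqrt(leg_length / gravity),
        "speed": np.sqrt(gravity * leg_length),
        "stride_length": leg_length,
        "step_width": leg_length,
    }
    out = df.copy()
    for m, s in scales.items():
        if m in out.columns:
            out[m] = out[m] / s
    return out
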