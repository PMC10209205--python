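"""Extrapolated centre of mass and margins of stability.

The extrapolated centre of mass (XCoM) augments the CoM position with its
velocity scaled by the inverted-pendulum time constant:

    XCoM = CoM + sqrt(L / g) * dCoM/dt      (per horizontal component)

Margins of stability are signed distances between the XCoM and the edges of
the base of support.  In the anterior-posterior direction two margins are
evaluated at each heel strike: the forward margin (FW MoS), from the XCoM to
the heel marker of the anterior foot, and the backward margin (BW MoS), from
the fifth-metatarsal marker of the posterior foot to the XCoM.  A larger
FW MoS means more resistance to a forward loss of stability.  The
mediolateral margin (ML MoS) is the minimum signed distance from the XCoM to
the stance-foot fifth-metatarsal marker during single stance, positive when
the XCoM is medial to the marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .strides import Stride

GRAVITY = 9.806  # m/s^2, value used for nondimensionalization throughout


class MosWarning(UserWarning):
    """A stride was skipped in an MoS computation (missing events)."""


def compute_xcom(
    com: np.ndarray,
    com_vel: np.ndarray,
    leg_length: float,
    g: float = GRAVITY,
) -> np.ndarray:
    """Extrapolated centre of mass, elementwise over any matching shapes."""
    if leg_length <= 0:
        raise ValueError("leg length must be positive")
    if g <= 0:
        raise ValueError("gravity must be positive")
    return np.asarray(com) + np.sqrt(leg_length / g) * np.asarray(com_vel)


def ap_margins_at(
    heel_anterior_x: float, mt5_posterior_x: float, xcom_x: float
) -> tuple[float, float]:
    """FW and BW margins at one heel-strike instant (AP coordinates in m)."""
    fw = heel_anterior_x - xcom_x
    bw = xcom_x - mt5_posterior_x
    return fw, bw


def compute_ap_mos(stride: Stride, g: float = GRAVITY) -> tuple[np.ndarray, np.ndarray]:
    """FW/BW margins of stability at both heel strikes of a stride.

    Returns two length-2 arrays ``(fw, bw)`` ordered (left heel strike,
    closing right heel strike).  The anterior foot at each instant is
    resolved by comparing the AP heel positions rather than assuming the
    striking foot leads.  The identity ``fw + bw == AP BoS extent`` holds per
    event by construction.
    """
    n = stride.n_points
    lhs_idx = int(round(stride.phases["left_heel_strike"] / 100.0 * (n - 1)))
    events = [(lhs_idx, "left"), (n - 1, "right")]
    com = stride.landmarks["com"]
    xcom = compute_xcom(com, stride.com_vel, stride.leg_length, g)
    fw = np.empty(2)
    bw = np.empty(2)
    for i, (idx, _striking) in enumerate(events):
        rx = stride.landmarks["r_heel"][idx, 0]
        lx = stride.landmarks["l_heel"][idx, 0]
        if rx >= lx:
            ant_heel = rx
            post_mt5 = stride.landmarks["l_mt5"][idx, 0]
        else:
            ant_heel = lx
            post_mt5 = stride.landmarks["r_mt5"][idx, 0]
        fw[i], bw[i] = ap_margins_at(ant_heel, post_mt5, xcom[idx, 0])
    return fw, bw


def compute_ml_mos(stride: Stride, g: float = GRAVITY) -> float:
    """ML margin of stability over the right-foot single-stance window.

    Minimum over single stance (left toe-off to left heel strike) of the
    signed ML distance from the XCoM to the right fifth-metatarsal marker,
    positive when the XCoM lies medial (toward the body midline) to the
    marker.  Returns NaN (with a warning) when the window is empty.
    """
    n = stride.n_points
    a = int(round(stride.phases["left_toe_off"] / 100.0 * (n - 1)))
    b = int(round(stride.phases["left_heel_strike"] / 100.0 * (n - 1)))
    if b <= a:
        warnings.warn("empty single-stance window; stride skipped", MosWarning)
        return float("nan")
    com = stride.landmarks["com"][a : b + 1]
    vel = stride.com_vel[a : b + 1]
    xcom_y = compute_xcom(com[:, 1], vel[:, 1], stride.leg_length, g)
    mt5_y = stride.landmarks["r_mt5"][a : b + 1, 1]
    # right stance foot: medial is +y (toward the midline)
    signed = xcom_y - mt5_y
    return float(np.min(signed))


def ml_margin_series(
    xcom_ml: np.ndarray, mt5_ml: np.ndarray, stance_side: str
) -> np.ndarray:
    """Signed ML margin samples, positive when the XCoM is medial."""
    if stance_side == "right":
        return np.asarray(xcom_ml) - np.asarray(mt5_ml)
    if stance_side == "left":
        return np.asarray(mt5_ml) - np.asarray(xcom_ml)
    raise ValueError(f"stance_side must be 'left' or 'right', got {stance_side!r}")


@dataclass
class MosResult:
    """Per-subject MoS summary: per-stride values, mean and RMS variability."""

    fw_mos: np.ndarray
    bw_mos: np.ndarray
    ml_mos: np.ndarray

    def summary(self) -> dict[str, float]:
        out = {}
        for name, arr in (
            ("fw_mos", self.fw_mos),
            ("bw_mos", self.bw_mos),
            ("ml_mos", self.ml_mos),
        ):
            arr = np.asarray(arr, float)
            arr = arr[np.isfinite(arr)]
            out[f"{name}_mean"] = float(np.mean(arr)) if len(arr) else float("nan")
            out[f"{name}_variability"] = (
                float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
            )
        return out
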