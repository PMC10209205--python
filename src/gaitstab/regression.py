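"""Stepping-strategy and ankle/trunk-compensation regressions.

The stepping regression relates the deviation of each foot placement to the
deviation of the CoM state (position, velocity, acceleration in AP/ML/VT) at
the midstance of the preceding single-support phase:

    dFP = b1 dCoM_x + b2 dCoM_y + b3 dCoM_z
        + b4 dCoM'_x + b5 dCoM'_y + b6 dCoM'_z
        + b7 dCoM''_x + b8 dCoM''_y + b9 dCoM''_z

fitted once per subject in the AP and once in the ML direction by ordinary
least squares without intercept (all variables mean-centred).  The
prediction error of the ML fit (predicted minus actual placement) is then
regressed on the stance-foot mean ML CoP deviation and the mean ML trunk
angular-velocity deviation to quantify ankle and trunk compensation:

    Error = b_ankle dCoP_bar + b_trunk dOmega_bar_trunk

Conventions
-----------
Both left and right placements enter the fits.  Mediolateral quantities of
left-foot placements are negated before pooling (mirror symmetry), and
deviations are taken from the per-side mean so that left/right asymmetries
in the gait pattern do not masquerade as control gains.  Foot placement is
measured relative to the CoM position at the heel-strike instant, which
keeps the response independent of the previous placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .strides import Stride

#: column order of the 9-element CoM state vector
STATE_NAMES = (
    "pos_ap",
    "pos_ml",
    "pos_vt",
    "vel_ap",
    "vel_ml",
    "vel_vt",
    "acc_ap",
    "acc_ml",
    "acc_vt",
)

#: indices of mediolateral components within the state vector
ML_STATE_IDX = (1, 4, 7)


class RegressionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# measurement primitives (shared with the synthetic generator)
# ---------------------------------------------------------------------------


def _interp_rows(t: np.ndarray, arr: np.ndarray, t_query: float) -> np.ndarray:
    """Linear interpolation of each column of ``arr`` at one instant.

    Uses a binary search so repeated point queries on long recordings stay
    cheap; exact at sample instants.
    """
    arr = np.atleast_2d(np.asarray(arr, float).T).T
    i = int(np.searchsorted(t, t_query))
    if i <= 0:
        return arr[0].copy()
    if i >= len(t):
        return arr[-1].copy()
    if t[i] == t_query:
        return arr[i].copy()
    w = (t_query - t[i - 1]) / (t[i] - t[i - 1])
    return (1.0 - w) * arr[i - 1] + w * arr[i]


def midstance_state_raw(
    t: np.ndarray,
    com: np.ndarray,
    vel: np.ndarray,
    acc: np.ndarray,
    anchor_idx: int,
    t_midstance: float,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """9-element CoM state at a midstance instant.

    Position is taken relative to the CoM position at the stride-opening
    heel strike (``anchor_idx``), which removes forward progression without
    tying the predictor to a foot marker.  Velocity and acceleration are the
    precomputed full-series central differences, interpolated at the
    midstance instant.  ``rotation`` (3x3, rows = stride-frame axes) maps
    the vectors into the stride frame when given.
    """
    pos = _interp_rows(t, com, t_midstance) - com[anchor_idx]
    v = _interp_rows(t, vel, t_midstance)
    a = _interp_rows(t, acc, t_midstance)
    if rotation is not None:
        pos = rotation @ pos
        v = rotation @ v
        a = rotation @ a
    return np.concatenate([pos, v, a])


def foot_placement_raw(
    t: np.ndarray,
    heel: np.ndarray,
    com: np.ndarray,
    t_heel_strike: float,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """(AP, ML) foot placement relative to the CoM at the heel strike."""
    d = _interp_rows(t, heel, t_heel_strike) - _interp_rows(t, com, t_heel_strike)
    if rotation is not None:
        d = rotation @ d
    return d[:2]


def pool_ml_sign(values: np.ndarray, sides: np.ndarray, ml_cols) -> np.ndarray:
    """Negate ML columns of left-foot placements (mirror pooling)."""
    out = np.array(values, float, copy=True)
    left = np.asarray(sides) == "L"
    if out.ndim == 1:
        out[left] *= -1.0
    else:
        for c in np.atleast_1d(ml_cols):
            out[left, c] *= -1.0
    return out


def center_by_side(values: np.ndarray, sides: np.ndarray) -> np.ndarray:
    """Deviations from the per-side (left/right placement) mean."""
    out = np.array(values, float, copy=True)
    sides = np.asarray(sides)
    for side in np.unique(sides):
        m = sides == side
        out[m] = out[m] - np.mean(out[m], axis=0)
    return out


def extract_midstance_state(stride: Stride, placement: str = "right") -> np.ndarray:
    """CoM state at midstance from a percent-gait-normalized stride.

    ``placement`` selects which upcoming foot placement the state precedes:
    ``"left"`` uses the right-foot single-support midpoint, ``"right"`` the
    left-foot single-support midpoint.  Convenience surface over the raw
    pipeline path; positions are stride-frame values (already anchored at
    the stride origin by the frame transform).
    """
    n = stride.n_points
    if placement == "left":
        a = stride.phases["left_toe_off"]
        b = stride.phases["left_heel_strike"]
    elif placement == "right":
        a = stride.phases["right_toe_off"]
        b = 100.0
    else:
        raise ValueError("placement must be 'left' or 'right'")
    if b <= a:
        raise RegressionError("single-support window is empty; stride excluded")
    phase = 0.5 * (a + b)
    x = phase / 100.0 * (n - 1)
    grid = np.arange(n)
    pos = np.array([np.interp(x, grid, stride.landmarks["com"][:, j]) for j in range(3)])
    vel = np.array([np.interp(x, grid, stride.com_vel[:, j]) for j in range(3)])
    acc = np.array([np.interp(x, grid, stride.com_acc[:, j]) for j in range(3)])
    return np.concatenate([pos, vel, acc])


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


@dataclass
class SteppingRegression:
    """Fitted stepping regression for one subject and direction."""

    direction: str  # "AP" or "ML"
    gains: np.ndarray  # (9,)
    r_squared: float
    n_steps: int
    residuals: np.ndarray
    fitted: np.ndarray
    actual: np.ndarray
    se: np.ndarray = field(default=None)  # type: ignore[assignment]
    pvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.gains) != len(STATE_NAMES):
            raise RegressionError("expected 9 gains")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise RegressionError(f"R^2 out of range: {self.r_squared}")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))


@dataclass
class CompensationRegression:
    """Fitted ankle/trunk compensation regression for one subject."""

    beta_ankle: float
    beta_trunk: float
    r_squared: float
    n_steps: int
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise RegressionError(f"R^2 out of range: {self.r_squared}")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pairwise correlation / zero variance
        bad = []
        sd = X.std(axis=0)
        bad += [names[i] for i in np.flatnonzero(sd < 1e-12)]
        if not bad:
            c = np.corrcoef(X, rowvar=False)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if abs(c[i, j]) > 1 - 1e-9:
                        bad += [names[i], names[j]]
        raise RegressionError(
            f"rank-deficient predictor matrix (rank {rank} < {X.shape[1]}); "
            f"collinear or constant columns: {sorted(set(bad)) or 'unknown'}"
        )


def fit_stepping(
    states: np.ndarray,
    placements: np.ndarray,
    sides: np.ndarray,
    direction: str = "ML",
    min_steps: int = 30,
    center: bool = True,
) -> SteppingRegression:
    """OLS fit of foot-placement deviations on the 9 CoM-state deviations.

    Parameters
    ----------
    states : (m, 9)
        Midstance CoM states in the pooled (mirror) convention, one row per
        placement.
    placements : (m, 2)
        (AP, ML) foot placements, pooled convention.
    sides : (m,)
        "L"/"R" placement side; used for per-side mean-centring.
    direction
        "AP" or "ML": which placement coordinate to fit.
    """
    direction = direction.upper()
    if direction not in ("AP", "ML"):
        raise ValueError("direction must be 'AP' or 'ML'")
    states = np.asarray(states, float)
    placements = np.asarray(placements, float)
    if len(states) < min_steps:
        raise RegressionError(
            f"need at least {min_steps} placements, got {len(states)}"
        )
    y = placements[:, 0 if direction == "AP" else 1]
    if center:
        X = center_by_side(states, sides)
        y = center_by_side(y, sides)
    else:
        X = states
    _check_full_rank(X, STATE_NAMES)
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum(y**2))  # y is centred: total sum of squares
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SteppingRegression(
        direction=direction,
        gains=np.asarray(res.params),
        r_squared=r2,
        n_steps=len(y),
        residuals=np.asarray(res.resid),
        fitted=fitted,
        actual=y,
        se=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
    )


def compute_fp_error(
    reg: SteppingRegression, n_expected: int | None = None
) -> np.ndarray:
    """Per-placement stepping error: predicted minus actual placement.

    The error is defined over the fit set only; passing a different
    expected length raises.  Over the fit set the errors average to zero
    (OLS residual property with mean-centred variables).
    """
    if n_expected is not None and n_expected != reg.n_steps:
        raise RegressionError(
            f"error requested for {n_expected} placements but the regression "
            f"was fitted on {reg.n_steps}"
        )
    return reg.fitted - reg.actual


def fit_compensation(
    errors: np.ndarray,
    cop_dev: np.ndarray,
    trunk_dev: np.ndarray,
    min_steps: int = 30,
) -> CompensationRegression:
    """OLS fit of stepping errors on CoP and trunk angular-velocity deviations.

    Two-predictor regression without intercept (inputs are deviations);
    reports per-coefficient t-tests against zero.  Raises when either
    predictor is constant.
    """
    e = np.asarray(errors, float)
    c = np.asarray(cop_dev, float)
    w = np.asarray(trunk_dev, float)
    if not (len(e) == len(c) == len(w)):
        raise ValueError("errors and predictors must be aligned")
    if len(e) < min_steps:
        raise RegressionError(f"need at least {min_steps} placements, got {len(e)}")
    X = np.column_stack([c - c.mean(), w - w.mean()])
    y = e - e.mean()
    sd = X.std(axis=0)
    if np.any(sd < 1e-12):
        name = ("cop", "trunk")[int(np.argmin(sd))]
        raise RegressionError(f"constant predictor: {name}")
    res = sm.OLS(y, X).fit()
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum(res.resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return CompensationRegression(
        beta_ankle=float(res.params[0]),
        beta_trunk=float(res.params[1]),
        r_squared=r2,
        n_steps=len(y),
        se=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        residuals=np.asarray(res.resid),
    )
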