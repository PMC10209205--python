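"""Local divergence exponent (Rosenstein-style) on stride-normalized series.

The input is a scalar time series (one CoM-velocity component) in which
every stride has been resampled to a fixed number of samples and the strides
concatenated, so one "time unit" is one stride.  The series is delay-embedded
(dimension 5, delay 10 by default), each embedded point is paired with its
nearest neighbour outside a temporal exclusion (Theiler) window of one
stride, and the mean log Euclidean separation of the pairs is followed
forward in time.  The local divergence exponent (LDE) is the slope of a
least-squares line fitted to the early part of that divergence curve,
expressed per stride-normalized time; larger values mean locally less stable
gait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

_LOG_FLOOR = 1e-12  # distances below this are clipped before taking logs


class LdeError(ValueError):
    pass


@dataclass
class LdeResult:
    lde: float
    divergence_curve: np.ndarray  # mean log divergence vs forward offset
    fit_interval: tuple[float, float]  # in strides
    samples_per_stride: int
    n_points: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.lde):
            raise LdeError("divergence exponent is not finite")


def delay_embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay-embedding matrix of shape (n - (dim-1)*delay, dim)."""
    series = np.asarray(series, float)
    n = len(series) - (dim - 1) * delay
    if n < 1:
        raise LdeError(
            f"series of length {len(series)} too short for dim={dim}, delay={delay}"
        )
    return np.column_stack([series[i * delay : i * delay + n] for i in range(dim)])


def nearest_neighbors(
    embedded: np.ndarray, theiler: int, n_candidates: int | None = None
) -> np.ndarray:
    """Nearest neighbour of each point excluding temporal neighbours.

    For point i the neighbour j minimizes the Euclidean distance subject to
    ``|i - j| >= theiler``.  Returns -1 where no admissible neighbour exists.
    """
    n = len(embedded)
    tree = cKDTree(embedded)
    k = min(n, (n_candidates or 2 * theiler + 2))
    out = np.full(n, -1, dtype=int)
    pending = np.arange(n)
    while len(pending):
        _, idx = tree.query(embedded[pending], k=k)
        if k == 1:
            idx = idx[:, None]
        ok = np.abs(idx - pending[:, None]) >= theiler
        first = np.argmax(ok, axis=1)
        found = ok[np.arange(len(pending)), first]
        out[pending[found]] = idx[np.arange(len(pending)), first][found]
        pending = pending[~found]
        if k == n:
            break
        k = min(n, k * 4)
    return out


def divergence_curve(
    series: np.ndarray,
    dim: int = 5,
    delay: int = 10,
    theiler: int | None = None,
    horizon: int | None = None,
    samples_per_stride: int = 100,
) -> np.ndarray:
    """Mean log divergence of nearest-neighbour pairs vs forward offset.

    ``curve[k]`` is the average over admissible pairs (i, j) of
    ``log ||X_{i+k} - X_{j+k}||`` for k = 0..horizon.  The Theiler window
    and horizon both default to one stride of samples.
    """
    theiler = samples_per_stride if theiler is None else theiler
    horizon = samples_per_stride if horizon is None else horizon
    emb = delay_embed(series, dim, delay)
    n = len(emb)
    n_follow = n - horizon
    if n_follow < 2:
        raise LdeError("series too short to follow divergence over the horizon")
    nn = nearest_neighbors(emb[:n_follow], theiler)
    valid = nn >= 0
    i_idx = np.flatnonzero(valid)
    j_idx = nn[valid]
    if len(i_idx) == 0:
        raise LdeError("no admissible nearest-neighbour pairs")
    curve = np.empty(horizon + 1)
    for k in range(horizon + 1):
        d = np.linalg.norm(emb[i_idx + k] - emb[j_idx + k], axis=1)
        curve[k] = float(np.mean(np.log(np.maximum(d, _LOG_FLOOR))))
    return curve


def compute_lde(
    series: np.ndarray,
    dim: int = 5,
    delay: int = 10,
    fit_interval: tuple[float, float] = (0.0, 0.5),
    samples_per_stride: int = 100,
    theiler: int | None = None,
) -> LdeResult:
    """Local divergence exponent of one stride-normalized scalar series.

    The exponent is the least-squares slope of the divergence curve over
    ``fit_interval`` (in strides; default the first half stride), expressed
    per stride-normalized time unit.
    """
    curve = divergence_curve(
        series,
        dim=dim,
        delay=delay,
        theiler=theiler,
        horizon=samples_per_stride,
        samples_per_stride=samples_per_stride,
    )
    a = int(round(fit_interval[0] * samples_per_stride))
    b = int(round(fit_interval[1] * samples_per_stride))
    if b <= a + 1:
        raise LdeError("fit interval too short")
    k = np.arange(a, b + 1)
    slope = np.polyfit(k / samples_per_stride, curve[a : b + 1], 1)[0]
    return LdeResult(
        lde=float(slope),
        divergence_curve=curve,
        fit_interval=fit_interval,
        samples_per_stride=samples_per_stride,
        n_points=len(series),
    )


def normalized_velocity_series(
    stride_velocities: list[np.ndarray], samples_per_stride: int = 100
) -> np.ndarray:
    """Concatenate per-stride CoM-velocity arrays onto a common stride grid.

    Each array (one stride, any length >= 2) is linearly resampled to
    ``samples_per_stride`` points and the strides are concatenated, giving
    the stride-normalized input the divergence analysis expects.
    """
    out = []
    grid = np.linspace(0.0, 1.0, samples_per_stride, endpoint=False)
    for arr in stride_velocities:
        arr = np.asarray(arr, float)
        x = np.linspace(0.0, 1.0, len(arr))
        out.append(np.interp(grid, x, arr))
    return np.concatenate(out)
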