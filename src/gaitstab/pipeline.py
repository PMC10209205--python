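"""End-to-end analysis: recordings -> per-step/per-stride feature tables.

`analyze_recording` runs the full chain for one trial: event detection,
clock synchronization, stride segmentation, per-stride frames, margins of
stability, spatiotemporal measures, and the per-step predictors of the
stepping and compensation regressions.  Two placements enter the step table
per stride (the left heel strike inside the stride and the right heel
strike closing it); mediolateral step quantities are stored in the pooled
mirror convention (left-placement ML negated).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from .lde import LdeResult, compute_lde, normalized_velocity_series
from .recordings import InsoleRecording, KinematicRecording
from .regression import (
    STATE_NAMES,
    CompensationRegression,
    SteppingRegression,
    center_by_side,
    compute_fp_error,
    fit_compensation,
    fit_stepping,
    foot_placement_raw,
    midstance_state_raw,
)
from .stability import ap_margins_at, compute_xcom, ml_margin_series
from .strides import (
    StrideSlice,
    build_stride_frame,
    kinematic_derivatives,
    leg_length_raw,
    segment_strides,
)

log = logging.getLogger("gaitstab")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline (paper defaults)."""

    force_threshold: float = 30.0  # N
    refractory: float = 0.2  # s
    contact_tol: float = 0.002  # m
    gravity: float = 9.806  # m/s^2
    n_percent: int = 101
    midstance_frac: float = 0.5  # position within the single-support window
    fp_reference: str = "com"  # or "stride_origin"
    lde_dim: int = 5
    lde_delay: int = 10
    lde_fit: tuple[float, float] = (0.0, 0.5)
    lde_samples_per_stride: int = 100
    lde_n_strides: int = 650
    min_steps: int = 30
    alpha: float = 0.05
    equal_var: bool = True  # pooled-variance t-tests (Welch when False)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lde_fit"] = list(d["lde_fit"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "lde_fit" in d:
            d["lde_fit"] = tuple(d["lde_fit"])
        return cls(**d)

    def digest(self) -> str:
        d = asdict(self)
        d["lde_fit"] = list(d["lde_fit"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class GaitAnalysis:
    """Feature tables of one analyzed trial."""

    events: ev.GaitEvents
    slices: list[StrideSlice]
    steps: pd.DataFrame  # one row per placement (2 per stride)
    strides: pd.DataFrame  # one row per stride
    clock_offset: float
    config: AnalysisConfig

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def _stance_runs(force: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = force >= threshold
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(force) - 1)
    return list(zip(starts, ends))


def _cop_mean_at(
    insole_df: pd.DataFrame,
    runs: list[tuple[int, int]],
    t_event_kin: float,
    clock_offset: float,
) -> float:
    """Mean ML CoP over the loaded interval containing a kinematic instant."""
    t_ins = t_event_kin - clock_offset
    times = insole_df["time"].to_numpy()
    cop = insole_df["cop_ml"].to_numpy()
    idx = int(np.searchsorted(times, t_ins))
    for a, b in runs:
        if a <= idx <= b:
            seg = cop[a : b + 1]
            seg = seg[np.isfinite(seg)]
            return float(np.mean(seg)) if len(seg) else float("nan")
    return float("nan")


def analyze_recording(
    kin: KinematicRecording,
    insole: InsoleRecording | None = None,
    events: ev.GaitEvents | None = None,
    conditions=None,
    clock_offset: float | None = None,
    config: AnalysisConfig | None = None,
) -> GaitAnalysis:
    """Run the full single-trial analysis.

    ``conditions`` optionally tags each segmented stride (sequence as long
    as the stride list, or a single tag for the whole trial).  When
    ``events`` is given, detection is skipped; when ``clock_offset`` is
    given, jump synchronization is skipped.
    """
    cfg = config or AnalysisConfig()
    if events is None:
        events = ev.detect_events_kinematic(kin, contact_tol=cfg.contact_tol)
    events.validate()
    if insole is not None and clock_offset is None:
        clock_offset = ev.synchronize_jumps(
            kin, insole, g=cfg.gravity, force_threshold=cfg.force_threshold
        )
    clock_offset = clock_offset or 0.0

    slices = segment_strides(events)
    if not slices:
        raise ev.EventDetectionError("no complete stride found")

    if conditions is None:
        conditions = ["S"] * len(slices)
    elif isinstance(conditions, str):
        conditions = [conditions] * len(slices)
    elif len(conditions) != len(slices):
        raise ValueError(
            f"got {len(conditions)} condition tags for {len(slices)} strides"
        )

    t = kin.time
    com = kin.landmark("com")
    vel, acc = kinematic_derivatives(com, kin.rate)
    heel = {"L": kin.landmark("l_heel"), "R": kin.landmark("r_heel")}
    mt5 = {"L": kin.landmark("l_mt5"), "R": kin.landmark("r_mt5")}
    trunk = kin.trunk_angvel_ml

    runs = {}
    if insole is not None:
        for side_key, side_name in (("L", "left"), ("R", "right")):
            runs[side_key] = _stance_runs(
                insole.foot(side_name)["vgrf"].to_numpy(), cfg.force_threshold
            )

    step_rows = []
    stride_rows = []
    for sl, cond in zip(slices, conditions):
        frame = build_stride_frame(kin, sl)
        R = frame.rotation
        L = leg_length_raw(kin, sl)

        # single-support windows: (start_idx, end_idx, placement side)
        windows = {
            "L": (sl.left_toe_off, sl.left_heel_strike),  # right-foot stance
            "R": (sl.right_toe_off, sl.end),  # left-foot stance
        }
        # per-stride spatiotemporal measures (raw path)
        vel_rot = vel[sl.start : sl.end + 1] @ R.T
        r0 = heel["R"][sl.start] @ R.T
        r1 = heel["R"][sl.end] @ R.T
        l_at_lhs = heel["L"][sl.left_heel_strike] @ R.T
        r_at_rhs = heel["R"][sl.start] @ R.T
        stride_rows.append(
            {
                "stride": sl.index,
                "start_time": float(t[sl.start]),
                "condition": cond,
                "stride_time": float(t[sl.end] - t[sl.start]),
                "stance_time": float(t[sl.right_toe_off] - t[sl.start]),
                "speed": float(np.mean(vel_rot[:, 0])),
                "stride_length": float(r1[0] - r0[0]),
                "step_width": float(abs(l_at_lhs[1] - r_at_rhs[1])),
                "leg_length": L,
            }
        )

        for side in ("L", "R"):
            a, b = windows[side]
            if b <= a:
                log.warning(
                    "stride %d: empty single-support window for %s placement; "
                    "step excluded",
                    sl.index,
                    side,
                )
                continue
            t_ms = t[a] + cfg.midstance_frac * (t[b] - t[a])
            state = midstance_state_raw(t, com, vel, acc, sl.start, t_ms, R)
            t_hs = float(t[b]) if side == "R" else float(t[sl.left_heel_strike])
            if cfg.fp_reference == "com":
                fp = foot_placement_raw(t, heel[side], com, t_hs, R)
            else:
                h = heel[side][b if side == "R" else sl.left_heel_strike]
                fp = (R @ (h - frame.origin))[:2]
            if side == "L":  # pooled mirror convention
                state = state.copy()
                state[[1, 4, 7]] *= -1.0
                fp = np.array([fp[0], -fp[1]])

            # margins of stability at this heel strike
            idx_hs = b if side == "R" else sl.left_heel_strike
            xcom = compute_xcom(
                com[idx_hs] @ R.T, vel[idx_hs] @ R.T, L, cfg.gravity
            )
            r_heel_x = (heel["R"][idx_hs] @ R.T)[0]
            l_heel_x = (heel["L"][idx_hs] @ R.T)[0]
            if r_heel_x >= l_heel_x:
                ant_x, post_x = r_heel_x, (mt5["L"][idx_hs] @ R.T)[0]
            else:
                ant_x, post_x = l_heel_x, (mt5["R"][idx_hs] @ R.T)[0]
            fw, bw = ap_margins_at(ant_x, post_x, xcom[0])

            # ML MoS over the single-support window preceding the placement
            stance_side = "R" if side == "L" else "L"
            seg = slice(a, b + 1)
            xcom_ml = compute_xcom(
                (com[seg] @ R.T)[:, 1], (vel[seg] @ R.T)[:, 1], L, cfg.gravity
            )
            mt5_ml = (mt5[stance_side][seg] @ R.T)[:, 1]
            ml_mos = float(
                np.min(
                    ml_margin_series(
                        xcom_ml, mt5_ml, "right" if stance_side == "R" else "left"
                    )
                )
            )

            trunk_mean = float(np.mean(trunk[a : b + 1]))
            cop_mean = float("nan")
            if insole is not None:
                insole_side = "left" if stance_side == "L" else "right"
                cop_mean = _cop_mean_at(
                    insole.foot(insole_side),
                    runs[stance_side],
                    t_hs - 1e-6,
                    clock_offset,
                )
            sgn = -1.0 if side == "L" else 1.0
            row = {
                "stride": sl.index,
                "side": side,
                "t_hs": t_hs,
                "condition": cond,
                "fp_ap": float(fp[0]),
                "fp_ml": float(fp[1]),
                "fw_mos": float(fw),
                "bw_mos": float(bw),
                "ml_mos": ml_mos,
                "cop_mean": sgn * cop_mean,
                "trunk_mean": sgn * trunk_mean,
                "leg_length": L,
            }
            for name, val in zip(STATE_NAMES, state):
                row[f"state_{name}"] = float(val)
            step_rows.append(row)

    return GaitAnalysis(
        events=events,
        slices=slices,
        steps=pd.DataFrame(step_rows),
        strides=pd.DataFrame(stride_rows),
        clock_offset=float(clock_offset),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# regressions on an analyzed trial
# ---------------------------------------------------------------------------


def _step_arrays(analysis: GaitAnalysis):
    steps = analysis.steps
    states = steps[[f"state_{n}" for n in STATE_NAMES]].to_numpy()
    fp = steps[["fp_ap", "fp_ml"]].to_numpy()
    sides = steps["side"].to_numpy()
    return states, fp, sides


def stepping_regression(
    analysis: GaitAnalysis, direction: str = "ML", min_steps: int | None = None
) -> SteppingRegression:
    """Fit the per-subject stepping regression in one direction."""
    states, fp, sides = _step_arrays(analysis)
    return fit_stepping(
        states,
        fp,
        sides,
        direction=direction,
        min_steps=min_steps if min_steps is not None else analysis.config.min_steps,
    )


def compensation_regression(
    analysis: GaitAnalysis,
    ml_reg: SteppingRegression | None = None,
    min_steps: int | None = None,
) -> CompensationRegression:
    """Fit the ankle/trunk compensation regression for one subject.

    Steps lacking an insole CoP mean are dropped (with the matching rows of
    the error vector) before fitting.
    """
    min_steps = min_steps if min_steps is not None else analysis.config.min_steps
    if ml_reg is None:
        ml_reg = stepping_regression(analysis, "ML", min_steps=min_steps)
    errors = compute_fp_error(ml_reg)
    steps = analysis.steps
    sides = steps["side"].to_numpy()
    cop = center_by_side(steps["cop_mean"].to_numpy(), sides)
    trunk = center_by_side(steps["trunk_mean"].to_numpy(), sides)
    ok = np.isfinite(cop) & np.isfinite(trunk)
    if not np.all(ok):
        log.warning("dropping %d steps without insole coverage", int((~ok).sum()))
    return fit_compensation(errors[ok], cop[ok], trunk[ok], min_steps=min_steps)


def lde_from_analysis(
    kin: KinematicRecording,
    analysis: GaitAnalysis,
    direction: str = "AP",
    n_strides: int | None = None,
) -> LdeResult:
    """Local divergence exponent of one CoM-velocity component.

    Uses the first ``n_strides`` segmented strides (default: the configured
    stride count, clipped to what is available so every comparison uses the
    same number of strides).
    """
    cfg = analysis.config
    axis = {"AP": 0, "ML": 1, "VT": 2}[direction.upper()]
    n_use = min(
        n_strides if n_strides is not None else cfg.lde_n_strides,
        len(analysis.slices),
    )
    com = kin.landmark("com")
    vel, _ = kinematic_derivatives(com, kin.rate)
    per_stride = []
    for sl in analysis.slices[:n_use]:
        frame = build_stride_frame(kin, sl)
        per_stride.append((vel[sl.start : sl.end + 1] @ frame.rotation.T)[:, axis])
    series = normalized_velocity_series(per_stride, cfg.lde_samples_per_stride)
    return compute_lde(
        series,
        dim=cfg.lde_dim,
        delay=cfg.lde_delay,
        fit_interval=cfg.lde_fit,
        samples_per_stride=cfg.lde_samples_per_stride,
    )


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_analysis(analysis: GaitAnalysis, out_dir: str | Path) -> dict[str, Path]:
    """Write the tidy per-step/per-stride tables plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "steps": out / "steps.csv",
        "strides": out / "strides.csv",
        "manifest": out / "manifest.json",
    }
    analysis.steps.to_csv(paths["steps"], index=False, float_format=_FLOAT_FMT)
    analysis.strides.to_csv(paths["strides"], index=False, float_format=_FLOAT_FMT)
    manifest = {
        "config_digest": analysis.config.digest(),
        "config": asdict(analysis.config),
        "n_strides": analysis.n_strides,
        "clock_offset": analysis.clock_offset,
    }
    manifest["config"]["lde_fit"] = list(manifest["config"]["lde_fit"])
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def regression_table(
    regs: dict[str, SteppingRegression],
    comp: CompensationRegression | None = None,
) -> pd.DataFrame:
    """Tidy coefficient table for the fitted regressions."""
    rows = []
    for direction, reg in regs.items():
        for name, gain, se, p in zip(STATE_NAMES, reg.gains, reg.se, reg.pvalues):
            rows.append(
                {
                    "regression": f"stepping_{direction}",
                    "coefficient": name,
                    "value": float(gain),
                    "se": float(se),
                    "p": float(p),
                }
            )
        rows.append(
            {
                "regression": f"stepping_{direction}",
                "coefficient": "r_squared",
                "value": reg.r_squared,
                "se": np.nan,
                "p": np.nan,
            }
        )
    if comp is not None:
        for name, val, se, p in zip(
            ("beta_ankle", "beta_trunk"), (comp.beta_ankle, comp.beta_trunk),
            comp.se, comp.pvalues,
        ):
            rows.append(
                {
                    "regression": "compensation_ML",
                    "coefficient": name,
                    "value": float(val),
                    "se": float(se),
                    "p": float(p),
                }
            )
        rows.append(
            {
                "regression": "compensation_ML",
                "coefficient": "r_squared",
                "value": comp.r_squared,
                "se": np.nan,
                "p": np.nan,
            }
        )
    return pd.DataFrame(rows)
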