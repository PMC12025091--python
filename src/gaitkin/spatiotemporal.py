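"""Spatiotemporal gait parameters from events and scaled displacements.

Pixel displacements become meters through a single static scale factor per
camera, calibrated from the pixel span of tape marks a known distance apart
on the walkway.  Perspective-induced scale variation along the walkway is a
documented, uncorrected error source of this single-scale approach.

Definitions
-----------
* step length: |x_left_ankle - x_right_ankle| * m_per_px at a heel strike,
  labeled by the striking side
* stride length (default): sum of the two consecutive step lengths inside
  one side's cycle; ``stride_mode="displacement"`` instead uses the
  ipsilateral ankle x displacement between successive ipsilateral strikes
* cycle duration: mean interval between successive ipsilateral heel strikes
* step time: interval between successive contralateral heel strikes;
  cadence (steps/min) = 60 / mean step time
* gait speed: net MidHip x displacement over the analysed complete cycles,
  scaled, divided by elapsed time
* stance %: (toe off - heel strike) / cycle duration * 100 per side
* double support %: the two double-contact intervals per cycle (ipsilateral
  HS to contralateral TO, and contralateral HS to ipsilateral TO)
* step width: mean scaled lateral ankle separation during double-support
  frames, from the frontal camera
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gait_events import GaitEvents
from .keypoint_io import KeypointTrajectorySet
from .landmarks import Landmark


@dataclass(frozen=True)
class ScaleFactor:
    """Meters-per-pixel calibration for one camera."""

    meters_per_pixel: float
    tape_pixels: float
    tape_meters: float
    camera: str = "sagittal"


def scale_from_tape(
    tape_pixels: float, tape_meters: float, camera: str = "sagittal"
) -> ScaleFactor:
    """Calibration from tape marks: known distance / measured pixel span."""
    if tape_pixels <= 0 or tape_meters <= 0:
        raise ValueError("tape span must be positive in both pixels and meters")
    return ScaleFactor(
        meters_per_pixel=tape_meters / tape_pixels,
        tape_pixels=tape_pixels,
        tape_meters=tape_meters,
        camera=camera,
    )


@dataclass
class SpatioTemporalParams:
    """One trial's spatiotemporal summary.

    Cadence is reported both as steps/min (60 / step time) and strides/min
    (60 / cycle duration); conventions differ across clinical reports, so
    both scales are emitted explicitly.
    """

    cadence_steps_min: float
    cadence_strides_min: float
    gait_speed_ms: float
    stride_length_right_m: float
    stride_length_left_m: float
    cycle_duration_s: float
    stance_pct_right: float
    stance_pct_left: float
    swing_pct_right: float
    swing_pct_left: float
    double_support_pct: float
    step_width_m: Optional[float] = None
    n_cycles_right: int = 0
    n_cycles_left: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _x_at_time(traj: KeypointTrajectorySet, lm: Landmark, t: float) -> float:
    """Landmark x at time t by linear interpolation over observed frames."""
    x = traj.x(lm)
    times = traj.times
    ok = ~np.isnan(x)
    if ok.sum() < 2 or t < times[ok][0] or t > times[ok][-1]:
        return np.nan
    return float(np.interp(t, times[ok], x[ok]))


def step_lengths(
    traj: KeypointTrajectorySet,
    events_right: GaitEvents,
    events_left: GaitEvents,
    scale: ScaleFactor,
) -> pd.DataFrame:
    """Per-step lengths (m): lateral ankle gap at each heel strike.

    Returns a DataFrame (time_s, side, step_length_m, flag); steps where an
    ankle is unobserved are skipped with a flag, coincident ankles are
    flagged implausible.
    """
    rows = []
    strikes = [(t, "right") for t in events_right.heel_strikes]
    strikes += [(t, "left") for t in events_left.heel_strikes]
    for t, side in sorted(strikes):
        xr = _x_at_time(traj, Landmark.RAnkle, t)
        xl = _x_at_time(traj, Landmark.LAnkle, t)
        if np.isnan(xr) or np.isnan(xl):
            rows.append((t, side, np.nan, "ankle_missing"))
            continue
        length = abs(xl - xr) * scale.meters_per_pixel
        flag = "implausible_zero" if length == 0 else ""
        rows.append((t, side, length, flag))
    return pd.DataFrame(rows, columns=["time_s", "side", "step_length_m", "flag"])


def _stance_pct(ev: GaitEvents) -> tuple[float, int]:
    """Mean stance percentage and cycle count for one side."""
    pcts = []
    for a, b in zip(ev.heel_strikes[:-1], ev.heel_strikes[1:]):
        tos = ev.toe_offs[(ev.toe_offs > a) & (ev.toe_offs < b)]
        if len(tos) == 1:
            pcts.append((tos[0] - a) / (b - a) * 100.0)
    return (float(np.mean(pcts)) if pcts else np.nan), len(pcts)


def _double_support_pct(ev_ipsi: GaitEvents, ev_contra: GaitEvents) -> float:
    """Mean double-support percentage over ipsilateral cycles."""
    pcts = []
    for a, b in zip(ev_ipsi.heel_strikes[:-1], ev_ipsi.heel_strikes[1:]):
        cyc = b - a
        # initial DS: ipsilateral HS -> contralateral TO
        cto = ev_contra.toe_offs[(ev_contra.toe_offs > a) & (ev_contra.toe_offs < b)]
        # terminal DS: contralateral HS -> ipsilateral TO
        chs = ev_contra.heel_strikes[
            (ev_contra.heel_strikes > a) & (ev_contra.heel_strikes < b)
        ]
        ito = ev_ipsi.toe_offs[(ev_ipsi.toe_offs > a) & (ev_ipsi.toe_offs < b)]
        if len(cto) >= 1 and len(chs) >= 1 and len(ito) == 1:
            ds1 = cto[0] - a
            ds2 = ito[0] - chs[0]
            if ds1 >= 0 and ds2 >= 0:
                pcts.append((ds1 + ds2) / cyc * 100.0)
    return float(np.mean(pcts)) if pcts else np.nan


def step_width(
    frontal_traj: KeypointTrajectorySet,
    events_right: GaitEvents,
    events_left: GaitEvents,
    frontal_scale: ScaleFactor,
) -> float:
    """Mean scaled lateral ankle separation during double-support frames.

    Double-support intervals are taken from the (synchronized) sagittal
    events: each heel strike opens an interval closed by the next
    contralateral toe off.
    """
    times = frontal_traj.times
    in_ds = np.zeros(len(times), dtype=bool)
    for ev_hs, ev_to in ((events_right, events_left), (events_left, events_right)):
        for hs in ev_hs.heel_strikes:
            later = ev_to.toe_offs[ev_to.toe_offs > hs]
            if len(later):
                in_ds |= (times >= hs) & (times <= later[0])
    sep = np.abs(
        frontal_traj.x(Landmark.LAnkle) - frontal_traj.x(Landmark.RAnkle)
    )
    vals = sep[in_ds & ~np.isnan(sep)]
    if len(vals) == 0:
        return np.nan
    return float(np.mean(vals)) * frontal_scale.meters_per_pixel


def spatiotemporal_summary(
    traj: KeypointTrajectorySet,
    events_right: GaitEvents,
    events_left: GaitEvents,
    scale: ScaleFactor,
    frontal_traj: KeypointTrajectorySet | None = None,
    frontal_scale: ScaleFactor | None = None,
    stride_mode: str = "step_sum",
) -> SpatioTemporalParams:
    """Full spatiotemporal summary for one trial.

    Requires >= 2 ipsilateral heel strikes per side.  Step width is None
    unless a frontal trial and its scale are supplied.
    """
    if len(events_right.heel_strikes) < 2 or len(events_left.heel_strikes) < 2:
        raise ValueError("need >= 2 heel strikes per side")

    cyc_r = np.diff(events_right.heel_strikes)
    cyc_l = np.diff(events_left.heel_strikes)
    cycle_duration = float(np.mean(np.concatenate([cyc_r, cyc_l])))

    # step time: successive contralateral heel strikes
    all_hs = sorted(
        [(t, "right") for t in events_right.heel_strikes]
        + [(t, "left") for t in events_left.heel_strikes]
    )
    step_times = [
        b[0] - a[0] for a, b in zip(all_hs[:-1], all_hs[1:]) if a[1] != b[1]
    ]
    mean_step_time = float(np.mean(step_times))
    cadence_steps = 60.0 / mean_step_time
    cadence_strides = 60.0 / cycle_duration

    steps = step_lengths(traj, events_right, events_left, scale)
    stride_r = _stride_length(events_right, steps, traj, scale, stride_mode, "right")
    stride_l = _stride_length(events_left, steps, traj, scale, stride_mode, "left")

    # gait speed over the span of complete cycles
    t0 = min(events_right.heel_strikes[0], events_left.heel_strikes[0])
    t1 = max(events_right.heel_strikes[-1], events_left.heel_strikes[-1])
    x0 = _x_at_time(traj, Landmark.MidHip, t0)
    x1 = _x_at_time(traj, Landmark.MidHip, t1)
    gait_speed = abs(x1 - x0) * scale.meters_per_pixel / (t1 - t0)

    stance_r, ncyc_r = _stance_pct(events_right)
    stance_l, ncyc_l = _stance_pct(events_left)
    ds = np.nanmean(
        [
            _double_support_pct(events_right, events_left),
            _double_support_pct(events_left, events_right),
        ]
    )

    width = None
    if frontal_traj is not None and frontal_scale is not None:
        width = step_width(frontal_traj, events_right, events_left, frontal_scale)

    return SpatioTemporalParams(
        cadence_steps_min=cadence_steps,
        cadence_strides_min=cadence_strides,
        gait_speed_ms=gait_speed,
        stride_length_right_m=stride_r,
        stride_length_left_m=stride_l,
        cycle_duration_s=cycle_duration,
        stance_pct_right=stance_r,
        stance_pct_left=stance_l,
        swing_pct_right=100.0 - stance_r,
        swing_pct_left=100.0 - stance_l,
        double_support_pct=float(ds),
        step_width_m=width,
        n_cycles_right=ncyc_r,
        n_cycles_left=ncyc_l,
    )


def _stride_length(
    ev: GaitEvents,
    steps: pd.DataFrame,
    traj: KeypointTrajectorySet,
    scale: ScaleFactor,
    mode: str,
    side: str,
) -> float:
    """Mean stride length (m) for one side under the chosen mode."""
    if mode == "displacement":
        lm = Landmark.RAnkle if side == "right" else Landmark.LAnkle
        vals = []
        for a, b in zip(ev.heel_strikes[:-1], ev.heel_strikes[1:]):
            xa, xb = _x_at_time(traj, lm, a), _x_at_time(traj, lm, b)
            if not (np.isnan(xa) or np.isnan(xb)):
                vals.append(abs(xb - xa) * scale.meters_per_pixel)
        return float(np.mean(vals)) if vals else np.nan
    if mode != "step_sum":
        raise ValueError(f"unknown stride_mode {mode!r}")
    ok = steps[steps["step_length_m"].notna()]
    vals = []
    for a, b in zip(ev.heel_strikes[:-1], ev.heel_strikes[1:]):
        inside = ok[(ok["time_s"] > a) & (ok["time_s"] <= b)]
        if len(inside) == 2:  # contralateral then ipsilateral step
            vals.append(float(inside["step_length_m"].sum()))
    return float(np.mean(vals)) if vals else np.nan
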