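"""Heel-strike and toe-off detection from sagittal keypoint trajectories.

The coordinate-based (Zeni-style) method is used: relative to the body
center (MidHip), the foot is farthest forward at heel strike and farthest
backward at toe off.  With walking direction ``d`` (+1 toward +x):

* heel strikes  = local maxima of d * (x_heel  - x_MidHip)
* toe offs      = local minima of d * (x_bigtoe - x_MidHip)

Peak finding is guarded by a minimum inter-event spacing of 0.4 x the
median stride period (initialized from the dominant frequency of the
relative-position signal), and events within half a stride of either
series boundary are dropped — pose noise otherwise creates spurious
extrema.  A velocity-based variant (zero crossings of relative foot
velocity) is available via ``method="velocity"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .keypoint_io import KeypointTrajectorySet
from .landmarks import Landmark, side_landmark


class InsufficientCyclesError(ValueError):
    """Raised when fewer than two heel strikes are detected."""


class NotAWalkingTrialError(ValueError):
    """Raised when the subject shows no net forward displacement."""


@dataclass
class GaitEvents:
    """Ordered heel-strike and toe-off times (s) for one side."""

    side: str
    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    direction: int
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        for name, arr in (("heel_strikes", self.heel_strikes),
                          ("toe_offs", self.toe_offs)):
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        # exactly one toe off between consecutive ipsilateral heel strikes
        for a, b in zip(self.heel_strikes[:-1], self.heel_strikes[1:]):
            k = int(np.sum((self.toe_offs > a) & (self.toe_offs < b)))
            if k != 1:
                self.warnings.append(
                    f"{k} toe-offs between heel strikes at {a:.3f}-{b:.3f} s"
                )

    @property
    def n_cycles(self) -> int:
        return max(0, len(self.heel_strikes) - 1)


def walking_direction(traj: KeypointTrajectorySet) -> int:
    """Sign of the net MidHip x displacement (first to last observed frame)."""
    x = traj.x(Landmark.MidHip)
    obs = np.flatnonzero(~np.isnan(x))
    if len(obs) < 2:
        raise NotAWalkingTrialError("MidHip observed in fewer than 2 frames")
    net = x[obs[-1]] - x[obs[0]]
    if net == 0:
        raise NotAWalkingTrialError("no net MidHip displacement")
    return 1 if net > 0 else -1


def _relative_forward(traj, lm: Landmark, d: int) -> np.ndarray:
    rel = d * (traj.x(lm) - traj.x(Landmark.MidHip))
    # bridge any residual NaN so the peak finder sees a contiguous signal;
    # detected peaks at bridged samples are genuine only if neighbors agree
    if np.isnan(rel).any() and not np.isnan(rel).all():
        idx = np.arange(len(rel))
        ok = ~np.isnan(rel)
        rel = np.interp(idx, idx[ok], rel[ok])
    return rel


def _stride_period_frames(rel: np.ndarray, fps: float) -> float:
    """Stride period estimate (frames) from the dominant spectral peak."""
    x = rel - np.nanmean(rel)
    x = np.nan_to_num(x)
    freqs, power = signal.periodogram(x, fs=fps)
    band = (freqs >= 0.3) & (freqs <= 3.0)  # plausible stride rates
    if band.any() and power[band].max() > 0:
        f0 = freqs[band][np.argmax(power[band])]
    else:
        f0 = 1.0
    return fps / f0


def detect_events(
    traj: KeypointTrajectorySet,
    side: str,
    direction: int | None = None,
    method: str = "coordinate",
    min_spacing_factor: float = 0.4,
) -> GaitEvents:
    """Detect heel-strike and toe-off events for one side.

    Parameters
    ----------
    traj : preprocessed sagittal trajectory set.
    side : "right" or "left".
    direction : walking direction; inferred from MidHip if None.
    method : "coordinate" (relative-position extrema, default) or
        "velocity" (sign changes of relative foot velocity).
    """
    if traj.plane != "sagittal":
        raise ValueError("event detection requires the sagittal camera")
    d = walking_direction(traj) if direction is None else int(direction)

    heel = side_landmark("Heel", side)
    if np.isnan(traj.x(heel)).mean() > 0.5:  # heel unreliable -> ankle
        heel = side_landmark("Ankle", side)
    toe = side_landmark("BigToe", side)

    rel_heel = _relative_forward(traj, heel, d)
    rel_toe = _relative_forward(traj, toe, d)

    period = _stride_period_frames(rel_heel, traj.fps)
    spacing = max(1, int(round(min_spacing_factor * period)))

    if method == "coordinate":
        # prominence guard: pose jitter creates shallow mid-swing bumps
        prom_h = 0.2 * np.ptp(rel_heel)
        prom_t = 0.2 * np.ptp(rel_toe)
        hs_idx, _ = signal.find_peaks(rel_heel, distance=spacing,
                                      prominence=prom_h)
        to_idx, _ = signal.find_peaks(-rel_toe, distance=spacing,
                                      prominence=prom_t)
    elif method == "velocity":
        vh = np.gradient(rel_heel)
        vt = np.gradient(rel_toe)
        hs_idx = np.flatnonzero((vh[:-1] > 0) & (vh[1:] <= 0)) + 1
        to_idx = np.flatnonzero((vt[:-1] < 0) & (vt[1:] >= 0)) + 1
        hs_idx = _enforce_spacing(hs_idx, rel_heel, spacing)
        to_idx = _enforce_spacing(to_idx, -rel_toe, spacing)
    else:
        raise ValueError(f"unknown event method {method!r}")

    # drop events within half a stride of either boundary
    n = len(rel_heel)
    margin = period / 2.0
    hs_idx = hs_idx[(hs_idx >= margin) & (hs_idx <= n - 1 - margin)]
    to_idx = to_idx[(to_idx >= margin) & (to_idx <= n - 1 - margin)]

    if len(hs_idx) < 2:
        raise InsufficientCyclesError(
            f"only {len(hs_idx)} heel strikes detected on {side} side"
        )
    return GaitEvents(
        side=side,
        heel_strikes=hs_idx / traj.fps,
        toe_offs=to_idx / traj.fps,
        direction=d,
    )


def _enforce_spacing(idx: np.ndarray, score: np.ndarray, spacing: int) -> np.ndarray:
    """Greedy thinning: keep the higher-scoring event of any close pair."""
    if len(idx) == 0:
        return idx
    order = idx[np.argsort(-score[idx], kind="stable")]
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= spacing for j in kept):
            kept.append(int(i))
    return np.asarray(sorted(kept), dtype=int)


def events_table(events_list: list[GaitEvents], fps: float):
    """Long-format events table (side, event_type, frame, time_s)."""
    import pandas as pd

    rows = []
    for ev in events_list:
        for t in ev.heel_strikes:
            rows.append((ev.side, "heel_strike", int(round(t * fps)), t))
        for t in ev.toe_offs:
            rows.append((ev.side, "toe_off", int(round(t * fps)), t))
    df = pd.DataFrame(rows, columns=["side", "event_type", "frame", "time_s"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)
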