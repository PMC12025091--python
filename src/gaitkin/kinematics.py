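"""Segment and joint angles from 2D keypoint trajectories.

Six quantities are computed, mirroring standard 2D clinical gait
conventions.  In the sagittal (side) view: hip flexion/extension, knee
flexion/extension and ankle dorsi/plantar flexion, each per side.  In the
frontal view: shoulder obliquity, pelvic obliquity and hip
abduction/adduction.

Line definitions
----------------
* shoulder obliquity: RShoulder-LShoulder line vs horizontal
* pelvic obliquity:   RHip-LHip line vs horizontal
* hip FE:   hip->knee line vs the trunk line Neck->MidHip
* hip AA:   hip->knee line vs the downward perpendicular of RHip-LHip
* knee FE:  hip->knee line vs knee->ankle line
* ankle FE: foot line Heel->SmallToe vs shank line Knee->Ankle, minus 90 deg

Sign conventions (y-up coordinates; ``direction`` = +1 when the subject
walks toward +x) are chosen so that flexion, dorsiflexion and adduction are
positive regardless of walking direction; the convention string stored on
each series documents the choice.  The synthetic gait generator builds its
skeleton with these exact conventions inverted, so a noiseless round trip
recovers the generating curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .keypoint_io import KeypointTrajectorySet
from .landmarks import Landmark, side_landmark

N_CYCLE_SAMPLES = 101  # 0..100 % of the gait cycle

SAGITTAL_JOINTS = ("hip_FE", "knee_FE", "ankle_FE")
FRONTAL_JOINTS = ("shoulder_obliquity", "pelvic_obliquity", "hip_AA")


class UndefinedAngleError(ValueError):
    """Raised when an angle is requested for coincident points."""


@dataclass
class AngleSeries:
    """One joint/segment angle over time, in degrees (NaN where undefined)."""

    joint: str
    side: str  # "right", "left", or "none"
    plane: str
    values: np.ndarray
    fps: float
    sign_convention: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps

    @property
    def key(self) -> str:
        return f"{self.joint}_{self.side}" if self.side != "none" else self.joint


@dataclass
class CycleCurve:
    """A gait-cycle-normalized angle curve: 101 samples at 0..100 %."""

    joint: str
    side: str
    plane: str
    samples: np.ndarray  # mean across retained cycles, length 101
    n_cycles_averaged: int
    per_cycle: list = field(default_factory=list)  # each length 101
    n_cycles_discarded: int = 0

    @property
    def phase_pct(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, N_CYCLE_SAMPLES)


@dataclass
class RomValue:
    """Range of motion: per-cycle peak-to-peak excursion and its mean."""

    joint: str
    side: str
    plane: str
    rom_deg: float
    per_cycle_roms: list[float]


# ---------------------------------------------------------------------------
# Angle primitives


def _wrap180(a):
    """Wrap angles (degrees) into (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def signed_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Counter-clockwise rotation (deg) from vector(s) u to v, in (-180, 180].

    Works on single vectors or (n, 2) stacks; returns NaN where either
    vector is zero-length or contains NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    ang = np.degrees(np.arctan2(cross, dot))
    bad = (np.linalg.norm(u, axis=-1) == 0) | (np.linalg.norm(v, axis=-1) == 0)
    return np.where(bad, np.nan, ang)


def segment_angle_to_horizontal(p1, p2) -> float | np.ndarray:
    """Signed acute-range angle (-90, 90] between the line p1->p2 and +x.

    Measured counter-clockwise in y-up coordinates; a horizontal line gives
    0, a vertical line 90.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    scalar = d.ndim == 1
    if scalar and not np.any(d):
        raise UndefinedAngleError("coincident points define no line")
    ang = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    zero = (d[..., 0] == 0) & (d[..., 1] == 0)
    ang = np.where(zero, np.nan, ang)
    return float(ang) if scalar else ang


def angle_between_lines(a1, a2, b1, b2, signed: bool = True) -> float | np.ndarray:
    """Rotation from direction (a2 - a1) to direction (b2 - b1), degrees.

    Signed variant lies in (-180, 180]; unsigned is its absolute value.
    """
    a1, a2 = np.asarray(a1, float), np.asarray(a2, float)
    b1, b2 = np.asarray(b1, float), np.asarray(b2, float)
    u, v = a2 - a1, b2 - b1
    scalar = u.ndim == 1
    if scalar and (not np.any(u) or not np.any(v)):
        raise UndefinedAngleError("degenerate line in angle computation")
    ang = signed_angle(u, v)
    if not signed:
        ang = np.abs(ang)
    return float(ang) if scalar else ang


# ---------------------------------------------------------------------------
# Full-body angle extraction


def _dir(traj: KeypointTrajectorySet, a: Landmark, b: Landmark) -> np.ndarray:
    """Per-frame direction vectors a->b, shape (n, 2)."""
    return traj.point(b) - traj.point(a)


def _rot_minus90(v: np.ndarray) -> np.ndarray:
    """Rotate vectors by -90 deg (clockwise): (x, y) -> (y, -x)."""
    return np.stack([v[..., 1], -v[..., 0]], axis=-1)


def compute_angles(
    traj: KeypointTrajectorySet, direction: int = 1
) -> list[AngleSeries]:
    """Compute all angle series available in the trajectory's plane.

    ``direction`` is +1 when the subject walks toward +x, -1 otherwise;
    sagittal signs are multiplied by it so flexion stays positive for
    either walking direction.  Frames with any required landmark missing
    yield NaN.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    d = float(direction)
    series: list[AngleSeries] = []

    if traj.plane == "sagittal":
        trunk = _dir(traj, Landmark.Neck, Landmark.MidHip)  # points down
        for side in ("right", "left"):
            hip = traj.point(side_landmark("Hip", side))
            knee = traj.point(side_landmark("Knee", side))
            ankle = traj.point(side_landmark("Ankle", side))
            heel = traj.point(side_landmark("Heel", side))
            smalltoe = traj.point(side_landmark("SmallToe", side))
            thigh = knee - hip
            shank = ankle - knee
            foot = smalltoe - heel
            hip_fe = d * signed_angle(trunk, thigh)
            knee_fe = -d * signed_angle(thigh, shank)
            ankle_fe = _wrap180(_wrap180(d * signed_angle(shank, foot)) - 90.0)
            series += [
                AngleSeries("hip_FE", side, "sagittal", hip_fe, traj.fps,
                            "flexion positive (thigh forward of trunk)"),
                AngleSeries("knee_FE", side, "sagittal", knee_fe, traj.fps,
                            "flexion positive (shank behind thigh)"),
                AngleSeries("ankle_FE", side, "sagittal", ankle_fe, traj.fps,
                            "dorsiflexion positive; neutral foot "
                            "perpendicular to shank (90 deg offset)"),
            ]
    elif traj.plane == "frontal":
        rsh, lsh = traj.point(Landmark.RShoulder), traj.point(Landmark.LShoulder)
        rhip, lhip = traj.point(Landmark.RHip), traj.point(Landmark.LHip)
        series += [
            AngleSeries("shoulder_obliquity", "none", "frontal",
                        segment_angle_to_horizontal(rsh, lsh), traj.fps,
                        "CCW positive from horizontal, R->L shoulder line"),
            AngleSeries("pelvic_obliquity", "none", "frontal",
                        segment_angle_to_horizontal(rhip, lhip), traj.fps,
                        "CCW positive from horizontal, R->L hip line"),
        ]
        pelvis = lhip - rhip
        perp_down = _rot_minus90(pelvis)
        for side, sgn in (("right", 1.0), ("left", -1.0)):
            hip = traj.point(side_landmark("Hip", side))
            knee = traj.point(side_landmark("Knee", side))
            aa = sgn * signed_angle(perp_down, knee - hip)
            series.append(
                AngleSeries("hip_AA", side, "frontal", aa, traj.fps,
                            "adduction (knee toward midline) positive")
            )
    else:  # pragma: no cover - plane validated upstream
        raise ValueError(f"unknown plane {traj.plane!r}")
    return series


# ---------------------------------------------------------------------------
# Cycle normalization and ROM


class EmptyCurveError(ValueError):
    """Raised when no complete, fully observed gait cycle is available."""


def time_normalize(angles: AngleSeries, heel_strikes: np.ndarray) -> CycleCurve:
    """Resample each heel-strike-to-heel-strike cycle onto 101 points.

    Cycles containing residual missing angle samples are discarded and
    counted; the returned curve is the mean across retained cycles.

    Parameters
    ----------
    angles : AngleSeries
    heel_strikes : ordered ipsilateral heel-strike times (s); each
        consecutive pair delimits one cycle.
    """
    hs = np.asarray(heel_strikes, dtype=float)
    if len(hs) < 2:
        raise EmptyCurveError("need at least two heel strikes for one cycle")
    t = angles.times
    vals = np.asarray(angles.values, dtype=float)
    per_cycle = []
    discarded = 0
    for start, stop in zip(hs[:-1], hs[1:]):
        # frames whose linear interpolation the cycle depends on
        i0 = max(0, int(np.floor(start * angles.fps)))
        i1 = min(len(vals) - 1, int(np.ceil(stop * angles.fps)))
        if i0 >= i1 or start < t[0] or stop > t[-1]:
            discarded += 1
            continue
        if np.isnan(vals[i0 : i1 + 1]).any():
            discarded += 1
            continue
        phases = np.linspace(start, stop, N_CYCLE_SAMPLES)
        per_cycle.append(np.interp(phases, t, vals))
    if not per_cycle:
        raise EmptyCurveError(
            f"no retained cycles for {angles.joint} ({discarded} discarded)"
        )
    mean_curve = np.mean(per_cycle, axis=0)
    return CycleCurve(
        joint=angles.joint,
        side=angles.side,
        plane=angles.plane,
        samples=mean_curve,
        n_cycles_averaged=len(per_cycle),
        per_cycle=per_cycle,
        n_cycles_discarded=discarded,
    )


def rom(curve: CycleCurve) -> RomValue:
    """Per-cycle max - min excursion, averaged across cycles."""
    cycles = curve.per_cycle if curve.per_cycle else [curve.samples]
    roms = [float(np.max(c) - np.min(c)) for c in cycles]
    return RomValue(
        joint=curve.joint,
        side=curve.side,
        plane=curve.plane,
        rom_deg=float(np.mean(roms)),
        per_cycle_roms=roms,
    )
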