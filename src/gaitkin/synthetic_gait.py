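"""Synthetic 2D walking trials with fully known ground truth.

A planar skeleton is advanced by forward kinematics: the pelvis translates
at constant speed with a small vertical oscillation, the trunk stays near
vertical, and thigh/shank/foot are placed from low-order harmonic joint
waveforms — chosen so ROM and peak locations have closed or near-closed
forms, not for physiological realism.  The limb placement inverts the
exact line definitions and sign conventions of :mod:`gaitkin.kinematics`,
so on noiseless output the analysis pipeline recovers the generating
curves to resampling accuracy.

The generator emits:
  * an in-memory :class:`~gaitkin.keypoint_io.KeypointTrajectorySet`,
  * optionally a directory of per-frame BODY_25 JSON files byte-compatible
    with :func:`gaitkin.keypoint_io.read_openpose_dir`,
  * a :class:`GroundTruth` record (true per-frame angles, event times from
    a 1 kHz evaluation of the continuous foot trajectory, spatiotemporal
    parameters, ROMs, scale factor).

Degradation model: isotropic Gaussian pixel noise, independent Bernoulli
keypoint dropout written as the OpenPose (0, 0, 0) sentinel, and
confidence ~ Uniform(0.6, 1.0) for observed keypoints.

Emulated acquisition: a subject walking ~6 m at self-selected speed,
filmed at 25 fps, 640 x 480, sagittal or frontal view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .keypoint_io import KeypointTrajectorySet, flip_y
from .landmarks import N_LANDMARKS, Landmark

__all__ = [
    "GaitModelParams",
    "GroundTruth",
    "simulate_trial",
    "simulate_frontal_trial",
    "simulate_paired_study",
    "write_openpose_dir",
    "PRESETS",
    "preset_params",
]

_FINE_HZ = 1000.0  # grid for ground-truth event extraction


@dataclass
class GaitModelParams:
    """Generator parameters; defaults emulate a pediatric walking trial.

    Angle waveforms (degrees, phase phi in stride fractions, right leg;
    the left leg is phase-shifted by 0.5 cycle):

    * hip FE    = hip_offset + hip_amp * sin(2 pi phi + hip_phase)
    * knee FE   = knee_c0 + knee_c1 * (1 - cos 2 pi phi)
                  + knee_c2 * (1 - cos(4 pi phi + knee_phase2))
    * ankle FE  = ankle_amp * sin(2 pi phi + ankle_phase)
    * pelvic / shoulder obliquity, hip AA: single sinusoids (frontal view)
    """

    fps: float = 25.0
    image_size: tuple[int, int] = (640, 480)
    duration_s: float = 7.0
    walk_speed: float = 0.9  # m/s, self-selected pediatric pace
    cadence_steps_min: float = 112.0
    direction: int = 1

    # segment lengths (m), pediatric-scale
    trunk_len: float = 0.45
    thigh_len: float = 0.32
    shank_len: float = 0.31
    foot_len: float = 0.18
    pelvis_width: float = 0.20
    shoulder_width: float = 0.28

    # sagittal angle waveform coefficients (degrees)
    hip_offset: float = 10.0
    hip_amp: float = 18.0
    hip_phase: float = np.pi / 2  # peak flexion at heel strike
    knee_c0: float = 4.0
    knee_c1: float = 18.0
    knee_c2: float = 10.0
    knee_phase2: float = np.pi / 3
    ankle_amp: float = 10.0
    ankle_phase: float = 0.0
    # asymmetry: per-side multiplicative ROM scaling (hemiplegia presets)
    rom_scale_right: float = 1.0
    rom_scale_left: float = 1.0

    # frontal waveform coefficients (degrees) and step width (m)
    pelvic_obliquity_amp: float = 4.0
    shoulder_obliquity_amp: float = 2.0
    hip_aa_amp: float = 4.0
    hip_aa_offset: float = 2.0
    step_width: float = 0.10
    step_width_osc: float = 0.005

    vertical_osc_amp: float = 0.02  # pelvis bounce (m), period = half stride

    # rescale hip_amp so the geometric step length (ankle gap at heel
    # strike) matches walk_speed * stride_period / 2 — the ground-contact
    # consistency real gait has; without it the feet "slip" and
    # speed != cadence x step length
    calibrate_step: bool = True

    scale_px_per_m: float = 95.0
    noise_sigma_px: float = 2.0
    dropout_prob: float = 0.02
    conf_low: float = 0.6
    conf_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.trunk_len, self.thigh_len, self.shank_len, self.foot_len,
               self.walk_speed, self.cadence_steps_min, self.fps) <= 0:
            raise ValueError("lengths and rates must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must lie in [0, 1)")
        kmax = abs(self.knee_c0) + 2 * abs(self.knee_c1) + 2 * abs(self.knee_c2)
        if kmax > 160:
            raise ValueError(
                f"knee waveform reaches {kmax:.0f} deg (> 160): implausible"
            )

    @property
    def stride_period(self) -> float:
        """Stride (full cycle) period in seconds: two steps per stride."""
        return 120.0 / self.cadence_steps_min


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    angles: dict  # key -> per-frame degrees (e.g. "hip_FE_right")
    times: np.ndarray
    heel_strikes: dict  # side -> times (s)
    toe_offs: dict
    spatiotemporal: dict
    roms: dict  # key -> degrees
    meters_per_pixel: float
    params: GaitModelParams = None


# ---------------------------------------------------------------------------
# Waveforms


def _hip_fe(p: GaitModelParams, phi: np.ndarray, scale: float) -> np.ndarray:
    return p.hip_offset + scale * p.hip_amp * np.sin(2 * np.pi * phi + p.hip_phase)


def _knee_fe(p: GaitModelParams, phi: np.ndarray, scale: float) -> np.ndarray:
    return (
        p.knee_c0
        + scale * p.knee_c1 * (1 - np.cos(2 * np.pi * phi))
        + scale * p.knee_c2 * (1 - np.cos(4 * np.pi * phi + p.knee_phase2))
    )


def _ankle_fe(p: GaitModelParams, phi: np.ndarray, scale: float) -> np.ndarray:
    return scale * p.ankle_amp * np.sin(2 * np.pi * phi + p.ankle_phase)


def _side_waveforms(p: GaitModelParams, t: np.ndarray, side: str):
    phi = t / p.stride_period
    if side == "left":
        phi = phi + 0.5
    scale = p.rom_scale_right if side == "right" else p.rom_scale_left
    return _hip_fe(p, phi, scale), _knee_fe(p, phi, scale), _ankle_fe(p, phi, scale)


def _rot(v: np.ndarray, deg: np.ndarray) -> np.ndarray:
    """Rotate 2-vectors (stacked in last axis) CCW by per-sample degrees."""
    rad = np.radians(deg)
    c, s = np.cos(rad), np.sin(rad)
    return np.stack(
        [c * v[..., 0] - s * v[..., 1], s * v[..., 0] + c * v[..., 1]], axis=-1
    )


# ---------------------------------------------------------------------------
# Sagittal forward kinematics (meters, y-up, ground at y = 0)


def _sagittal_skeleton(p: GaitModelParams, t: np.ndarray) -> dict:
    """Landmark positions (m) at times t; returns name -> (len(t), 2)."""
    d = float(p.direction)
    hip_h = p.thigh_len + p.shank_len + 0.05
    midhip = np.stack(
        [
            d * p.walk_speed * t,
            hip_h
            + p.vertical_osc_amp * np.sin(4 * np.pi * t / p.stride_period),
        ],
        axis=-1,
    )
    neck = midhip + np.array([0.0, p.trunk_len])
    pts = {
        "MidHip": midhip,
        "RHip": midhip.copy(),
        "LHip": midhip.copy(),
        "Neck": neck,
        "Nose": neck + np.array([d * 0.04, 0.14]),
        "RShoulder": neck + np.array([0.0, -0.03]),
        "LShoulder": neck + np.array([0.0, -0.03]),
    }
    for side in ("right", "left"):
        h, k, a = _side_waveforms(p, t, side)
        # thigh tilted forward (toward walking direction) by hip FE
        thigh_dir = np.stack(
            [d * np.sin(np.radians(h)), -np.cos(np.radians(h))], axis=-1
        )
        shank_ang = h - k  # shank absolute forward tilt
        shank_dir = np.stack(
            [d * np.sin(np.radians(shank_ang)), -np.cos(np.radians(shank_ang))],
            axis=-1,
        )
        knee = midhip + p.thigh_len * thigh_dir
        ankle = knee + p.shank_len * shank_dir
        foot_dir = _rot(shank_dir, d * (90.0 + a))
        heel = ankle - 0.30 * p.foot_len * foot_dir
        smalltoe = heel + p.foot_len * foot_dir
        bigtoe = heel + 1.08 * p.foot_len * foot_dir
        pre = "R" if side == "right" else "L"
        pts[f"{pre}Knee"] = knee
        pts[f"{pre}Ankle"] = ankle
        pts[f"{pre}Heel"] = heel
        pts[f"{pre}SmallToe"] = smalltoe
        pts[f"{pre}BigToe"] = bigtoe
    # arms and head filler (uninvolved in analysis)
    for pre in ("R", "L"):
        sh = pts[f"{pre}Shoulder"]
        pts[f"{pre}Elbow"] = sh + np.array([d * 0.03, -0.22])
        pts[f"{pre}Wrist"] = sh + np.array([d * 0.06, -0.42])
        pts[f"{pre}Eye"] = pts["Nose"] + np.array([-d * 0.01, 0.02])
        pts[f"{pre}Ear"] = pts["Nose"] + np.array([-d * 0.05, 0.0])
    missing = [lm.name for lm in Landmark if lm.name not in pts]
    assert not missing, f"skeleton incomplete: {missing}"
    return pts


def _mean_step_gap(p: GaitModelParams) -> float:
    """Ankle gap (m) at the heel strikes of one steady stride."""
    T = p.stride_period
    tf = np.linspace(2 * T, 3 * T, 1000, endpoint=False)
    pts = _sagittal_skeleton(p, tf)
    d = float(p.direction)
    gaps = []
    for pre in ("R", "L"):
        rel = d * (pts[f"{pre}Heel"][:, 0] - pts["MidHip"][:, 0])
        i = int(np.argmax(rel))
        gaps.append(abs(pts["LAnkle"][i, 0] - pts["RAnkle"][i, 0]))
    return float(np.mean(gaps))


def _calibrate_step(p: GaitModelParams) -> GaitModelParams:
    """Bisect a hip-amplitude multiplier until the geometric step length
    equals walk_speed * stride_period / 2.

    Skipped when calibration is disabled, the hip waveform is flat, or the
    target is outside the reachable range (parameters are then used as
    given)."""
    if not p.calibrate_step or p.hip_amp == 0:
        return p
    target = p.walk_speed * p.stride_period / 2.0
    base = p.hip_amp

    def gap(m: float) -> float:
        return _mean_step_gap(replace(p, hip_amp=m * base, calibrate_step=False))

    lo, hi = 0.2, 3.0
    if not (gap(lo) <= target <= gap(hi)):
        return p
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if gap(mid) < target:
            lo = mid
        else:
            hi = mid
    return replace(p, hip_amp=0.5 * (lo + hi) * base, calibrate_step=False)


def _true_angles_sagittal(p: GaitModelParams, t: np.ndarray) -> dict:
    out = {}
    for side in ("right", "left"):
        h, k, a = _side_waveforms(p, t, side)
        out[f"hip_FE_{side}"] = h
        out[f"knee_FE_{side}"] = k
        out[f"ankle_FE_{side}"] = a
    return out


def _true_events(p: GaitModelParams) -> tuple[dict, dict]:
    """Ground-truth events from a 1 kHz noiseless foot trajectory.

    Heel strikes are maxima of the forward heel position relative to the
    pelvis; toe offs are minima of the relative big-toe position — the
    same geometric definition the detector applies at camera rate.
    """
    tf = np.arange(0.0, p.duration_s, 1.0 / _FINE_HZ)
    pts = _sagittal_skeleton(p, tf)
    d = float(p.direction)
    hs, to = {}, {}
    min_dist = int(0.5 * p.stride_period * _FINE_HZ)
    for side, pre in (("right", "R"), ("left", "L")):
        rel_heel = d * (pts[f"{pre}Heel"][:, 0] - pts["MidHip"][:, 0])
        rel_toe = d * (pts[f"{pre}BigToe"][:, 0] - pts["MidHip"][:, 0])
        hs_i, _ = _signal.find_peaks(rel_heel, distance=min_dist)
        to_i, _ = _signal.find_peaks(-rel_toe, distance=min_dist)
        hs[side] = tf[hs_i]
        to[side] = tf[to_i]
    return hs, to


def _true_spatiotemporal(p: GaitModelParams, hs: dict, to: dict) -> dict:
    """Spatiotemporal truth from the noiseless geometry and true events."""
    T = p.stride_period
    # geometric ankle gap at the true heel strikes (what the measurement
    # definition yields on perfect data)
    step_by_side = {}
    for side in ("right", "left"):
        if len(hs[side]) == 0:
            continue
        pts = _sagittal_skeleton(p, hs[side])
        gap = np.abs(pts["LAnkle"][:, 0] - pts["RAnkle"][:, 0])
        step_by_side[side] = float(np.mean(gap))
    mean_step = float(np.mean(list(step_by_side.values())))
    stance = {}
    for side in ("right", "left"):
        pcts = []
        for a, b in zip(hs[side][:-1], hs[side][1:]):
            t_off = to[side][(to[side] > a) & (to[side] < b)]
            if len(t_off) == 1:
                pcts.append((t_off[0] - a) / (b - a) * 100.0)
        stance[side] = float(np.mean(pcts)) if pcts else np.nan
    return {
        "gait_speed_ms": p.walk_speed,
        "cadence_steps_min": p.cadence_steps_min,
        "cadence_strides_min": 60.0 / T,
        "cycle_duration_s": T,
        "step_length_m": mean_step,
        "stride_length_right_m": 2 * step_by_side.get("right", np.nan),
        "stride_length_left_m": 2 * step_by_side.get("left", np.nan),
        "stance_pct_right": stance["right"],
        "stance_pct_left": stance["left"],
        "step_width_m": p.step_width,
    }


def _true_roms(p: GaitModelParams) -> dict:
    """Per-joint stride ROM from the waveform coefficients.

    Hip and ankle are single sinusoids (ROM = 2 * amplitude); the
    two-harmonic knee ROM is evaluated on a dense phase grid of the
    analytic waveform.
    """
    phi = np.linspace(0.0, 1.0, 20001)
    out = {}
    for side in ("right", "left"):
        s = p.rom_scale_right if side == "right" else p.rom_scale_left
        out[f"hip_FE_{side}"] = 2 * s * p.hip_amp
        out[f"ankle_FE_{side}"] = 2 * s * p.ankle_amp
        knee = _knee_fe(p, phi, s)
        out[f"knee_FE_{side}"] = float(np.ptp(knee))
    out["pelvic_obliquity"] = 2 * p.pelvic_obliquity_amp
    out["shoulder_obliquity"] = 2 * p.shoulder_obliquity_amp
    out["hip_AA_right"] = 2 * p.hip_aa_amp
    out["hip_AA_left"] = 2 * p.hip_aa_amp
    return out


# ---------------------------------------------------------------------------
# Projection, degradation, emission


def _project_and_degrade(
    p: GaitModelParams, pts: dict, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Meters -> pixels (y-up), plus noise, dropout and confidences."""
    n = len(next(iter(pts.values())))
    xy = np.empty((n, N_LANDMARKS, 2))
    for lm in Landmark:
        xy[:, int(lm), :] = pts[lm.name]
    # center the walk path horizontally, feet near the lower image area
    xs = xy[:, :, 0]
    x_mid = (np.nanmin(xs) + np.nanmax(xs)) / 2.0
    xy[:, :, 0] = (xy[:, :, 0] - x_mid) * p.scale_px_per_m + p.image_size[0] / 2.0
    xy[:, :, 1] = xy[:, :, 1] * p.scale_px_per_m + 0.15 * p.image_size[1]
    if p.noise_sigma_px > 0:
        xy += rng.normal(0.0, p.noise_sigma_px, size=xy.shape)
    conf = rng.uniform(p.conf_low, p.conf_high, size=(n, N_LANDMARKS))
    if p.dropout_prob > 0:
        drop = rng.random((n, N_LANDMARKS)) < p.dropout_prob
        xy[drop] = np.nan
        conf[drop] = 0.0
    return xy, conf


def simulate_trial(
    p: GaitModelParams | None = None, out_dir: str | Path | None = None
) -> tuple[KeypointTrajectorySet, GroundTruth]:
    """Generate one sagittal walking trial.

    Returns the trajectory set (y-up pixel coordinates, NaN at dropped
    keypoints) and its ground truth.  If ``out_dir`` is given, per-frame
    OpenPose BODY_25 JSON files are also written there.
    """
    if p is None:
        p = GaitModelParams()
    p = _calibrate_step(p)
    rng = np.random.default_rng(p.seed)
    t = np.arange(int(round(p.duration_s * p.fps))) / p.fps
    pts = _sagittal_skeleton(p, t)
    xy, conf = _project_and_degrade(p, pts, rng)
    traj = KeypointTrajectorySet(
        fps=p.fps, image_size=p.image_size, plane="sagittal", xy=xy, conf=conf,
        source="synthetic", meta={"seed": p.seed},
    )
    hs, to = _true_events(p)
    truth = GroundTruth(
        angles=_true_angles_sagittal(p, t),
        times=t,
        heel_strikes=hs,
        toe_offs=to,
        spatiotemporal=_true_spatiotemporal(p, hs, to),
        roms=_true_roms(p),
        meters_per_pixel=1.0 / p.scale_px_per_m,
        params=p,
    )
    if out_dir is not None:
        write_openpose_dir(traj, out_dir)
    return traj, truth


# ---------------------------------------------------------------------------
# Frontal view


def simulate_frontal_trial(
    p: GaitModelParams | None = None,
) -> tuple[KeypointTrajectorySet, GroundTruth]:
    """Generate a frontal-view trial (subject walking toward the camera).

    Without perspective projection the body stays at constant image scale;
    obliquity and hip abduction/adduction waveforms are applied directly
    to the pelvis/shoulder lines and thigh directions, and the lateral
    ankle separation oscillates around the true step width.
    """
    if p is None:
        p = GaitModelParams()
    rng = np.random.default_rng(p.seed)
    t = np.arange(int(round(p.duration_s * p.fps))) / p.fps
    phi = t / p.stride_period
    hip_h = p.thigh_len + p.shank_len + 0.05
    n = len(t)

    pelv_obl = p.pelvic_obliquity_amp * np.sin(2 * np.pi * phi)
    shld_obl = p.shoulder_obliquity_amp * np.sin(2 * np.pi * phi + np.pi)
    aa_r = p.hip_aa_offset + p.hip_aa_amp * np.sin(2 * np.pi * phi)
    aa_l = p.hip_aa_offset + p.hip_aa_amp * np.sin(2 * np.pi * (phi + 0.5))

    midhip = np.stack(
        [np.zeros(n),
         hip_h + p.vertical_osc_amp * np.sin(4 * np.pi * phi)], axis=-1
    )
    neck = midhip + np.array([0.0, p.trunk_len])
    # subject's left on image +x; obliquity tilts the R->L line CCW
    pelvis_dir = _rot(np.tile([1.0, 0.0], (n, 1)), pelv_obl)
    shoulder_dir = _rot(np.tile([1.0, 0.0], (n, 1)), shld_obl)
    pts = {
        "MidHip": midhip,
        "Neck": neck,
        "Nose": neck + np.array([0.0, 0.14]),
        "RHip": midhip - 0.5 * p.pelvis_width * pelvis_dir,
        "LHip": midhip + 0.5 * p.pelvis_width * pelvis_dir,
        "RShoulder": neck - 0.5 * p.shoulder_width * shoulder_dir,
        "LShoulder": neck + 0.5 * p.shoulder_width * shoulder_dir,
    }
    perp_down = np.stack([pelvis_dir[:, 1], -pelvis_dir[:, 0]], axis=-1)
    for side, aa, sgn in (("right", aa_r, 1.0), ("left", aa_l, -1.0)):
        pre = "R" if side == "right" else "L"
        hip = pts[f"{pre}Hip"]
        thigh_dir = _rot(perp_down, sgn * aa)
        knee = hip + p.thigh_len * thigh_dir
        pts[f"{pre}Knee"] = knee
        lat = (-1.0 if side == "right" else 1.0) * 0.5 * (
            p.step_width + p.step_width_osc * np.sin(2 * np.pi * phi)
        )
        ankle = np.stack([lat, np.full(n, 0.06)], axis=-1)
        pts[f"{pre}Ankle"] = ankle
        pts[f"{pre}Heel"] = ankle + np.array([0.0, -0.03])
        pts[f"{pre}BigToe"] = ankle + np.array([0.0, -0.05])
        pts[f"{pre}SmallToe"] = ankle + (
            np.array([-0.03, -0.05]) if side == "right" else np.array([0.03, -0.05])
        )
        sh = pts[f"{pre}Shoulder"]
        pts[f"{pre}Elbow"] = sh + np.array([0.0, -0.22])
        pts[f"{pre}Wrist"] = sh + np.array([0.0, -0.42])
        pts[f"{pre}Eye"] = pts["Nose"] + np.array([sgn * -0.03, 0.02])
        pts[f"{pre}Ear"] = pts["Nose"] + np.array([sgn * -0.06, 0.0])

    xy, conf = _project_and_degrade(p, pts, rng)
    traj = KeypointTrajectorySet(
        fps=p.fps, image_size=p.image_size, plane="frontal", xy=xy, conf=conf,
        source="synthetic-frontal", meta={"seed": p.seed},
    )
    # declared events on the phase grid (frontal video carries no forward
    # foot motion to detect them from)
    T = p.stride_period
    stance_frac = 0.62
    hs_r = np.arange(0.0, p.duration_s, T)
    truth = GroundTruth(
        angles={
            "pelvic_obliquity": pelv_obl,
            "shoulder_obliquity": shld_obl,
            "hip_AA_right": aa_r,
            "hip_AA_left": aa_l,
        },
        times=t,
        heel_strikes={"right": hs_r, "left": hs_r + 0.5 * T},
        toe_offs={"right": hs_r + stance_frac * T,
                  "left": hs_r + (0.5 + stance_frac) * T},
        spatiotemporal={"step_width_m": p.step_width},
        roms=_true_roms(p),
        meters_per_pixel=1.0 / p.scale_px_per_m,
        params=p,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# OpenPose JSON emission


def write_openpose_dir(traj: KeypointTrajectorySet, out_dir: str | Path) -> None:
    """Write one BODY_25 JSON file per frame in the OpenPose dialect.

    Coordinates are converted back to image (y-down) convention; missing
    keypoints become the (0, 0, 0) sentinel.  Confidence of observed
    keypoints is floored at 0.5 so the loader's default threshold does not
    re-drop them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = traj.image_size[1]
    for i in range(traj.n_frames):
        kp = []
        for j in range(N_LANDMARKS):
            x, y = traj.xy[i, j]
            c = traj.conf[i, j]
            if np.isnan(x) or np.isnan(y) or c <= 0:
                kp += [0.0, 0.0, 0.0]
            else:
                kp += [round(float(x), 3), round(float(flip_y(y, h)), 3),
                       round(float(max(c, 0.5)), 3)]
        doc = {"version": 1.3, "people": [{"person_id": [-1],
                                           "pose_keypoints_2d": kp}]}
        with open(out_dir / f"frame_{i:012d}_keypoints.json", "w") as fh:
            json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Paired two-system study generator


def simulate_paired_study(
    n_subjects: int,
    mu: float = 50.0,
    sigma_between: float = 10.0,
    sigma_err_pose: float = 3.0,
    sigma_err_ref: float = 3.0,
    bias: float = 0.0,
    seed: int = 0,
    variable_name: str = "synthetic_variable",
    units: str = "",
):
    """Paired per-subject data with a known population ICC(A,2).

    Subject truths are Normal(mu, sigma_between^2); each method observes
    truth + its own bias and Normal error.  Returns the paired data and
    the closed-form population ICC implied by the variance components:

        ICC(A,2) = sigma_b^2 / (sigma_b^2 + (theta_c + sigma_e^2) / 2)

    with theta_c = bias^2 / 2 (two fixed methods offset by ``bias``) and
    sigma_e^2 the mean of the two error variances.
    """
    from .agreement import PairedMeasurements

    if n_subjects < 3:
        raise ValueError("need n >= 3 subjects")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mu, sigma_between, n_subjects)
    ref = truth + rng.normal(0.0, sigma_err_ref, n_subjects)
    pose = truth + bias + rng.normal(0.0, sigma_err_pose, n_subjects)
    sigma_e2 = (sigma_err_pose**2 + sigma_err_ref**2) / 2.0
    theta_c = bias**2 / 2.0
    denom = sigma_between**2 + (theta_c + sigma_e2) / 2.0
    pop_icc = sigma_between**2 / denom if denom > 0 else np.nan
    pairs = PairedMeasurements(variable_name, units, pose, ref)
    return pairs, float(pop_icc)


# ---------------------------------------------------------------------------
# Presets: gross per-group walking patterns


PRESETS: dict[str, dict] = {
    "sagittal-normal": {},
    "slow-short-stride": {"walk_speed": 0.7, "cadence_steps_min": 100.0},
    "hemiplegia-right": {"rom_scale_right": 0.55, "walk_speed": 0.75,
                         "cadence_steps_min": 104.0},
    "hemiplegia-left": {"rom_scale_left": 0.55, "walk_speed": 0.75,
                        "cadence_steps_min": 104.0},
    "spastic-paraparesis": {"rom_scale_right": 0.7, "rom_scale_left": 0.7,
                            "knee_c0": 12.0, "walk_speed": 0.65,
                            "cadence_steps_min": 98.0},
}


def preset_params(name: str, **overrides) -> GaitModelParams:
    """GaitModelParams for a named preset, with keyword overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return GaitModelParams(**kwargs)


def preset_yaml() -> str:
    """The preset table serialized as YAML (for the CLI and docs)."""
    import yaml

    return yaml.safe_dump({k: dict(v) for k, v in PRESETS.items()},
                          sort_keys=True)
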