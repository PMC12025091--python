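"""Reading OpenPose BODY_25 output and the package's tabular trajectory format.

OpenPose writes one JSON file per video frame.  Each file holds a ``people``
list; each person carries a flat ``pose_keypoints_2d`` array of 75 floats
(25 landmarks x (x, y, confidence)).  An undetected landmark is encoded as
the sentinel triple (0, 0, 0).

On load this module
  * sorts files lexicographically into frame order (zero-padded indices),
  * selects and tracks a single person per frame (confidence sum, then
    MidHip proximity to the previous selection),
  * marks sentinel keypoints and keypoints below a confidence threshold as
    missing, and
  * flips the image y-axis so that y points UP, giving "angle relative to
    the horizontal" its ordinary geometric meaning downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .landmarks import LANDMARK_NAMES, N_LANDMARKS, Landmark

DEFAULT_CONF_MIN = 0.30
PLANES = ("sagittal", "frontal")


class FormatError(ValueError):
    """Raised for malformed OpenPose JSON input."""


@dataclass
class KeypointTrajectorySet:
    """Time-indexed pixel trajectories of the 25 BODY_25 landmarks.

    Attributes
    ----------
    fps : float
        Acquisition frame rate (frames/second).
    image_size : tuple[int, int]
        (width, height) in pixels of the source video.
    plane : str
        ``"sagittal"`` or ``"frontal"`` camera plane.
    xy : ndarray, shape (n_frames, 25, 2)
        Pixel coordinates in y-UP convention; NaN where missing.
    conf : ndarray, shape (n_frames, 25)
        Detection confidence in [0, 1]; 0 where the person or keypoint was
        absent.
    """

    fps: float
    image_size: tuple[int, int]
    plane: str
    xy: np.ndarray
    conf: np.ndarray
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        self.xy = np.asarray(self.xy, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if self.xy.shape != (len(self.conf), N_LANDMARKS, 2):
            raise ValueError(f"xy has shape {self.xy.shape}, expected (n, 25, 2)")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame_index / fps)."""
        return np.arange(self.n_frames) / self.fps

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask (n_frames, 25), True where a landmark is missing."""
        return np.isnan(self.xy).any(axis=2)

    def point(self, lm: Landmark) -> np.ndarray:
        """(n_frames, 2) trajectory of one landmark (NaN where missing)."""
        return self.xy[:, int(lm), :]

    def x(self, lm: Landmark) -> np.ndarray:
        return self.xy[:, int(lm), 0]

    def y(self, lm: Landmark) -> np.ndarray:
        return self.xy[:, int(lm), 1]

    def copy(self) -> "KeypointTrajectorySet":
        return KeypointTrajectorySet(
            fps=self.fps,
            image_size=self.image_size,
            plane=self.plane,
            xy=self.xy.copy(),
            conf=self.conf.copy(),
            source=self.source,
            meta=dict(self.meta),
        )


def flip_y(y: np.ndarray | float, image_height: float) -> np.ndarray | float:
    """Map image-row coordinates (y down) to y-up coordinates.

    The transform ``y -> H - y`` is its own inverse, so applying it twice
    restores raw image coordinates.
    """
    return image_height - np.asarray(y, dtype=float)


def _parse_frame_file(path: Path) -> list[np.ndarray]:
    """Return the per-person (25, 3) keypoint arrays of one frame file."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable or malformed OpenPose JSON: {path}") from exc
    people = doc.get("people", [])
    persons = []
    for person in people:
        kp = person.get("pose_keypoints_2d", [])
        if len(kp) != 3 * N_LANDMARKS:
            raise FormatError(
                f"{path}: pose_keypoints_2d has {len(kp)} values, expected 75"
            )
        persons.append(np.asarray(kp, dtype=float).reshape(N_LANDMARKS, 3))
    return persons


def select_person(frames: Sequence[Sequence[np.ndarray]]) -> list[int | None]:
    """Pick one person per frame from raw multi-person detections.

    Within a frame, candidates are scored by summed keypoint confidence;
    across frames, the candidate whose MidHip lies nearest the previously
    selected MidHip is preferred (greedy proximity tracking).  A frame with
    no detections selects nobody (``None``).
    """
    chosen: list[int | None] = []
    prev_midhip: np.ndarray | None = None
    for persons in frames:
        if not persons:
            chosen.append(None)
            continue
        confs = np.array([p[:, 2].sum() for p in persons])
        if prev_midhip is None:
            idx = int(np.argmax(confs))
        else:
            dists = []
            for p in persons:
                mh = p[int(Landmark.MidHip), :2]
                if p[int(Landmark.MidHip), 2] <= 0:
                    dists.append(np.inf)
                else:
                    dists.append(float(np.hypot(*(mh - prev_midhip))))
            dists = np.asarray(dists)
            if np.isfinite(dists).any():
                # proximity first; confidence breaks near-ties (within 20 px)
                near = dists <= dists[np.isfinite(dists)].min() + 20.0
                cand = np.flatnonzero(near)
                idx = int(cand[np.argmax(confs[cand])])
            else:
                idx = int(np.argmax(confs))
        sel = persons[idx]
        if sel[int(Landmark.MidHip), 2] > 0:
            prev_midhip = sel[int(Landmark.MidHip), :2]
        chosen.append(idx)
    return chosen


def read_openpose_dir(
    path: str | Path,
    fps: float,
    plane: str = "sagittal",
    image_size: tuple[int, int] = (640, 480),
    conf_min: float = DEFAULT_CONF_MIN,
) -> KeypointTrajectorySet:
    """Load a directory of per-frame OpenPose JSON files.

    Frames are ordered by lexicographic filename sort.  Keypoints with the
    (0, 0, 0) sentinel, zero confidence, raw coordinates (0, 0), or
    confidence below ``conf_min`` are marked missing (NaN).  The y-axis is
    flipped to point upward.

    Raises
    ------
    FormatError
        If a file is unreadable, not valid JSON, or a keypoint array does
        not hold exactly 75 numbers.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix == ".json")
    if not files:
        raise FileNotFoundError(f"no .json frame files in {path}")
    raw_frames = [_parse_frame_file(f) for f in files]
    indices = select_person(raw_frames)

    n = len(raw_frames)
    xy = np.full((n, N_LANDMARKS, 2), np.nan)
    conf = np.zeros((n, N_LANDMARKS))
    for i, (persons, idx) in enumerate(zip(raw_frames, indices)):
        if idx is None:
            continue
        p = persons[idx]
        missing = (p[:, 2] <= 0.0) | ((p[:, 0] == 0.0) & (p[:, 1] == 0.0))
        missing |= p[:, 2] < conf_min
        ok = ~missing
        xy[i, ok, 0] = p[ok, 0]
        xy[i, ok, 1] = flip_y(p[ok, 1], image_size[1])
        conf[i] = p[:, 2]

    return KeypointTrajectorySet(
        fps=fps, image_size=image_size, plane=plane, xy=xy, conf=conf,
        source=str(path),
    )


# ---------------------------------------------------------------------------
# Long-format tabular trajectory file (frame, time_s, landmark, x, y,
# confidence, missing).


def to_frame_table(traj: KeypointTrajectorySet) -> pd.DataFrame:
    """Long-format DataFrame of one trajectory set."""
    n = traj.n_frames
    frames = np.repeat(np.arange(n), N_LANDMARKS)
    return pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames / traj.fps,
            "landmark": np.tile(np.asarray(LANDMARK_NAMES, dtype=object), n),
            "x": traj.xy[:, :, 0].ravel(),
            "y": traj.xy[:, :, 1].ravel(),
            "confidence": traj.conf.ravel(),
            "missing": traj.missing.ravel(),
        }
    )


def write_trajectory_csv(traj: KeypointTrajectorySet, path: str | Path) -> None:
    """Write a trajectory set as a long-format CSV with a metadata header."""
    path = Path(path)
    header = (
        f"# gaitkin-trajectory v1 fps={traj.fps!r} "
        f"width={traj.image_size[0]} height={traj.image_size[1]} "
        f"plane={traj.plane}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # %.17g round-trips IEEE doubles exactly
        to_frame_table(traj).to_csv(fh, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path) -> KeypointTrajectorySet:
    """Read a trajectory set written by :func:`write_trajectory_csv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# gaitkin-trajectory"):
            raise FormatError(f"{path}: not a gaitkin trajectory file")
        kv = dict(tok.split("=", 1) for tok in header.split() if "=" in tok)
        df = pd.read_csv(fh, float_precision="round_trip")
    n = int(df["frame"].max()) + 1
    name_to_idx = {name: i for i, name in enumerate(LANDMARK_NAMES)}
    xy = np.full((n, N_LANDMARKS, 2), np.nan)
    conf = np.zeros((n, N_LANDMARKS))
    rows = df["frame"].to_numpy()
    cols = df["landmark"].map(name_to_idx).to_numpy()
    xy[rows, cols, 0] = df["x"].to_numpy()
    xy[rows, cols, 1] = df["y"].to_numpy()
    conf[rows, cols] = df["confidence"].to_numpy()
    return KeypointTrajectorySet(
        fps=float(kv["fps"]),
        image_size=(int(kv["width"]), int(kv["height"])),
        plane=kv["plane"],
        xy=xy,
        conf=conf,
        source=str(path),
    )
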