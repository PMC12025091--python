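"""Gap interpolation and smoothing of keypoint trajectories.

Pose-estimation trajectories carry short dropouts (undetected keypoints)
and frame-to-frame pixel jitter.  Before any angle is computed:

1. Maximal runs of consecutive missing samples shorter than ``max_gap_ms``
   (default 300 ms, exclusive) are filled by linear interpolation between
   the flanking observed samples.  Longer runs, and runs touching either
   end of the series, are left missing; gait cycles containing them are
   discarded later rather than extrapolated.
2. Each contiguous observed segment is low-pass filtered with a zero-phase
   (forward-backward) Butterworth filter, 4th order, 6 Hz cutoff by
   default — the conventional smoothing for gait kinematics.  Segments too
   short to filter are passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .keypoint_io import KeypointTrajectorySet


@dataclass
class PreprocessConfig:
    """Parameters for gap filling and smoothing.

    ``max_gap_ms`` is an exclusive bound: a run is filled only when its
    duration ``run_length / fps * 1000`` is strictly below it.
    """

    fps: float
    max_gap_ms: float = 300.0
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    apply_filter: bool = True

    def __post_init__(self) -> None:
        if self.max_gap_ms <= 0:
            raise ValueError("max_gap_ms must be positive")
        if self.apply_filter and not (0 < self.filter_cutoff_hz < self.fps / 2):
            raise ValueError(
                f"filter_cutoff_hz must lie in (0, fps/2) = (0, {self.fps / 2})"
            )


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of maximal True runs in a boolean mask."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def interpolate_gaps(
    series: np.ndarray, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short missing runs in a uniformly sampled series.

    Parameters
    ----------
    series : 1-D array with NaN marking missing samples.
    cfg : PreprocessConfig

    Returns
    -------
    filled : array with short interior gaps linearly interpolated.
    still_missing : boolean mask of samples left missing (long gaps and
        gaps touching a series boundary).
    """
    series = np.asarray(series, dtype=float)
    out = series.copy()
    mask = np.isnan(series)
    if mask.all():
        return out, mask
    n = len(series)
    for start, stop in _missing_runs(mask):
        run = stop - start
        if start == 0 or stop == n:
            continue  # boundary gap: no anchor on one side
        if run * 1000.0 / cfg.fps >= cfg.max_gap_ms:
            continue
        left, right = series[start - 1], series[stop]
        t = np.arange(1, run + 1) / (run + 1)
        out[start:stop] = left + t * (right - left)
    return out, np.isnan(out)


def smooth(series: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase low-pass filter applied per contiguous observed segment.

    Residual-missing samples (NaN) are untouched; observed segments shorter
    than the filtfilt padding requirement pass through unfiltered.
    """
    series = np.asarray(series, dtype=float)
    if not cfg.apply_filter:
        return series.copy()
    out = series.copy()
    sos = signal.butter(
        cfg.filter_order, cfg.filter_cutoff_hz, btype="low", fs=cfg.fps, output="sos"
    )
    # forward-backward filtering doubles the order; padlen mirrors filtfilt
    min_len = 3 * (2 * cfg.filter_order + 1)
    observed = ~np.isnan(series)
    for start, stop in _missing_runs(observed):
        seg = series[start:stop]
        if len(seg) < min_len:
            continue
        out[start:stop] = signal.sosfiltfilt(sos, seg)
    return out


def preprocess_trajectories(
    traj: KeypointTrajectorySet, cfg: PreprocessConfig | None = None
) -> tuple[KeypointTrajectorySet, dict]:
    """Apply gap filling then smoothing to every landmark coordinate.

    Returns the cleaned trajectory set and a stats dict with the counts of
    samples filled and left missing.
    """
    if cfg is None:
        cfg = PreprocessConfig(fps=traj.fps)
    out = traj.copy()
    n_filled = 0
    n_residual = 0
    for lm in range(traj.xy.shape[1]):
        for axis in (0, 1):
            series = traj.xy[:, lm, axis]
            was_missing = np.isnan(series)
            filled, still = interpolate_gaps(series, cfg)
            n_filled += int(was_missing.sum() - still.sum())
            n_residual += int(still.sum())
            out.xy[:, lm, axis] = smooth(filled, cfg)
    # filled/residual counted per coordinate axis; halve to per-keypoint
    stats = {"samples_filled": n_filled // 2, "samples_missing": n_residual // 2}
    return out, stats
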