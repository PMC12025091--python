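"""End-to-end orchestration: load -> preprocess -> events -> kinematics ->
spatiotemporal -> agreement, with logged counts and reproducible outputs.

A run is driven by a :class:`RunConfig`; the config used is written
verbatim into the output directory together with a manifest of per-stage
counts, so a run can be audited and repeated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import gait_events, kinematics, preprocess, spatiotemporal
from .keypoint_io import KeypointTrajectorySet, read_openpose_dir
from .synthetic_gait import preset_params, simulate_trial

log = logging.getLogger("gaitkin")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    input_dir: str | None = None
    output_dir: str = "gaitkin_out"
    fps: float = 25.0
    plane: str = "sagittal"
    image_width: int = 640
    image_height: int = 480
    tape_pixels: float = 570.0
    tape_meters: float = 6.0
    conf_min: float = 0.30
    # preprocess
    max_gap_ms: float = 300.0
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    apply_filter: bool = True
    # events
    events_method: str = "coordinate"
    # spatiotemporal
    stride_mode: str = "step_sum"
    # agreement
    n_boot: int = 1000
    ccc_lag_mode: str = "zero"
    tukey_multiplier: float = 1.8
    seed: int = 0
    # synthetic input (used when input_dir is None)
    preset: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class TrialResult:
    """Outputs of one processed trial."""

    traj: KeypointTrajectorySet
    events: dict  # side -> GaitEvents
    angle_series: list
    curves: dict  # key -> CycleCurve
    roms: dict  # key -> RomValue
    params: spatiotemporal.SpatioTemporalParams
    manifest: dict = field(default_factory=dict)


def _load_input(cfg: RunConfig) -> KeypointTrajectorySet:
    if cfg.input_dir is not None:
        path = Path(cfg.input_dir)
        if not path.is_dir():
            raise FileNotFoundError(f"input directory not found: {path}")
        return read_openpose_dir(
            path, fps=cfg.fps, plane=cfg.plane,
            image_size=(cfg.image_width, cfg.image_height),
            conf_min=cfg.conf_min,
        )
    params = preset_params(cfg.preset or "sagittal-normal", seed=cfg.seed)
    traj, _ = simulate_trial(params)
    return traj


def process_trial(
    traj: KeypointTrajectorySet, cfg: RunConfig
) -> TrialResult:
    """Run the sagittal analysis chain on one loaded trajectory set."""
    manifest: dict = {"n_frames": traj.n_frames, "errors": []}

    pcfg = preprocess.PreprocessConfig(
        fps=traj.fps, max_gap_ms=cfg.max_gap_ms,
        filter_cutoff_hz=cfg.filter_cutoff_hz,
        filter_order=cfg.filter_order, apply_filter=cfg.apply_filter,
    )
    clean, stats = preprocess.preprocess_trajectories(traj, pcfg)
    manifest.update(stats)
    log.info("preprocess: %s", stats)

    direction = gait_events.walking_direction(clean)
    manifest["direction"] = direction
    events = {
        side: gait_events.detect_events(
            clean, side, direction=direction, method=cfg.events_method
        )
        for side in ("right", "left")
    }
    manifest["n_heel_strikes"] = {
        s: int(len(e.heel_strikes)) for s, e in events.items()
    }

    angle_series = kinematics.compute_angles(clean, direction)
    curves: dict = {}
    roms: dict = {}
    retained = discarded = 0
    for s in angle_series:
        if s.side not in events:
            continue
        try:
            curve = kinematics.time_normalize(
                s, events[s.side].heel_strikes
            )
        except kinematics.EmptyCurveError as exc:
            manifest["errors"].append(str(exc))
            continue
        curves[s.key] = curve
        roms[s.key] = kinematics.rom(curve)
        retained += curve.n_cycles_averaged
        discarded += curve.n_cycles_discarded
    manifest["cycles_retained"] = retained
    manifest["cycles_discarded"] = discarded

    scale = spatiotemporal.scale_from_tape(cfg.tape_pixels, cfg.tape_meters)
    params = spatiotemporal.spatiotemporal_summary(
        clean, events["right"], events["left"], scale,
        stride_mode=cfg.stride_mode,
    )
    return TrialResult(
        traj=clean, events=events, angle_series=angle_series,
        curves=curves, roms=roms, params=params, manifest=manifest,
    )


def write_trial_outputs(result: TrialResult, cfg: RunConfig) -> Path:
    """Write angle, curve, ROM, event and parameter tables plus manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    angles = pd.DataFrame(
        {s.key: s.values for s in result.angle_series},
    )
    angles.insert(0, "time_s", result.angle_series[0].times)
    angles.to_csv(out / "angles.csv", index=False)

    if result.curves:
        cyc = pd.DataFrame({k: c.samples for k, c in result.curves.items()})
        cyc.insert(0, "pct_cycle", np.linspace(0, 100, kinematics.N_CYCLE_SAMPLES))
        cyc.to_csv(out / "cycle_curves.csv", index=False)

    pd.DataFrame(
        [
            {"joint": r.joint, "side": r.side, "plane": r.plane,
             "rom_deg": r.rom_deg, "n_cycles": len(r.per_cycle_roms)}
            for r in result.roms.values()
        ]
    ).to_csv(out / "rom.csv", index=False)

    gait_events.events_table(
        list(result.events.values()), result.traj.fps
    ).to_csv(out / "events.csv", index=False)
    result.params.to_frame().to_csv(out / "spatiotemporal.csv", index=False)

    (out / "config.yaml").write_text(cfg.to_yaml())
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str)
    )
    return out


def run_trial(cfg: RunConfig) -> TrialResult:
    """Load (or simulate) one trial, process it, and write its outputs."""
    traj = _load_input(cfg)
    result = process_trial(traj, cfg)
    write_trial_outputs(result, cfg)
    return result


def run_validation_study(
    paired_values: pd.DataFrame,
    cfg: RunConfig,
    paired_curves: dict | None = None,
    group_col: str | None = None,
) -> dict[str, agr.AgreementReport]:
    """Agreement reports from a paired-values table.

    ``paired_values`` columns: subject_id, variable, pose_value, ref_value
    (plus an optional group column).  Returns reports keyed by group name
    ("all" for the pooled report); each is also written as delimited files
    under the output directory.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups: dict[str, pd.DataFrame] = {"all": paired_values}
    if group_col is not None and group_col in paired_values:
        for name, sub in paired_values.groupby(group_col):
            groups[str(name)] = sub

    reports = {}
    for name, df in groups.items():
        variables = []
        for var, sub in df.groupby("variable"):
            sub = sub.dropna(subset=["pose_value", "ref_value"])
            if len(sub) < 3:
                log.warning("skipping %s/%s: %d paired subjects", name, var,
                            len(sub))
                continue
            variables.append(
                agr.PairedMeasurements(
                    variable_name=str(var),
                    units="",
                    pose_values=sub["pose_value"].to_numpy(),
                    ref_values=sub["ref_value"].to_numpy(),
                    subject_ids=list(sub["subject_id"]),
                )
            )
        report = agr.agreement_report(
            variables,
            curve_pairs=paired_curves if name == "all" else None,
            n_boot=cfg.n_boot, seed=cfg.seed,
            ccc_lag_mode=cfg.ccc_lag_mode,
            tukey_multiplier=cfg.tukey_multiplier,
        )
        reports[name] = report
        report.variables.to_csv(out / f"agreement_{name}.csv", index=False)
        if len(report.curves):
            report.curves.to_csv(out / f"ccc_{name}.csv", index=False)
        if len(report.outlier_screen):
            report.outlier_screen.to_csv(
                out / f"outlier_screen_{name}.csv", index=False
            )
    (out / "config.yaml").write_text(cfg.to_yaml())
    return reports
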