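# Methods

This document defines the measurement model, every convention the code
relies on, the simulator design, and the numerical choices. All angles are
in degrees, distances in meters (or pixels where stated), time in seconds.

## Coordinate conventions

OpenPose emits image coordinates with y pointing down. On load, y is
flipped (`y_up = H − y_raw`) so the plane is a conventional right-handed
frame and "angle relative to the horizontal" has its ordinary geometric
meaning. A keypoint is *missing* when OpenPose writes the (0, 0, 0)
sentinel, when its confidence is below `conf_min` (default 0.30), or when
no person is detected in the frame. Walking direction `d ∈ {+1, −1}` is
the sign of the net mid-hip x displacement.

### Person selection

Frames may contain several detections. Within a frame candidates are
ranked by summed keypoint confidence; across frames the candidate whose
mid-hip lies nearest the previously selected mid-hip wins, with confidence
breaking near ties (within 20 px). This is a greedy single-target tracker,
adequate for a single-subject walkway recording.

## Preprocessing

- **Gap interpolation.** Missing runs strictly shorter than 300 ms
  (`run_frames · 1000 / fps < 300`) are filled linearly between the
  flanking observed samples. Runs touching a series boundary have no
  anchor on one side and are never filled. At 25 fps this fills a 7-frame
  (280 ms) gap and leaves an 8-frame (320 ms) gap missing.
- **Smoothing.** Zero-phase (forward–backward) 4th-order Butterworth
  low-pass at 6 Hz, applied per contiguous observed segment
  (`scipy.signal.sosfiltfilt`; second-order sections for numerical
  stability). Segments shorter than 3·(2·order + 1) samples are left
  unfiltered rather than padded artificially. Zero-phase filtering
  preserves event timing; the 6 Hz cutoff retains gait harmonics
  (stride rates are ≈ 0.8–1 Hz) while suppressing pose jitter.

## Joint and segment angles

`signed_angle(u, v)` is the rotation from u to v, positive
counterclockwise, wrapped to (−180°, 180°]. With `d` the walking
direction:

| angle | definition |
|---|---|
| hip FE | `d · signed(trunk_dir, thigh_dir)`, trunk_dir = MidHip→Neck reversed (MidHip − Neck points down the trunk), thigh_dir = Hip→Knee; flexion positive |
| knee FE | `−d · signed(thigh_dir, shank_dir)`, shank_dir = Knee→Ankle; flexion positive |
| ankle FE | `wrap(d · signed(shank_dir, foot_dir)) − 90°`, foot_dir = Heel→SmallToe; 0° = plantigrade, dorsiflexion positive |
| shoulder / pelvic obliquity | angle of the shoulder / hip line to the horizontal, folded to (−90°, 90°] |
| hip AA (frontal) | signed angle between the downward pelvis normal and the thigh, mirrored so abduction is positive on both sides |

The frontal-plane pelvis normal is the hip-line direction rotated −90°
((x, y) → (y, −x)), which points downward for a left-to-right hip line.

### Cycle normalization and ROM

Each ipsilateral heel-strike-to-heel-strike interval is one gait cycle.
The angle series is linearly resampled onto 101 points (0–100 %). Cycles
containing any residual missing sample are discarded and counted. ROM is
the per-cycle max − min excursion, averaged across retained cycles.

## Gait events

Coordinate-based detection: relative to the mid-hip, the foot is farthest
forward at heel strike and farthest backward at toe off, so

- heel strikes = local maxima of `d · (x_heel − x_midhip)`
- toe offs = local minima of `d · (x_bigtoe − x_midhip)`

Peak finding is initialized with a stride-period estimate from the
dominant periodogram frequency of the relative-position signal in the
0.3–3 Hz band. Guards: minimum inter-event spacing of 0.4 stride periods,
minimum prominence of 0.2 × the signal's peak-to-peak range, and events
within half a stride of either series boundary are dropped (boundary
extrema are unreliable). If more than half the heel samples are missing,
the ankle substitutes for the heel. A velocity-based variant (sign changes
of relative foot velocity) is selectable.

## Spatiotemporal parameters

Spatial calibration is a single scale factor from a tape mark of known
physical length on the walkway: `m_per_px = tape_meters / tape_pixels`.
This assumes motion in a plane parallel to the image sensor (no
perspective correction).

- **Step length**: |x ankle left − x ankle right| · m_per_px at each heel
  strike.
- **Stride length**: sum of the two step lengths within one cycle
  (default), or the ipsilateral ankle displacement over the cycle
  (`stride_mode="displacement"`).
- **Cadence**: 60 / mean interval between contralateral heel strikes
  (steps/min); also reported as strides/min = 60 / cycle duration.
- **Gait speed**: mid-hip displacement over the span of complete cycles,
  divided by the elapsed time.
- **Stance %**: (toe off − heel strike) / cycle duration; swing is the
  complement.
- **Double support %**: (contralateral TO − HS) + (ipsilateral TO −
  contralateral HS), as a fraction of the cycle.
- **Step width**: frontal-plane lateral ankle separation averaged over
  double-support frames.

Temporal quantities depend only on event times, never on the scale
factor; this invariance is tested.

## Agreement statistics

For paired per-subject measurements (pose method vs reference method):

- **MAE**: mean |pose − ref|, with SD (ddof = 1) and max.
- **ICC(A,k)**: two-way model, absolute agreement, average measures.
  From the two-way ANOVA mean squares (rows = subjects, columns = k
  methods): `ICC = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)`. Estimates
  are reported untruncated (they can be negative, and the estimator is a
  ratio that is heavy-tailed when the true ICC is near 0). Requires
  n ≥ 3 and non-zero variance.
- **Bootstrap CI**: subjects resampled with replacement (default
  B = 1000); percentile 2.5/97.5 bounds. Degenerate resamples (zero
  variance) are skipped and counted. Deterministic given a seed.
- **Reliability levels**: ICC < 0.5 poor, [0.5, 0.75) moderate,
  [0.75, 0.9) good, ≥ 0.9 excellent.
- **CCC**: normalized cross-correlation of two 101-point cycle curves.
  At zero lag (default) it equals their Pearson correlation. `max` mode
  reports the maximum over circular lags within ±10 samples and the lag
  at which it occurs (the roll applied to the second curve). Levels on
  |CCC|: < 0.3 weak, [0.3, 0.7] moderate, > 0.7 strong.
- **Tukey screen**: values outside [Q1 − m·IQR, Q3 + m·IQR] are flagged;
  m = 1.8 by default (m = 1.5 classical, selectable). Quartiles use
  linear interpolation between order statistics (`np.percentile`
  default). The combined report screens per-subject absolute errors and
  emits the ICC with and without flagged subjects.

## Synthetic gait simulator

### Model

The simulator is an exact-ground-truth test harness, not a physiological
model. Joint waveforms are low-order harmonics of the stride phase
φ = t/T (T = 120 / cadence_steps_min; the left leg runs at φ + 0.5):

- hip FE = offset + amp · sin(2πφ + ψ₁)
- knee FE = c₀ + c₁(1 − cos 2πφ) + c₂(1 − cos(4πφ + ψ₂))
- ankle FE = a · sin(2πφ + ψ₃)

chosen so ROMs and peak locations have closed forms (hip and ankle ROM =
2 × amplitude). Forward kinematics places all 25 BODY_25 landmarks using
exactly the inverse of the angle conventions above, so the noiseless
round trip is limited only by floating-point error (≈ 1e−13°, enforced
< 0.5° end-to-end through event detection and resampling).

The pelvis translates at constant `walk_speed`; there is no
ground-contact constraint. To keep the generated trials self-consistent
(gait speed ≈ cadence/60 × step length, a relation the analysis code is
entitled to find in real walking), `simulate_trial` first *calibrates*
the hip amplitude by bisection so the inter-ankle gap at heel strike
equals `walk_speed · T / 2`. Calibration is skipped when disabled, when
the hip amplitude is zero, or when the target is unreachable within the
search bracket.

### Ground truth

True events come from the same geometric definitions as the detector,
evaluated on a 1 kHz noiseless fine grid (so truth is not quantized to
the video frame rate). True spatiotemporal values use the geometric
ankle gap at those events; true ROMs are closed-form where possible and
otherwise evaluated on a dense phase grid.

### Degradation model

Observed keypoints receive isotropic Gaussian pixel noise
(`noise_sigma_px`, default 2.0) and i.i.d. Bernoulli dropout
(`dropout_prob`, default 0.02; dropped keypoints get the OpenPose zero
sentinel and zero confidence). Observed confidences are Uniform(0.6, 1.0).
Written JSON rounds coordinates to 3 decimals.

### What it does not emulate

Musculoskeletal dynamics, ground-reaction forces, perspective projection
or lens distortion (single static scale), occlusion-correlated dropout,
multi-person scenes, or out-of-plane motion.

### Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| fps | 25 | Hz | consumer video rate |
| image size | 640 × 480 | px | consumer video resolution |
| duration_s | 7 | s | a few meters of walkway at self-selected pace |
| walk_speed | 0.9 | m/s | self-selected pediatric pace |
| cadence_steps_min | 112 | steps/min | matches the speed above at ~0.48 m steps |
| scale_px_per_m | 95 | px/m | ~6 m walkway spanning the frame |
| trunk/thigh/shank/foot length | 0.45 / 0.32 / 0.31 / 0.18 | m | pediatric segment lengths |
| hip_amp / knee c₀,c₁,c₂ / ankle_amp | 18 / 4, 18, 10 / 10 | deg | ROMs in normal sagittal ranges (hip ≈ 36°, knee ≈ 50–60°, ankle ≈ 20°) before step calibration |
| noise_sigma_px | 2.0 | px | typical pose-estimation jitter at this resolution |
| dropout_prob | 0.02 | — | occasional missed detections |
| conf range | 0.6–1.0 | — | confidences of accepted detections |

Presets (`sagittal-normal`, `slow-short-stride`, `hemiplegia-right/left`,
`spastic-paraparesis`) override speed, cadence, and per-side ROM scaling
to approximate gross clinical patterns; `gaitkin simulate --preset …`
exposes them, and `preset_yaml()` serializes the table.

### Paired-study generator

`simulate_paired_study` draws subject truths ~ N(μ, σ_b²) and per-method
observations truth + bias + N(0, σ_e²), returning the closed-form
population ICC(A,2) implied by the components:
`σ_b² / (σ_b² + (bias²/2 + σ̄_e²)/2)`. With σ_b = 10, σ_e = 3/3 and no
bias this is 100/104.5 ≈ 0.957; the estimator's 500-replicate mean falls
within 0.02 of it, and the bootstrap CI covers it in ≥ 90 % of replicates.

## Numerical choices

- Trajectory CSVs are written with `%.17g` and read with round-trip float
  parsing, so save/load is bit-exact on observed values.
- Filtering uses second-order sections (`sosfiltfilt`) for stability at
  order 4.
- The ICC bootstrap is vectorized over all resamples at once (mean-square
  algebra on an (B, n, 2) array), making B = 1000 effectively free.
- All randomness flows through `numpy.random.default_rng(seed)`; a
  pipeline run writes its config verbatim and re-runs bit-identically.
- Percentiles (quartiles, bootstrap CI bounds) use NumPy's default linear
  interpolation.

## Limitations

- 2D single-camera analysis: angles are projections; out-of-plane motion
  biases them.
- One global pixel scale: valid only while the subject stays near the
  calibrated plane.
- The coordinate-based event method assumes roughly steady-state walking
  across the field of view; it needs at least two clean heel strikes per
  side after boundary trimming.
- ICC estimates on small samples are noisy and can fall below 0; report
  the bootstrap CI, not the point estimate alone.
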