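"""Method-agreement statistics for markerless-vs-reference validation.

Given paired per-subject measurements from the markerless pipeline and a
reference motion-capture system, this module computes:

* absolute error per pair and its mean +/- SD and maximum (MAE summary);
* the intraclass correlation ICC(A,k) — two-way model, absolute agreement,
  average of k=2 measurements (McGraw & Wong), from the two-way ANOVA mean
  squares, with a nonparametric subject-level bootstrap percentile CI;
* the cross-correlation coefficient (CCC) between paired
  gait-cycle-normalized angle curves — at zero lag this is exactly the
  product-moment correlation of the two curves; a max-lag mode searches
  circular shifts within +/-10 samples;
* qualitative level labels (reliability bands 0.5 / 0.75 / 0.9 for ICC,
  coupling bands 0.3 / 0.7 for |CCC|);
* a Tukey interquartile-range outlier screen with multiplier 1.8 (the
  classical 1.5 is selectable), quartiles by linear interpolation between
  order statistics.

Negative ICC estimates are reported as computed (not truncated) and
labeled "poor".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_TUKEY_MULTIPLIER = 1.8
DEFAULT_N_BOOT = 1000
MAX_LAG = 10


@dataclass
class PairedMeasurements:
    """Per-subject values of one variable from two measurement systems."""

    variable_name: str
    units: str
    pose_values: np.ndarray
    ref_values: np.ndarray
    subject_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.pose_values = np.asarray(self.pose_values, dtype=float)
        self.ref_values = np.asarray(self.ref_values, dtype=float)
        if self.pose_values.shape != self.ref_values.shape:
            raise ValueError("pose and reference value arrays differ in length")
        if len(self.pose_values) < 2:
            raise ValueError("need at least 2 paired subjects")
        if self.subject_ids is None:
            self.subject_ids = list(range(len(self.pose_values)))

    @property
    def n(self) -> int:
        return len(self.pose_values)

    @property
    def matrix(self) -> np.ndarray:
        """(n, 2) matrix, columns = (reference, pose)."""
        return np.column_stack([self.ref_values, self.pose_values])


@dataclass
class IccResult:
    icc: float
    level: str
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    seed: Optional[int] = None
    n_degenerate: int = 0


@dataclass
class CccResult:
    ccc: float
    level: str
    lag_mode: str = "zero"
    lag: int = 0


# ---------------------------------------------------------------------------
# Absolute error


def absolute_error(mc: float, pe: float) -> float:
    """|motion capture - pose estimation| for one paired value."""
    return abs(mc - pe)


def mae(pairs: PairedMeasurements) -> dict:
    """MAE summary: mean, SD (ddof=1) and max of per-pair absolute errors."""
    ae = np.abs(pairs.ref_values - pairs.pose_values)
    return {
        "mean": float(np.mean(ae)),
        "sd": float(np.std(ae, ddof=1)) if len(ae) > 1 else 0.0,
        "max": float(np.max(ae)),
    }


# ---------------------------------------------------------------------------
# Level classifiers


def icc_level(icc: float) -> str:
    """Reliability band: <0.5 poor, [0.5,0.75) moderate, [0.75,0.9) good,
    >=0.9 excellent."""
    if np.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def ccc_level(ccc: float) -> str:
    """Coupling band on |ccc|: <0.3 weak, [0.3,0.7] moderate, >0.7 strong."""
    a = abs(ccc)
    if np.isnan(a):
        return "undefined"
    if a < 0.3:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# ICC(A,k)


def _icc_a_k_matrix(x: np.ndarray) -> np.ndarray:
    """ICC(A,k) for matrices of shape (..., n, k) from ANOVA mean squares.

    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    rows = x.mean(axis=-1, keepdims=True)
    cols = x.mean(axis=-2, keepdims=True)
    msr = k * ((rows - grand) ** 2).sum(axis=(-2, -1)) / (n - 1)
    msc = n * ((cols - grand) ** 2).sum(axis=(-2, -1)) / (k - 1)
    mse = ((x - rows - cols + grand) ** 2).sum(axis=(-2, -1)) / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom == 0, np.nan, (msr - mse) / denom)


def icc_a_k(pairs: PairedMeasurements) -> IccResult:
    """Point estimate of ICC(A,2) between the two measurement systems.

    Raises
    ------
    ValueError
        If fewer than 3 subjects, or the data carry zero total variance.
    """
    if pairs.n < 3:
        raise ValueError(f"ICC needs >= 3 subjects, got {pairs.n}")
    x = pairs.matrix
    if np.ptp(x) == 0:
        raise ValueError("zero total variance: ICC undefined")
    val = float(_icc_a_k_matrix(x))
    return IccResult(icc=val, level=icc_level(val))


def icc_bootstrap(
    pairs: PairedMeasurements,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> IccResult:
    """ICC(A,2) with a nonparametric percentile 95% CI.

    Subjects are resampled with replacement; resamples with zero variance
    (undefined ICC) are skipped and counted.  Deterministic for fixed seed.
    """
    base = icc_a_k(pairs)
    rng = np.random.default_rng(seed)
    x = pairs.matrix
    idx = rng.integers(0, pairs.n, size=(n_boot, pairs.n))
    samples = x[idx]  # (n_boot, n, 2)
    vals = _icc_a_k_matrix(samples)
    good = vals[~np.isnan(vals)]
    n_degenerate = n_boot - len(good)
    result = IccResult(
        icc=base.icc,
        level=base.level,
        n_boot=n_boot,
        seed=seed,
        n_degenerate=int(n_degenerate),
    )
    if len(good):
        result.ci_low = float(np.percentile(good, 2.5))
        result.ci_high = float(np.percentile(good, 97.5))
    return result


# ---------------------------------------------------------------------------
# Cross-correlation of cycle curves


def ccc(
    curve_a: np.ndarray, curve_b: np.ndarray, lag_mode: str = "zero"
) -> CccResult:
    """Normalized cross-correlation between two equal-length angle curves.

    ``lag_mode="zero"`` (default) evaluates lag 0 only — identical to the
    Pearson correlation of the two curves.  ``lag_mode="max"`` returns the
    maximum over circular lags within +/-10 samples, with the lag at which
    it occurs.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant curve: cross-correlation undefined")
    a0 = (a - a.mean()) / (np.std(a) * len(a))
    b0 = (b - b.mean()) / np.std(b)
    if lag_mode == "zero":
        r = float(np.dot(a0, b0))
        return CccResult(ccc=r, level=ccc_level(r), lag_mode="zero", lag=0)
    if lag_mode == "max":
        lags = range(-MAX_LAG, MAX_LAG + 1)
        vals = [float(np.dot(a0, np.roll(b0, lag))) for lag in lags]
        i = int(np.argmax(vals))
        r, lag = vals[i], list(lags)[i]
        return CccResult(ccc=r, level=ccc_level(r), lag_mode="max", lag=lag)
    raise ValueError(f"unknown lag_mode {lag_mode!r}")


# ---------------------------------------------------------------------------
# Tukey outlier screen


def tukey_outliers(
    values: Sequence[float], multiplier: float = DEFAULT_TUKEY_MULTIPLIER
) -> dict:
    """Flag values outside [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use linear interpolation between order statistics.  Returns
    a dict with the fences, quartiles and a boolean flag array.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("Tukey screen needs n >= 4")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    flags = (v < lo) | (v > hi)
    return {
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "lower_fence": float(lo),
        "upper_fence": float(hi),
        "multiplier": multiplier,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# Combined report


@dataclass
class AgreementReport:
    """Per-variable MAE/ICC table and per-curve CCC table."""

    variables: pd.DataFrame
    curves: pd.DataFrame
    outlier_screen: pd.DataFrame = field(default_factory=pd.DataFrame)


def agreement_report(
    variables: list[PairedMeasurements],
    curve_pairs: Optional[dict] = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ccc_lag_mode: str = "zero",
    tukey_multiplier: float = DEFAULT_TUKEY_MULTIPLIER,
    screen_outliers: bool = True,
) -> AgreementReport:
    """Assemble the full validation battery.

    Parameters
    ----------
    variables : paired scalar measurements (one entry per variable).
    curve_pairs : mapping curve-name -> (pose_curve, ref_curve) of
        101-sample cycle curves, or None.
    screen_outliers : when True, each variable with n >= 4 is also
        re-evaluated with Tukey-flagged subjects removed, and both results
        are reported.
    """
    var_rows = []
    screen_rows = []
    for pm in variables:
        summary = mae(pm)
        icc_res = icc_bootstrap(pm, n_boot=n_boot, seed=seed)
        row = {
            "variable": pm.variable_name,
            "units": pm.units,
            "n": pm.n,
            "pose_mean": float(np.mean(pm.pose_values)),
            "pose_sd": float(np.std(pm.pose_values, ddof=1)),
            "ref_mean": float(np.mean(pm.ref_values)),
            "ref_sd": float(np.std(pm.ref_values, ddof=1)),
            "mae_mean": summary["mean"],
            "mae_sd": summary["sd"],
            "mae_max": summary["max"],
            "icc": icc_res.icc,
            "icc_ci_low": icc_res.ci_low,
            "icc_ci_high": icc_res.ci_high,
            "icc_level": icc_res.level,
        }
        var_rows.append(row)
        if screen_outliers and pm.n >= 4:
            # screen on the per-subject absolute errors
            ae = np.abs(pm.ref_values - pm.pose_values)
            screen = tukey_outliers(ae, multiplier=tukey_multiplier)
            flags = screen["flags"]
            entry = {
                "variable": pm.variable_name,
                "n_flagged": int(flags.sum()),
                "flagged_subjects": [
                    s for s, f in zip(pm.subject_ids, flags) if f
                ],
                "icc_all": icc_res.icc,
                "icc_without_outliers": np.nan,
            }
            if 0 < flags.sum() and (~flags).sum() >= 3:
                kept = PairedMeasurements(
                    pm.variable_name,
                    pm.units,
                    pm.pose_values[~flags],
                    pm.ref_values[~flags],
                    [s for s, f in zip(pm.subject_ids, flags) if not f],
                )
                entry["icc_without_outliers"] = icc_a_k(kept).icc
            screen_rows.append(entry)

    curve_rows = []
    for name, (pose_curve, ref_curve) in (curve_pairs or {}).items():
        res = ccc(pose_curve, ref_curve, lag_mode=ccc_lag_mode)
        curve_rows.append(
            {"curve": name, "ccc": res.ccc, "ccc_level": res.level,
             "lag": res.lag, "lag_mode": res.lag_mode}
        )

    return AgreementReport(
        variables=pd.DataFrame(var_rows),
        curves=pd.DataFrame(curve_rows),
        outlier_screen=pd.DataFrame(screen_rows),
    )
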