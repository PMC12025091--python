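"""Agreement battery: MAE, ICC(A,2), bootstrap, CCC, levels, Tukey screen."""

import numpy as np
import pytest

from gaitkin import (
    PairedMeasurements,
    absolute_error,
    agreement_report,
    ccc,
    ccc_level,
    icc_a_k,
    icc_bootstrap,
    icc_level,
    mae,
    simulate_paired_study,
    tukey_outliers,
)
from gaitkin.agreement import _icc_a_k_matrix


# --------------------------------------------------------------------------
# Brute-force oracles (independent, loop-based implementations)


def brute_force_icc_a_k(x):
    """ICC(A,k) via explicit two-way ANOVA sums, scalar loops only."""
    n, k = len(x), len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = sum(
        (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


def brute_force_tukey(values, m):
    """Fences from hand-computed linear-interpolation quartiles."""
    v = sorted(values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(pos)
        frac = pos - lo
        return v[lo] if lo + 1 >= n else v[lo] + frac * (v[lo + 1] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1 - m * iqr, q3 + m * iqr


# --------------------------------------------------------------------------


class TestAbsoluteError:
    def test_example_pair(self):
        assert absolute_error(0.92, 0.76) == pytest.approx(0.16)

    def test_identity_zero(self):
        assert absolute_error(3.3, 3.3) == 0.0

    def test_summary(self):
        pm = PairedMeasurements("v", "", [2.0, 1.0], [1.0, 3.0])
        s = mae(pm)
        assert s["mean"] == 1.5 and s["max"] == 2.0


class TestIcc:
    def test_perfect_agreement_gives_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        pm = PairedMeasurements("v", "", vals, vals.copy())
        assert icc_a_k(pm).icc == pytest.approx(1.0)
        assert icc_a_k(pm).level == "excellent"

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            x = rng.normal(size=(20, 2)) * rng.uniform(0.5, 10) + rng.normal()
            pm = PairedMeasurements("v", "", x[:, 1], x[:, 0])
            assert icc_a_k(pm).icc == pytest.approx(
                brute_force_icc_a_k(x.tolist()), abs=1e-10
            )

    def test_matches_pingouin_icc2k(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        x = rng.normal(50, 10, size=(15, 2))
        x[:, 1] += rng.normal(0, 3, 15)
        pm = PairedMeasurements("v", "", x[:, 1], x[:, 0])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["ref", "pose"], 15),
                "score": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        row = res[res["Type"].isin(["ICC2k", "ICC(A,k)"])]
        icc2k = float(row["ICC"].iloc[0])
        assert icc_a_k(pm).icc == pytest.approx(icc2k, abs=1e-9)

    def test_mean_estimate_near_population_value(self):
        ests = []
        pop = None
        for s in range(500):
            pm, pop = simulate_paired_study(
                20, sigma_between=10, sigma_err_pose=3, sigma_err_ref=3,
                seed=10_000 + s,
            )
            ests.append(icc_a_k(pm).icc)
        assert abs(np.mean(ests) - pop) < 0.02

    def test_zero_between_subject_variance_centers_estimates_at_zero(self):
        # the estimator is a ratio with heavy tails when the true ICC is 0,
        # so the median (not the mean) is the stable location summary
        ests = []
        for s in range(500):
            pm, pop = simulate_paired_study(
                20, sigma_between=0.0, sigma_err_pose=3, sigma_err_ref=3,
                seed=20_000 + s,
            )
            assert pop == 0.0
            ests.append(icc_a_k(pm).icc)
        assert abs(np.median(ests)) < 0.1

    def test_constant_shift_of_both_methods_invariant(self, rng):
        x = rng.normal(size=(12, 2)) * 5
        a = _icc_a_k_matrix(x)
        b = _icc_a_k_matrix(x + 17.3)
        assert b == pytest.approx(a, abs=1e-10)

    def test_widening_method_bias_never_increases_icc(self, rng):
        # absolute agreement penalizes the gap between method means: any
        # offset that widens that gap can only lower the ICC
        for _ in range(30):
            subj = rng.normal(0, 10, size=(12, 1))
            x = subj + rng.normal(0, 2, size=(12, 2))
            base = _icc_a_k_matrix(x)
            gap_sign = np.sign(x[:, 1].mean() - x[:, 0].mean()) or 1.0
            shifted = x.copy()
            shifted[:, 1] += gap_sign * rng.uniform(1, 20)
            assert _icc_a_k_matrix(shifted) <= base + 1e-12

    def test_small_sample_and_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_a_k(PairedMeasurements("v", "", [1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(ValueError):
            icc_a_k(PairedMeasurements("v", "", [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_negative_icc_reported_untruncated(self):
        # near-constant subject means with a large method offset: the
        # subject mean square falls below the error mean square while the
        # method mean square keeps the denominator positive
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pose = np.array([15.2, 14.1, 13.3, 12.0, 11.4])
        res = icc_a_k(PairedMeasurements("v", "", pose, ref))
        assert res.icc < 0
        assert res.level == "poor"


class TestIccBootstrap:
    def test_perfect_agreement_ci_is_unit(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pm = PairedMeasurements("v", "", vals, vals.copy())
        res = icc_bootstrap(pm, n_boot=200, seed=1)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        pm, _ = simulate_paired_study(15, seed=3)
        a = icc_bootstrap(pm, n_boot=300, seed=42)
        b = icc_bootstrap(pm, n_boot=300, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_of_population_icc(self):
        cover = 0
        n_rep = 200
        for s in range(n_rep):
            pm, pop = simulate_paired_study(
                20, sigma_between=10, sigma_err_pose=3, sigma_err_ref=3,
                seed=30_000 + s,
            )
            r = icc_bootstrap(pm, n_boot=1000, seed=s)
            cover += r.ci_low <= pop <= r.ci_high
        assert cover / n_rep >= 0.90

    def test_ci_brackets_point_estimate(self):
        pm, _ = simulate_paired_study(20, seed=9)
        r = icc_bootstrap(pm, n_boot=1000, seed=9)
        assert r.ci_low <= r.icc <= r.ci_high


class TestCcc:
    phases = np.linspace(0.0, 2 * np.pi, 101)

    def test_identical_curves(self):
        c = np.sin(self.phases)
        res = ccc(c, c)
        assert res.ccc == pytest.approx(1.0) and res.level == "strong"

    def test_negated_curve(self):
        c = np.sin(self.phases)
        res = ccc(c, -c)
        assert res.ccc == pytest.approx(-1.0) and res.level == "strong"

    def test_sin_vs_cos_orthogonal(self):
        # one exact period: sample 0..100 of a 100-sample period
        ph = 2 * np.pi * np.arange(100) / 100
        res = ccc(np.sin(ph), np.cos(ph))
        assert abs(res.ccc) < 1e-12 and res.level == "weak"

    def test_zero_lag_equals_pearson(self, rng):
        for _ in range(20):
            a = rng.normal(size=101)
            b = rng.normal(size=101)
            r = np.corrcoef(a, b)[0, 1]
            assert ccc(a, b).ccc == pytest.approx(r, abs=1e-12)

    def test_max_mode_recovers_injected_shift(self):
        ph = 2 * np.pi * np.arange(100) / 100
        a = np.sin(ph)
        b = np.roll(a, 5)
        # brute force over all circular lags
        best = max(range(-10, 11),
                   key=lambda lag: np.corrcoef(a, np.roll(b, lag))[0, 1])
        res = ccc(a, b, lag_mode="max")
        assert res.lag == best == -5 or res.lag == best
        assert res.ccc == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=101)
        b = rng.normal(size=101)
        base = ccc(a, b).ccc
        assert ccc(3.2 * a + 10, b).ccc == pytest.approx(base, abs=1e-12)
        assert ccc(a, 0.5 * b - 4).ccc == pytest.approx(base, abs=1e-12)

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError):
            ccc(np.ones(101), np.sin(self.phases))


class TestLevels:
    @pytest.mark.parametrize(
        "value,expected",
        [(-0.2, "poor"), (0.0, "poor"), (0.49999, "poor"), (0.5, "moderate"),
         (0.74999, "moderate"), (0.75, "good"), (0.89999, "good"),
         (0.9, "excellent"), (1.0, "excellent")],
    )
    def test_icc_reliability_bands(self, value, expected):
        assert icc_level(value) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, "weak"), (0.29999, "weak"), (-0.29999, "weak"),
         (0.3, "moderate"), (-0.3, "moderate"), (0.7, "moderate"),
         (-0.7, "moderate"), (0.70001, "strong"), (-0.9, "strong"),
         (1.0, "strong")],
    )
    def test_ccc_coupling_bands(self, value, expected):
        assert ccc_level(value) == expected


class TestTukey:
    def test_flags_obvious_outlier(self):
        res = tukey_outliers([1, 2, 3, 4, 100], multiplier=1.8)
        assert list(res["flags"]) == [False, False, False, False, True]

    def test_all_equal_none_flagged(self):
        res = tukey_outliers([5.0] * 6)
        assert not res["flags"].any()
        assert res["lower_fence"] == res["upper_fence"] == 5.0

    def test_matches_brute_force_fences(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            v = rng.normal(size=n) * rng.uniform(0.1, 20)
            for m in (1.8, 1.5):
                res = tukey_outliers(v, multiplier=m)
                lo, hi = brute_force_tukey(v.tolist(), m)
                assert res["lower_fence"] == pytest.approx(lo, abs=1e-10)
                assert res["upper_fence"] == pytest.approx(hi, abs=1e-10)
                expected = (v < lo) | (v > hi)
                np.testing.assert_array_equal(res["flags"], expected)

    def test_wider_multiplier_flags_subset(self, rng):
        for _ in range(50):
            v = rng.standard_cauchy(20)
            f18 = set(np.flatnonzero(tukey_outliers(v, 1.8)["flags"]))
            f15 = set(np.flatnonzero(tukey_outliers(v, 1.5)["flags"]))
            assert f18 <= f15

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tukey_outliers([1.0, 2.0, 3.0])


class TestAgreementReport:
    def test_perfect_agreement_report(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        variables = [
            PairedMeasurements("gait_speed", "m/s", vals, vals.copy()),
            PairedMeasurements("cadence", "steps/min", vals * 10, vals * 10),
        ]
        rep = agreement_report(variables, n_boot=100, seed=0)
        assert np.allclose(rep.variables["icc"], 1.0)
        assert (rep.variables["mae_mean"] == 0.0).all()
        assert (rep.variables["icc_level"] == "excellent").all()

    def test_injected_outlier_flagged_with_and_without_iccs(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(50, 10, 12)
        pose = ref + rng.normal(0, 1, 12)
        pose[3] += 60.0  # one aberrant subject
        pm = PairedMeasurements("rom_knee", "deg", pose, ref,
                                subject_ids=list("abcdefghijkl"))
        rep = agreement_report([pm], n_boot=100, seed=0)
        screen = rep.outlier_screen.iloc[0]
        assert "d" in screen["flagged_subjects"]
        assert screen["icc_without_outliers"] > screen["icc_all"]

    def test_curves_section(self):
        ph = np.linspace(0, 2 * np.pi, 101)
        curves = {"knee_FE_right": (np.sin(ph), np.sin(ph) * 1.1 + 2)}
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        rep = agreement_report(
            [PairedMeasurements("v", "", vals, vals + 0.1)],
            curve_pairs=curves, n_boot=50, seed=0,
        )
        assert rep.curves.iloc[0]["ccc"] == pytest.approx(1.0)
        assert rep.curves.iloc[0]["ccc_level"] == "strong"

    def test_every_icc_inside_its_bootstrap_ci(self):
        variables = []
        for i in range(5):
            pm, _ = simulate_paired_study(
                20, sigma_between=10, sigma_err_pose=3, sigma_err_ref=3,
                seed=100 + i, variable_name=f"var{i}",
            )
            variables.append(pm)
        rep = agreement_report(variables, n_boot=300, seed=1)
        ok = (rep.variables["icc_ci_low"] <= rep.variables["icc"]) & (
            rep.variables["icc"] <= rep.variables["icc_ci_high"]
        )
        assert ok.all()
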