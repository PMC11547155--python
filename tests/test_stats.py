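"""Method-comparison statistics against oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attikit.cohort import CohortParams, simulate_pairs, simulate_replicates
from attikit.stats import (
    StatError,
    bin_measurements,
    bland_altman,
    cohen_kappa,
    compare_methods,
    icc_consistency,
    passing_bablok,
    pearson_ci,
    shapiro_wilk,
    spearman_brown,
    ttest_two_sample,
)


class TestShapiroWilk:
    def test_type_i_control_on_normal_cohorts(self):
        ok = 0
        for seed in range(100):
            pairs = simulate_pairs(CohortParams(seed=seed))
            if shapiro_wilk(pairs.mri)[1] > 0.05:
                ok += 1
        assert ok >= 95

    def test_detects_bimodality(self, rng):
        x = np.concatenate([rng.normal(-3, 0.3, 50), rng.normal(3, 0.3, 50)])
        assert shapiro_wilk(x)[1] < 0.01

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(StatError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(StatError):
            shapiro_wilk([1.0] * 10)


class TestTTest:
    def test_identical_groups(self, rng):
        x = rng.normal(size=20)
        res = ttest_two_sample(x, x.copy())
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_summary_form_matches_vector_form(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.3, 1.2, 25)
        v = ttest_two_sample(a, b)
        s = ttest_two_sample(
            (30, a.mean(), a.std(ddof=1)), (25, b.mean(), b.std(ddof=1))
        )
        assert v.t == pytest.approx(s.t, abs=1e-12)
        assert v.p == pytest.approx(s.p, abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        a = rng.normal(0, 1, 18)
        b = rng.normal(0.5, 1, 22)
        ours = ttest_two_sample(a, b)
        ref = sps.ttest_ind(a, b)
        assert ours.t == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_permutation_oracle_small_n(self, rng):
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(0.8, 1.0, 6)
        res = ttest_two_sample(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        reps = 200_000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            if abs(perm[:6].mean() - perm[6:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / reps
        assert res.p == pytest.approx(p_perm, abs=0.04)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatError):
            ttest_two_sample([1.0, 1.0], [1.0, 1.0])


class TestPearson:
    def test_symmetric_interval_at_zero_correlation(self):
        res = pearson_ci(r=0.0, n=50)
        assert res.ci[0] == pytest.approx(-res.ci[1], abs=1e-12)

    def test_collinear_data_degenerate(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.degenerate
        assert res.p == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(StatError):
            pearson_ci(r=0.5, n=3)

    def test_matches_scipy_confidence_interval(self, rng):
        from scipy import stats as sps

        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        ours = pearson_ci(x, y)
        ref = sps.pearsonr(x, y)
        ci = ref.confidence_interval()
        assert ours.r == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.ci[0] == pytest.approx(ci.low, abs=1e-9)
        assert ours.ci[1] == pytest.approx(ci.high, abs=1e-9)


class TestICC:
    def test_identical_columns_give_unity(self, rng):
        x = rng.normal(size=20)
        res = icc_consistency(np.column_stack([x, x]))
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_brute_force_anova_oracle(self, rng):
        table = rng.normal(size=(8, 2))
        n, k = table.shape
        # explicit sums of squares from first principles
        grand = table.mean()
        ss_rows = k * ((table.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((table.mean(axis=0) - grand) ** 2).sum()
        ss_tot = ((table - grand) ** 2).sum()
        msr = ss_rows / (n - 1)
        mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse)
        res = icc_consistency(table)
        assert res.icc_single == pytest.approx(expected, abs=1e-12)

    def test_spearman_brown_identity(self, rng):
        for _ in range(10):
            table = rng.normal(size=(rng.integers(4, 30), rng.integers(2, 5)))
            res = icc_consistency(table)
            assert res.icc_average == pytest.approx(
                spearman_brown(res.icc_single, res.k), abs=1e-12
            )

    def test_two_rater_covariance_identity(self, rng):
        for _ in range(10):
            t = rng.normal(size=(25, 2))
            x, y = t[:, 0], t[:, 1]
            direct = 2 * np.cov(x, y, ddof=1)[0, 1] / (np.var(x, ddof=1) + np.var(y, ddof=1))
            assert icc_consistency(t).icc_single == pytest.approx(direct, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        t = rng.normal(size=(15, 2))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["a", "b"], 15),
                "score": t.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ours = icc_consistency(t)
        by_type = ref.set_index("Type")["ICC"]
        assert ours.icc_single == pytest.approx(by_type["ICC(C,1)"], abs=1e-9)
        assert ours.icc_average == pytest.approx(by_type["ICC(C,k)"], abs=1e-9)

    def test_missing_cells_rejected(self):
        t = np.array([[1.0, 2.0], [np.nan, 1.0], [2.0, 3.0]])
        with pytest.raises(StatError):
            icc_consistency(t)


class TestBlandAltman:
    def test_identical_columns(self, rng):
        x = rng.normal(size=15)
        res = bland_altman(x, x.copy())
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_pure_offset(self, rng):
        x = rng.normal(size=15)
        res = bland_altman(x, x + 0.05)
        assert res.bias == pytest.approx(0.05, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_bias_equals_difference_of_means_exactly(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(0.1, 1.0, 200)
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(y.mean() - x.mean(), abs=1e-14)
        assert res.loa_high - res.loa_low == pytest.approx(3.92 * res.sd_diff, abs=1e-12)

    def test_large_cohort_bias_matches_the_mean_gap(self):
        p = CohortParams(n=200_000, seed=21)
        with pytest.warns(UserWarning):
            pairs = simulate_pairs(p)
        res = bland_altman(pairs.rx, pairs.mri)
        assert res.bias == pytest.approx(p.mean_mri - p.mean_rx, abs=0.001)


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(1.0, 11.0)
        res = passing_bablok(x, x)
        assert res.slope == 1.0
        assert res.intercept == 0.0
        assert res.cusum_p >= 0.99

    def test_exact_affine_line(self):
        x = np.arange(1.0, 13.0)
        res = passing_bablok(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_enumeration_oracle_on_random_data(self, rng):
        x = rng.normal(10, 2, 12)
        y = 1.4 * x + rng.normal(0, 0.8, 12)
        res = passing_bablok(x, y)
        slopes = []
        for i in range(12):
            for j in range(i + 1, 12):
                dx, dy = x[j] - x[i], y[j] - y[i]
                if dx == 0 and dy == 0:
                    continue
                s = np.sign(dy) * np.inf if dx == 0 else dy / dx
                if s != -1.0:
                    slopes.append(s)
        slopes = np.sort(slopes)
        nn = slopes.size
        k = int((slopes < -1).sum())
        if nn % 2:
            expected = slopes[(nn + 1) // 2 + k - 1]
        else:
            expected = 0.5 * (slopes[nn // 2 + k - 1] + slopes[nn // 2 + k])
        assert res.slope == pytest.approx(expected, abs=1e-14)
        assert res.intercept == pytest.approx(np.median(y - expected * x), abs=1e-14)

    def test_exchange_property(self, rng):
        x = rng.normal(10, 2, 15)
        y = 0.8 * x + rng.normal(0, 0.5, 15)
        assert passing_bablok(x, y).slope == pytest.approx(
            1.0 / passing_bablok(y, x).slope, abs=1e-12
        )

    def test_scale_equivariance(self, rng):
        x = rng.normal(10, 2, 14)
        y = 1.2 * x + rng.normal(0, 0.4, 14)
        base = passing_bablok(x, y).slope
        scaled = passing_bablok(2.0 * x, 3.0 * y).slope
        assert scaled == pytest.approx(1.5 * base, abs=1e-12)

    def test_slope_inside_its_interval(self, rng):
        x = rng.normal(0.17, 0.05, 47)
        y = x + rng.normal(0, 0.02, 47)
        res = passing_bablok(x, y)
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]
        assert res.intercept_ci[0] <= res.intercept <= res.intercept_ci[1]

    def test_constant_x_rejected(self):
        with pytest.raises(StatError):
            passing_bablok(np.ones(12), np.arange(12.0))

    def test_small_n_rejected(self):
        with pytest.raises(StatError, match="n >= 10"):
            passing_bablok(np.arange(5.0), np.arange(5.0))

    def test_cusum_type_i_error_calibrated(self):
        """Rejection rate of the linearity test at alpha = 0.05 across 2,000
        linear (null) cohorts of the study size stays near nominal."""
        rejections = 0
        m = 2000
        for seed in range(m):
            pairs = simulate_pairs(CohortParams(seed=100_000 + seed))
            if passing_bablok(pairs.rx, pairs.mri).cusum_p <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / m <= 0.07


class TestKappaAndBinning:
    def test_perfect_agreement(self):
        a = np.array([1, 2, 3, 1, 2, 3, 2])
        assert cohen_kappa(a, a.copy()).kappa == pytest.approx(1.0)

    def test_hand_computed_confusion_matrix(self):
        # [[10, 5], [5, 10]]: po = 2/3, pe = 1/2 -> kappa = 1/3
        a = [0] * 15 + [1] * 15
        b = [0] * 10 + [1] * 5 + [0] * 5 + [1] * 10
        assert cohen_kappa(a, b).kappa == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_independent_labels_near_zero(self, rng):
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        assert abs(cohen_kappa(a, b).kappa) < 0.05

    def test_matches_sklearn_weighted_variants(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 4, 300)
        b = np.clip(a + rng.integers(-1, 2, 300), 0, 3)
        for w, sk in (("none", None), ("linear", "linear"), ("quadratic", "quadratic")):
            assert cohen_kappa(a, b, weights=w).kappa == pytest.approx(
                cohen_kappa_score(a, b, weights=sk), abs=1e-12
            )

    def test_single_category_rejected(self):
        with pytest.raises(StatError):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_tercile_binning(self):
        out = bin_measurements(np.arange(1.0, 10.0))
        assert list(out) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_threshold_binning(self):
        assert list(bin_measurements(np.array([0.1, 0.2]), [0.15])) == [1, 2]

    def test_nonmonotone_thresholds_rejected(self):
        with pytest.raises(StatError):
            bin_measurements(np.arange(5.0), [0.3, 0.1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=40, unique=True))
    def test_binning_invariant_under_monotone_transform(self, values):
        # integer-spaced values keep the monotone map injective in floats
        values = np.asarray(values, dtype=float) * 0.1
        cuts = np.quantile(values, [1 / 3, 2 / 3])
        cuts = np.unique(cuts)
        before = bin_measurements(values, list(cuts))
        f = lambda v: np.exp(v / 50.0)  # strictly monotone
        after = bin_measurements(f(values), list(f(cuts)))
        assert np.array_equal(before, after)


class TestCompareMethods:
    def test_report_is_structurally_complete(self):
        pairs = simulate_pairs(CohortParams(seed=1))
        report = compare_methods(pairs)
        d = report.to_dict()
        from attikit.io import validate_report

        validate_report(d)
        assert d["n"] == 47
        assert set(d["normality"]) == {"mri", "rx"}

    def test_replicates_produce_observer_kappas(self):
        pairs = simulate_replicates(
            simulate_pairs(CohortParams(seed=2)), observer_noise_sd=0.01, seed=3
        )
        report = compare_methods(pairs)
        assert set(report.kappa) == {
            "inter_observer_mri",
            "inter_observer_rx",
            "intra_observer_mri",
            "intra_observer_rx",
        }

    def test_median_pb_slope_across_simulated_cohorts(self):
        """Monte-Carlo across cohorts at the default moments: the median
        regression slope sits at the marginal-SD ratio (~0.83)."""
        slopes = [
            passing_bablok(p.rx, p.mri).slope
            for p in (simulate_pairs(CohortParams(seed=s)) for s in range(500))
        ]
        assert np.median(slopes) == pytest.approx(0.8333, abs=0.05)

    def test_bias_recovery_under_mean_shift(self):
        shifts = []
        for seed in range(200):
            pairs = simulate_pairs(CohortParams(mean_mri=0.1700 + 0.05, seed=seed))
            shifts.append(bland_altman(pairs.rx, pairs.mri).bias)
        # true bias = (0.22 - 0.1751); MC error of the mean ~ 0.0005
        assert np.mean(shifts) == pytest.approx(0.22 - 0.1751, abs=0.002)
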