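"""ANOVA chain, Tukey letters and log-dose regression against formula oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from hcsneurons.dose_stats import (
    DoseGroupedFeature,
    analyze_all_features,
    bartlett_gate,
    compact_letter_display,
    fit_group_means,
    fit_log_dose_regression,
    load_reference_group_means,
    log_dose_x,
    oneway_anova,
    pearson_dose_correlation,
    reports_to_frames,
    tukey_hsd_letters,
    variance_explained_ratio,
    welch_anova_stat,
)

DOSES = (0.0, 10.0, 50.0, 100.0, 200.0, 1000.0)


def grouped(feature, arrays, doses=None):
    doses = doses or list(range(1, len(arrays) + 1))
    return DoseGroupedFeature(feature, [(d, np.asarray(a, float)) for d, a in zip(doses, arrays)])


class TestBartlettGate:
    def test_equal_variances_homoscedastic(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        data = grouped("f", [base, base + 10, base - 3])
        p, homo = bartlett_gate(data)
        assert homo and p > 0.9

    def test_gross_violation_flagged(self):
        rng = np.random.default_rng(0)
        data = grouped("f", [rng.normal(0, 1, 36), rng.normal(0, 10, 36)])
        _, homo = bartlett_gate(data)
        assert not homo

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        arrays = [rng.normal(0, 1 + 0.2 * i, 5) for i in range(3)]
        data = grouped("f", arrays)
        p, _ = bartlett_gate(data)
        # direct evaluation of Bartlett's statistic
        k = 3
        n = np.array([len(a) for a in arrays])
        s2 = np.array([np.var(a, ddof=1) for a in arrays])
        N = n.sum()
        sp2 = np.sum((n - 1) * s2) / (N - k)
        stat = (N - k) * math.log(sp2) - np.sum((n - 1) * np.log(s2))
        stat /= 1 + (np.sum(1 / (n - 1)) - 1 / (N - k)) / (3 * (k - 1))
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(stat, k - 1), abs=1e-6)

    def test_zero_variance_group_flagged_heteroscedastic(self):
        data = grouped("f", [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        p, homo = bartlett_gate(data)
        assert math.isnan(p) and not homo


class TestAnova:
    def test_identical_means_null(self):
        base = np.array([1.0, -1.0, 0.5, -0.5])
        res = oneway_anova(grouped("f", [base, base, base]), use_welch=False)
        assert res.r_squared == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_perfect_separation_r2_100(self):
        res = oneway_anova(grouped("f", [[0.0, 0.0], [1.0, 1.0]]), use_welch=False)
        assert res.r_squared == pytest.approx(100.0)

    def test_f_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        arrays = [rng.normal(i * 0.5, 1, 36) for i in range(6)]
        res = oneway_anova(grouped("f", arrays), use_welch=False)
        y = np.concatenate(arrays)
        grand = y.mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
        ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
        f_oracle = (ssb / 5) / (ssw / (len(y) - 6))
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-9)
        assert res.r_squared == pytest.approx(100 * ssb / (ssb + ssw), rel=1e-9)

    def test_welch_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        arrays = [rng.normal(i, 1 + i, 20) for i in range(4)]
        f, p = welch_anova_stat(arrays)
        frame = pd.DataFrame(
            {
                "y": np.concatenate(arrays),
                "g": np.repeat(np.arange(4), [len(a) for a in arrays]),
            }
        )
        ref = pingouin.welch_anova(data=frame, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_welch_approaches_standard_when_balanced_equal_variance(self):
        # with identical sample variances Welch's weighted numerator equals
        # the standard F; the denominator's finite-sample correction decays
        # as 1/n, so the two statistics converge for large balanced groups
        rng = np.random.default_rng(13)
        base = rng.normal(0, 1, 500)
        arrays = [base, base + 0.1, base + 0.2]
        std = oneway_anova(grouped("f", arrays), use_welch=False)
        f_w, _ = welch_anova_stat(arrays)
        k, n = 3, 500
        correction = 1 + 2 * (k - 2) / (k**2 - 1) * sum(
            (1 - 1 / k) ** 2 / (n - 1) for _ in range(k)
        )
        assert f_w * correction == pytest.approx(std.f_statistic, rel=1e-9)
        assert f_w == pytest.approx(std.f_statistic, rel=5e-3)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            DoseGroupedFeature("f", [(1.0, np.arange(3.0))])


class TestTukeyLetters:
    def test_all_equal_share_one_letter(self):
        rng = np.random.default_rng(4)
        arrays = [rng.normal(0, 1, 20) for _ in range(4)]
        res = tukey_hsd_letters(grouped("f", arrays))
        assert set(res.letters) == {"A"}

    def test_extreme_group_unique_letter(self):
        rng = np.random.default_rng(5)
        arrays = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(50, 1, 30)]
        res = tukey_hsd_letters(grouped("f", arrays))
        assert res.letters[0] == res.letters[1]
        assert res.letters[2] != res.letters[0]

    @pytest.mark.parametrize("seed", range(8))
    def test_display_consistent_with_decision_matrix(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        arrays = [rng.normal(rng.uniform(0, 4), 1, 15) for _ in range(k)]
        data = grouped("f", arrays)
        res = tukey_hsd_letters(data)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(res.letters[i]) & set(res.letters[j]))
                assert share == bool(res.not_different[i, j]), (i, j, res.letters)

    def test_cld_brute_force_oracle(self):
        # hand-checkable matrix: groups 0-1 alike, 1-2 alike, 0-2 differ
        nd = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=bool)
        letters = compact_letter_display(nd, np.array([0, 1, 2]))
        assert set(letters[0]) & set(letters[1])
        assert set(letters[1]) & set(letters[2])
        assert not (set(letters[0]) & set(letters[2]))


class TestRegression:
    def test_reference_somacount_quadratic(self):
        ref = load_reference_group_means()
        row = ref[ref.feature == "somaCount"].iloc[0]
        means = row[[f"dose_{d:g}" for d in DOSES]].to_numpy(float)
        fit = fit_group_means(np.array(DOSES), means, anova_r2=row.anova_r2)
        assert fit.selected_model == "quadratic"
        a, b, c = fit.quadratic_coef
        assert a == pytest.approx(-35.3, rel=0.02)
        assert b == pytest.approx(80.4, rel=0.02)
        assert c == pytest.approx(219.3, rel=0.02)

    def test_exactly_linear_data(self):
        arrays = [np.full(4, 2.0 * log_dose_x(d)) + [0, 0.001, -0.001, 0] for d in DOSES]
        data = grouped("f", arrays, doses=list(DOSES))
        fit = fit_log_dose_regression(data)
        assert fit.selected_model == "linear"
        assert fit.linear_coef[0] == pytest.approx(2.0, abs=1e-3)
        assert fit.linear_coef[1] == pytest.approx(0.0, abs=1e-3)
        assert fit.variance_explained == pytest.approx(100.0, abs=0.01)

    def test_reference_neuritelength_linear_slope(self):
        ref = load_reference_group_means()
        row = ref[ref.feature == "neuriteLength"].iloc[0]
        means = row[[f"dose_{d:g}" for d in DOSES]].to_numpy(float)
        fit = fit_group_means(np.array(DOSES), means, anova_r2=row.anova_r2)
        assert fit.selected_model == "linear"
        assert fit.linear_coef[0] == pytest.approx(-26100, rel=0.02)

    def test_balanced_raw_equals_group_means_coefficients(self):
        rng = np.random.default_rng(6)
        arrays = [rng.normal(5 - 2 * log_dose_x(d), 1, 36) for d in DOSES]
        data = grouped("f", arrays, doses=list(DOSES))
        raw_fit = fit_log_dose_regression(data)
        mean_fit = fit_group_means(np.array(DOSES), data.group_means())
        assert raw_fit.linear_coef == pytest.approx(mean_fit.linear_coef, rel=1e-9)
        assert raw_fit.quadratic_coef == pytest.approx(mean_fit.quadratic_coef, rel=1e-9)

    def test_quadratic_r2_never_below_linear(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            arrays = [rng.normal(rng.uniform(-2, 2), 1, 10) for _ in DOSES]
            fit = fit_log_dose_regression(grouped("f", arrays, doses=list(DOSES)))
            assert fit.quadratic_r2 >= fit.linear_r2 - 1e-9

    def test_variance_explained_perfect_fit(self):
        arrays = [np.full(5, 3.0 * log_dose_x(d) + 1) for d in DOSES]
        data = grouped("f", arrays, doses=list(DOSES))
        fit = fit_log_dose_regression(data)
        assert variance_explained_ratio(fit, data) == pytest.approx(100.0, abs=1e-6)

    def test_two_distinct_doses_skips_quadratic(self):
        data = grouped("f", [[1.0, 2.0], [3.0, 4.0]], doses=[0.0, 10.0])
        fit = fit_log_dose_regression(data)
        assert fit.selected_model == "linear"


class TestPearson:
    def test_strictly_increasing_is_one(self):
        arrays = [[log_dose_x(d)] * 3 for d in DOSES]
        data = grouped("f", [np.array(a) + [0, 1e-9, -1e-9] for a in arrays], doses=list(DOSES))
        assert pearson_dose_correlation(data) == pytest.approx(1.0, abs=1e-6)

    def test_constant_feature_missing(self):
        data = grouped("f", [[1.0, 1.0], [1.0, 1.0]], doses=[0.0, 10.0])
        assert math.isnan(pearson_dose_correlation(data))

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        arrays = [rng.normal(2 * log_dose_x(d), 1, 12) for d in DOSES]
        data = grouped("f", arrays, doses=list(DOSES))
        x, y = data.flat()
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_dose_correlation(data) == pytest.approx(oracle, abs=1e-12)


class TestWholeTable:
    def test_thirteen_feature_report_shape(self, dose_table):
        trends = {f"f{i}": (lambda x, i=i: (i + 1) * (2 - x)) for i in range(13)}
        table = dose_table(trends, images_per_dose=12, seed=10)
        reports = analyze_all_features(table)
        assert len(reports) == 13
        for rep in reports.values():
            assert rep.regression.selected_model in ("linear", "quadratic")
            assert isinstance(rep.regression.successful, bool)

    def test_pure_quadratic_trend_selects_quadratic(self, dose_table):
        table = dose_table({"q": lambda x: 4 * (x - 1.5) ** 2}, images_per_dose=24,
                           noise_sd=0.5, seed=11)
        reports = analyze_all_features(table)
        assert reports["q"].regression.selected_model == "quadratic"

    def test_report_frames_mirror_reference_table_columns(self, dose_table):
        table = dose_table({"f": lambda x: -x}, images_per_dose=6, seed=12)
        anova_f, reg_f = reports_to_frames(analyze_all_features(table))
        assert {"feature", "anova_r2", "f_statistic", "p_value", "used_welch"} <= set(anova_f.columns)
        assert list(reg_f.columns) == [
            "feature",
            "anova_r2",
            "linear_r2",
            "quadratic_r2",
            "selected_model",
            "variance_explained",
            "successful",
            "equation",
        ]
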