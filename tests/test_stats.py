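"""Cohort statistics against closed-form and library oracles."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from corkscrew.stats import (anova_tukey, group_compare, icc_interrater,
                             multiple_regression, partial_corr,
                             quadratic_fit)


class TestGroupCompare:
    def make_table(self, rng, shift=0.0, n=30):
        rows = []
        for g, mu in (("young", 0.0), ("old", shift)):
            for _ in range(n):
                rows.append({"group": g, "v1": rng.normal(mu, 1),
                             "v2": rng.normal(0, 1),
                             "flag": bool(rng.random() < 0.2)})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        table = self.make_table(rng, shift=0.0)
        out = group_compare(table, "group", ["v1", "v2"],
                            categorical_cols=["flag"])
        cont = out[out.test != "fisher-exact"]
        assert not cont.significant.any()

    def test_separated_groups_detected_at_bonferroni_level(self):
        rng = np.random.default_rng(1)
        table = self.make_table(rng, shift=3.0)
        out = group_compare(table, "group", ["v1", "v2", "v3", "v4"]
                            if False else ["v1", "v2"], n_tests=4)
        row = out[out.variable == "v1"].iloc[0]
        assert row.threshold == pytest.approx(0.0125)
        assert row.significant

    def test_bonferroni_threshold_for_four_tests(self):
        rng = np.random.default_rng(2)
        table = self.make_table(rng)
        table["v3"] = rng.normal(size=len(table))
        table["v4"] = rng.normal(size=len(table))
        out = group_compare(table, "group", ["v1", "v2", "v3", "v4"])
        assert np.allclose(out[out.test != "fisher-exact"].threshold,
                           0.05 / 4)

    def test_degenerate_variance_does_not_crash(self):
        table = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5,
                              "v": [1.0] * 10})
        out = group_compare(table, "group", ["v"])
        assert out.p.iloc[0] == 1.0 and not out.significant.iloc[0]

    def test_nonnormal_data_uses_rank_test(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "group": ["a"] * 40 + ["b"] * 40,
            "v": np.concatenate([rng.lognormal(0, 2, 40),
                                 rng.lognormal(0, 2, 40)]),
        })
        out = group_compare(table, "group", ["v"])
        assert out.test.iloc[0] == "kruskal-wallis"


class TestAnovaTukey:
    def test_constant_groups_handled(self):
        table = pd.DataFrame({"g": list("aabbcc"), "v": [2.0] * 6})
        out = anova_tukey(table, "g", "v")
        assert np.isnan(out["F"]) and out["p"] == 1.0
        assert not out["pairwise"].reject.any()

    def test_two_group_tukey_equals_ttest(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({
            "g": ["a"] * 25 + ["b"] * 25,
            "v": np.concatenate([rng.normal(0, 1, 25),
                                 rng.normal(0.8, 1, 25)]),
        })
        out = anova_tukey(table, "g", "v")
        t_p = sps.ttest_ind(table.v[table.g == "a"],
                            table.v[table.g == "b"]).pvalue
        assert float(out["pairwise"].p_adj.iloc[0]) == pytest.approx(
            t_p, abs=1e-3)
        assert out["p"] == pytest.approx(t_p, abs=1e-10)

    def test_age_decade_differences_under_generator(self):
        """Counts drawn from the quadratic age law separate the fifties
        decade from the twenties."""
        from corkscrew.phantom import generate_cohort
        table = generate_cohort(400, seed=9)
        table["decade"] = pd.cut(table.age_years, [20, 30, 40, 50, 60, 70],
                                 labels=["21-30", "31-40", "41-50", "51-60",
                                         ">60"])
        out = anova_tukey(table, "decade", "n_tortuous")
        pair = out["pairwise"]
        row = pair[((pair.group1 == "21-30") & (pair.group2 == "51-60")) |
                   ((pair.group1 == "51-60") & (pair.group2 == "21-30"))]
        assert float(row.p_adj.iloc[0]) < 0.05


class TestQuadraticFit:
    def test_exact_on_noise_free_polynomial(self):
        ages = np.linspace(21, 70, 40)
        counts = 0.037 * ages**2 - 1.458 * ages + 35.34
        fit = quadratic_fit(ages, counts)
        assert fit.coefficients["a"] == pytest.approx(0.037, abs=1e-9)
        assert fit.coefficients["b"] == pytest.approx(-1.458, abs=1e-9)
        assert fit.coefficients["c"] == pytest.approx(35.34, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        ages = np.linspace(21, 70, 30)
        fit = quadratic_fit(ages, np.full(30, 7.0))
        assert fit.coefficients["a"] == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients["b"] == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients["c"] == pytest.approx(7.0)

    def test_rank_deficiency_raises(self):
        with pytest.raises(ValueError):
            quadratic_fit(np.full(10, 40.0), np.arange(10.0))


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({"x": rng.normal(size=60)})
        table["y"] = 0.5 * table.x + rng.normal(size=60)
        out = partial_corr(table, "x", "y")
        r, p = sps.pearsonr(table.x, table.y)
        assert out.r == pytest.approx(r, abs=1e-12)
        assert out.p == pytest.approx(p, abs=1e-9)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(80, 4)),
                             columns=["x", "y", "c1", "c2"])
        table["y"] += 0.6 * table.x + 0.4 * table.c1
        ours = partial_corr(table, "x", "y", ["c1", "c2"])
        ref = pg.partial_corr(table, x="x", y="y", covar=["c1", "c2"])
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_mvn_closed_form_from_precision_matrix(self):
        """Partial correlation of a trivariate normal equals
        -P_xy / sqrt(P_xx P_yy) from the precision matrix P."""
        cov = np.array([[1.0, 0.6, 0.4],
                        [0.6, 1.0, 0.5],
                        [0.4, 0.5, 1.0]])
        prec = np.linalg.inv(cov)
        expected = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        rng = np.random.default_rng(7)
        data = rng.multivariate_normal(np.zeros(3), cov, size=20000)
        table = pd.DataFrame(data, columns=["x", "y", "z"])
        out = partial_corr(table, "x", "y", ["z"])
        assert out.r == pytest.approx(expected, abs=0.02)

    def test_y_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"x": rng.normal(size=50),
                              "z": rng.normal(size=50)})
        table["y"] = table.z
        out = partial_corr(table, "x", "y", ["z"])
        assert abs(out.r) < 1e-6

    def test_collinear_covariates_flagged(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({"x": rng.normal(size=40),
                              "y": rng.normal(size=40),
                              "c1": rng.normal(size=40)})
        table["c2"] = 2 * table.c1
        with pytest.warns(UserWarning, match="collinear"):
            out = partial_corr(table, "x", "y", ["c1", "c2"])
        assert out.collinear


class TestMultipleRegression:
    def test_single_predictor_standardized_coeff_is_pearson_r(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame({"x": rng.normal(size=70)})
        table["y"] = 1.5 * table.x + rng.normal(size=70)
        out = multiple_regression(table, "y", ["x"])
        r = sps.pearsonr(table.x, table.y)[0]
        assert out.std_coefficients["x"] == pytest.approx(r, abs=1e-9)

    def test_orthogonal_predictors_coefficients_stable(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(11)
        y = 2 * x1 + 0.5 * x2 + rng.normal(0, 0.3, n)
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        single = multiple_regression(table, "y", ["x1"])
        both = multiple_regression(table, "y", ["x1", "x2"])
        assert both.coefficients["x1"] == pytest.approx(
            single.coefficients["x1"], abs=1e-9)

    def test_age_drives_counts_in_generated_cohort(self):
        from corkscrew.phantom import generate_cohort
        table = generate_cohort(400, seed=12)
        table["sex_num"] = (table.sex == "F").astype(float)
        out = multiple_regression(table, "n_tortuous",
                                  ["age_years", "sex_num", "bmi"])
        assert out.std_coefficients["age_years"] > 0
        assert out.pvalues["age_years"] < 0.001


class TestICC:
    def test_identical_raters_icc_one(self):
        ratings = np.tile(np.arange(10.0), (3, 1)).T
        out = icc_interrater(ratings)
        assert out.icc == pytest.approx(1.0)

    def test_independent_noise_icc_near_zero(self):
        rng = np.random.default_rng(13)
        out = icc_interrater(rng.normal(size=(100, 2)))
        assert abs(out.icc) < 0.1

    def test_variance_ratio_nine_to_one_gives_point_nine(self):
        rng = np.random.default_rng(14)
        truth = rng.normal(0, 3.0, size=400)
        ratings = truth[:, None] + rng.normal(0, 1.0, size=(400, 2))
        out = icc_interrater(ratings)
        assert out.icc == pytest.approx(0.9, abs=0.03)
        assert out.ci95_low <= out.icc <= out.ci95_high

    def test_matches_pingouin_icc2(self):
        rng = np.random.default_rng(15)
        truth = rng.normal(0, 2.0, size=30)
        ratings = truth[:, None] + rng.normal(0, 1.0, size=(30, 3))
        ours = icc_interrater(ratings)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 3),
            "rater": np.tile(np.arange(3), 30),
            "score": ratings.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        ref2 = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert ours.icc == pytest.approx(float(ref2.ICC), abs=1e-6)
        lo, hi = ref2["CI95"]
        assert ours.ci95_low == pytest.approx(lo, abs=0.02)
        assert ours.ci95_high == pytest.approx(hi, abs=0.02)

    def test_zero_variance_and_shape_guards(self):
        out = icc_interrater(np.ones((10, 2)))
        assert out.icc == 0.0
        with pytest.raises(ValueError):
            icc_interrater(np.zeros((3, 2)))
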