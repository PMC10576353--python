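"""Matched-set covariate construction and conditional-logistic inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_pairs
from epimr.nested_case_control import (
    absi,
    assign_quintiles,
    bonferroni,
    clogit_fit,
    covariate_residuals,
    exclude_sets,
    fractional_polynomial_test,
    lrt,
    lrt_from_deviances,
    spearman_partial,
    standardize_by_control_sd,
)


def random_matched_frame(rng, n_pairs, covariates=("x",), beta=None):
    """1:1 sets with outcome drawn from the conditional-logistic model."""
    beta = np.zeros(len(covariates)) if beta is None else np.asarray(beta)
    rows = []
    for i in range(n_pairs):
        xa = rng.normal(0, 1, len(covariates))
        xb = rng.normal(0, 1, len(covariates))
        p_a_case = 1 / (1 + np.exp(-(xa - xb) @ beta))
        case_first = rng.random() < p_a_case
        for member, is_case in ((xa, case_first), (xb, not case_first)):
            row = {"set_id": f"s{i}", "is_case": int(is_case)}
            row.update(dict(zip(covariates, member)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestAbsi:
    def test_direct_arithmetic(self):
        assert absi(89, 75, 167) == pytest.approx(
            890 * 75 ** (-2 / 3) * 1.67 ** (5 / 6), rel=1e-12)
        assert absi(89, 75, 167) == pytest.approx(76.7, abs=0.1)
        assert absi(100, 100, 180) == pytest.approx(75.75, abs=0.05)

    def test_weight_scaling_law(self):
        assert absi(90, 8 * 70, 170) == pytest.approx(absi(90, 70, 170) / 4, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            absi(0, 70, 170)


class TestCovariateResiduals:
    def test_perfect_linear_fit_gives_zero_residuals(self, rng):
        df = pd.DataFrame({
            "sex": ["male"] * 10,
            "bmi": rng.uniform(20, 35, 10),
            "height": rng.uniform(150, 190, 10),
        })
        df["waist"] = 10 + 2.0 * df.bmi + 0.3 * df.height
        res = covariate_residuals(df)
        np.testing.assert_allclose(res.residual, 0.0, atol=1e-9)

    def test_three_point_ols_oracle(self):
        df = pd.DataFrame({
            "sex": ["male"] * 3,
            "bmi": [20.0, 25.0, 30.0],
            "height": [170.0, 170.0, 170.0],
            "waist": [70.0, 80.0, 96.0],
        })
        # constant height: drop it to keep the design full-rank
        res = covariate_residuals(df, predictors=["bmi"])
        coef = np.polyfit([20, 25, 30], [70, 80, 96], 1)
        expected = np.array([70, 80, 96]) - np.polyval(coef, [20, 25, 30])
        np.testing.assert_allclose(res.residual, expected, atol=1e-9)

    def test_missing_waist_gets_sex_specific_median_residual(self, rng):
        n = 20
        df = pd.DataFrame({
            "sex": ["male"] * (n // 2) + ["female"] * (n // 2),
            "bmi": rng.uniform(20, 35, n),
            "height": rng.uniform(150, 190, n),
        })
        df["waist"] = 5 + 2.2 * df.bmi + 0.35 * df.height + rng.normal(0, 3, n)
        df.loc[3, "waist"] = np.nan
        df.loc[15, "waist"] = np.nan
        res = covariate_residuals(df)
        male_med = np.median(res.residual[(df.sex == "male") & df.waist.notna()])
        female_med = np.median(res.residual[(df.sex == "female") & df.waist.notna()])
        assert res.residual[3] == pytest.approx(male_med)
        assert res.residual[15] == pytest.approx(female_med)
        assert res.imputed[3] and res.imputed[15] and not res.imputed[0]

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"sex": ["male"] * 5, "bmi": [25.0] * 5,
                           "height": [170.0] * 5, "waist": [80.0] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            covariate_residuals(df)


class TestQuintiles:
    def make_frame(self, male_vals, female_vals, case_vals=()):
        rows = [{"sex": "male", "is_case": 0, "biomarker": v} for v in male_vals]
        rows += [{"sex": "female", "is_case": 0, "biomarker": v} for v in female_vals]
        rows += [{"sex": "male", "is_case": 1, "biomarker": v} for v in case_vals]
        return pd.DataFrame(rows)

    def test_cutoffs_follow_declared_quantile_rule(self):
        df = self.make_frame(range(1, 11), np.arange(1, 11) * 10.0)
        scheme, assigned = assign_quintiles(df)
        np.testing.assert_allclose(
            scheme.cutoffs["male"], np.quantile(np.arange(1, 11), [0.2, 0.4, 0.6, 0.8]))
        assert scheme.category("male", 10.0) == 5
        # sex-specific: the female scale is 10x the male scale
        assert scheme.category("female", 10.0) == 1

    def test_trend_scores_are_control_quintile_medians(self):
        df = self.make_frame(range(1, 11), np.arange(1, 11) * 10.0)
        scheme, assigned = assign_quintiles(df)
        males = assigned[assigned.sex == "male"]
        for q, grp in males.groupby("quintile"):
            med = np.median(df[(df.sex == "male") & (df.is_case == 0)
                               & (df.biomarker.isin(grp.biomarker))].biomarker)
            assert grp.trend_score.iloc[0] == pytest.approx(
                scheme.medians["male"][q - 1])
        for sex in ("male", "female"):
            cuts = [-np.inf, *scheme.cutoffs[sex], np.inf]
            for q in range(5):
                assert cuts[q] <= scheme.medians[sex][q] <= cuts[q + 1]

    def test_case_below_control_minimum_lands_in_q1(self):
        df = self.make_frame(range(10, 20), range(10, 20), case_vals=[1.0])
        _, assigned = assign_quintiles(df)
        assert assigned.loc[assigned.is_case == 1, "quintile"].iloc[0] == 1

    def test_tied_cutoffs_resolve_downward(self):
        scheme, _ = assign_quintiles(
            self.make_frame([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        scheme.cutoffs["male"] = np.array([7.0, 7.0, 7.0, 7.0])
        assert scheme.category("male", 7.0) == 1
        assert scheme.category("male", 7.1) == 5

    def test_too_few_distinct_controls_rejected(self):
        with pytest.raises(ValueError, match="distinct control"):
            assign_quintiles(self.make_frame([1, 1, 1, 2, 3], range(1, 11)))

    def test_invariant_to_monotone_transform(self, rng):
        vals_m = rng.lognormal(2.5, 0.4, 120)
        vals_f = rng.lognormal(2.9, 0.4, 120)
        df = self.make_frame(vals_m, vals_f, case_vals=rng.lognormal(2.5, 0.5, 40))
        _, a = assign_quintiles(df)
        df2 = df.copy()
        df2["biomarker"] = np.log(df2["biomarker"]) ** 3 + 2  # strictly monotone
        _, b = assign_quintiles(df2)
        assert (a.quintile == b.quintile).all()

    def test_standardize_by_control_sd(self, rng):
        vals = rng.normal(15, 8.9, 500)
        df = self.make_frame(vals[:250], vals[250:])
        scheme, _ = assign_quintiles(df)
        assert scheme.control_sd == pytest.approx(np.std(vals, ddof=1))
        assert standardize_by_control_sd(scheme.control_sd, scheme) == pytest.approx(1.0)
        assert standardize_by_control_sd(0.0, scheme) == 0.0
        scheme.control_sd = 8.9
        assert standardize_by_control_sd(17.8, scheme) == pytest.approx(2.0)


class TestClogitFit:
    def test_closed_form_ln2(self):
        fit = clogit_fit(make_pairs([+1, +1, -1]), ["x"])
        assert fit.coefficients["x"] == pytest.approx(np.log(2), abs=1e-8)
        assert fit.rate_ratio("x")[0] == pytest.approx(2.0, abs=1e-7)
        assert fit.converged and fit.n_sets_informative == 3

    def test_balanced_differences_give_null(self):
        fit = clogit_fit(make_pairs([+1, -1]), ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-10)

    def test_no_informative_sets_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            clogit_fit(make_pairs([0, 0, 0]), ["x"])

    def test_equals_logit_on_pair_differences(self, rng):
        """Dual-route check: the matched-set likelihood maximum must agree with
        statsmodels no-intercept logistic regression on case-minus-control
        differences (an algebraic identity for 1:1 sets)."""
        for rep in range(10):
            df = random_matched_frame(rng, 80, ("x", "z"), beta=[0.5, -0.3])
            fit = clogit_fit(df, ["x", "z"])
            cases = df[df.is_case == 1].set_index("set_id")[["x", "z"]]
            ctrls = df[df.is_case == 0].set_index("set_id")[["x", "z"]]
            diffs = (cases - ctrls).to_numpy()
            sm_fit = sm.Logit(np.ones(len(diffs)), diffs).fit(disp=False)
            np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-6)
            np.testing.assert_allclose(np.sqrt(np.diag(fit.covariance)),
                                       sm_fit.bse, atol=1e-5)

    def test_matches_statsmodels_conditional_logit_on_1_to_2_sets(self, rng):
        """Beyond 1:1: agreement with statsmodels ConditionalLogit."""
        rows = []
        for i in range(60):
            xs = rng.normal(0, 1, 3)
            probs = np.exp(0.7 * xs)
            case = rng.choice(3, p=probs / probs.sum())
            for j, x in enumerate(xs):
                rows.append({"set_id": f"s{i}", "is_case": int(j == case), "x": x})
        df = pd.DataFrame(rows)
        fit = clogit_fit(df, ["x"])
        groups = pd.factorize(df.set_id)[0]
        ref = sm.ConditionalLogit(df.is_case.to_numpy(), df[["x"]].to_numpy(),
                                  groups=groups).fit(disp=False)
        assert fit.coefficients["x"] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_matching_factor_absorption(self, rng):
        """A covariate constant within every set changes nothing — the reason
        conditioning on matched sets absorbs the matching factors."""
        df = random_matched_frame(rng, 100, ("x",), beta=[0.4])
        df["matched_age"] = np.repeat(rng.uniform(40, 70, 100), 2)
        base = clogit_fit(df, ["x"])
        aug = clogit_fit(df, ["x", "matched_age"])
        assert aug.coefficients["x"] == pytest.approx(base.coefficients["x"], abs=1e-5)
        assert aug.log_likelihood == pytest.approx(base.log_likelihood, abs=1e-7)

    def test_separation_is_flagged(self):
        fit = clogit_fit(make_pairs([+1, +1, +1, +1]), ["x"])
        assert fit.separation and not fit.converged


class TestLrt:
    def test_chi_square_tail_values(self):
        assert lrt_from_deviances(203.84, 200.0, 1) == pytest.approx(0.050, abs=5e-4)
        assert lrt_from_deviances(201.0, 200.0, 1) == pytest.approx(0.317, abs=5e-4)

    def test_nested_model_comparison(self, rng):
        df = random_matched_frame(rng, 150, ("x", "z"), beta=[0.6, 0.0])
        full = clogit_fit(df, ["x", "z"])
        reduced = clogit_fit(df, ["x"])
        p = lrt(full, reduced)
        assert 0 <= p <= 1
        # identical deviances give statistic 0, p = 1
        assert lrt_from_deviances(10.0, 10.0, 1) == 1.0

    def test_reduced_better_than_full_rejected(self, rng):
        df = random_matched_frame(rng, 50, ("x", "z"), beta=[0.5, 0.2])
        full = clogit_fit(df, ["x", "z"])
        reduced = clogit_fit(df, ["x"])
        with pytest.raises(ValueError, match="nested|more coefficients"):
            lrt(reduced, full)


class TestFractionalPolynomials:
    def test_deviance_arithmetic(self):
        from scipy import stats
        assert lrt_from_deviances(200.0, 192.0, 3) == pytest.approx(
            stats.chi2.sf(8, 3), rel=1e-12)
        assert lrt_from_deviances(200.0, 192.0, 3) == pytest.approx(0.046, abs=5e-4)

    def test_linear_effect_not_flagged_nonlinear(self, rng):
        rows = []
        for i in range(400):
            xa, xb = rng.lognormal(2.7, 0.5, 2)
            p = 1 / (1 + np.exp(-0.05 * (xa - xb)))
            case_a = rng.random() < p
            rows.append({"set_id": f"s{i}", "is_case": int(case_a), "biomarker": xa})
            rows.append({"set_id": f"s{i}", "is_case": int(not case_a), "biomarker": xb})
        df = pd.DataFrame(rows)
        res = fractional_polynomial_test(df, "biomarker")
        assert res.p_nonlinearity > 0.05
        assert res.ll_fp2 >= res.ll_fp1 >= res.ll_linear - 1e-9

    def test_log_effect_selects_log_power(self, rng):
        """Exposure acting log-linearly: the FP1 scan should prefer power 0."""
        hits = 0
        for rep in range(5):
            rows = []
            for i in range(500):
                xa, xb = rng.lognormal(2.7, 0.7, 2)
                p = 1 / (1 + np.exp(-2.0 * (np.log(xa) - np.log(xb))))
                case_a = rng.random() < p
                rows.append({"set_id": f"s{i}", "is_case": int(case_a), "biomarker": xa})
                rows.append({"set_id": f"s{i}", "is_case": int(not case_a),
                             "biomarker": xb})
            res = fractional_polynomial_test(pd.DataFrame(rows), "biomarker")
            hits += res.fp1_power == 0.0
        assert hits >= 4


class TestSpearmanPartial:
    def test_perfect_monotone_association(self, rng):
        x = rng.uniform(0, 1, 30)
        r, p = spearman_partial(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r, _ = spearman_partial(x, -x)
        assert r == pytest.approx(-1.0)

    def test_no_covariates_matches_scipy_spearman(self, rng):
        from scipy import stats
        x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        r, p = spearman_partial(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)

    def test_matches_pingouin_partial_correlation(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 60
        age = rng.uniform(40, 70, n)
        x = 0.05 * age + rng.normal(0, 1, n)
        y = 0.03 * age + 0.4 * x + rng.normal(0, 1, n)
        r, p = spearman_partial(x, y, covariates=[age])
        df = pd.DataFrame({"x": x, "y": y, "age": age})
        ref = pg.partial_corr(df, x="x", y="y", covar="age", method="spearman")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_partial([1.0] * 10, list(range(10)))


class TestMultiplicityAndExclusions:
    def test_bonferroni_explicit_count(self):
        assert bonferroni(0.001, 28) == pytest.approx(0.028)
        assert bonferroni(0.2, 12) == 1.0

    def test_excluding_a_case_drops_its_whole_set(self):
        df = make_pairs([+1, -1, +2])
        df["early"] = [True, False, False, False, False, False]
        kept = exclude_sets(df, df["early"], drop_if="case")
        assert set(kept.set_id) == {"s1", "s2"}

    def test_any_member_exclusion(self):
        df = make_pairs([+1, -1])
        df["diabetes"] = [False, True, False, False]  # control of s0 flagged
        kept = exclude_sets(df, df["diabetes"], drop_if="any")
        assert set(kept.set_id) == {"s1"}
        # under drop_if='case' the control flag does not drop the set
        kept2 = exclude_sets(df, df["diabetes"], drop_if="case")
        assert set(kept2.set_id) == {"s0", "s1"}
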