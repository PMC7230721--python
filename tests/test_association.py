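import numpy as np
import pandas as pd
import pytest

from calorflex.association import (
    DEFAULT_SEED,
    ModelSpec,
    association_grid,
    descriptives_by_sex,
    fit_model,
    napierian_transform,
    normality_screen,
    phenotype_anova,
    phenotype_comparison_table,
    sex_ttest,
)
from calorflex.errors import DomainError, InsufficientDataError


class TestNormalityScreen:
    def test_normal_draws_pass_mostly(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        hits = sum(normality_screen(rng.normal(0, 1, 60)) for _ in range(100))
        assert hits >= 90

    def test_lognormal_draws_rejected_mostly(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        hits = sum(
            not normality_screen(np.exp(rng.normal(0, 1, 60))) for _ in range(100)
        )
        assert hits >= 90

    def test_constant_is_non_normal(self):
        assert normality_screen(np.full(20, 3.0)) is False

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            normality_screen([1.0, 2.0, 3.0])


class TestNapierianTransform:
    def test_powers_of_e(self):
        out = napierian_transform([1.0, np.e, np.e**2])
        assert out == pytest.approx([0.0, 1.0, 2.0])

    def test_inverse_identity(self, rng):
        x = rng.uniform(0.1, 50, 30)
        assert np.exp(napierian_transform(x)) == pytest.approx(x)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            napierian_transform([1.0, 0.0])


class TestSexTtest:
    def test_identical_groups(self):
        t, df, p = sex_ttest({"male": [1, 2, 3], "female": [1, 2, 3]})
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_hand_value(self):
        # pooled sd = 1, t = -3/sqrt(2/3) = -3.674, df 4
        t, df, p = sex_ttest({"male": [1, 2, 3], "female": [4, 5, 6]})
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-9)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_label_swap_symmetry(self):
        t1, _, p1 = sex_ttest({"male": [1, 2, 3], "female": [4, 5, 6]})
        t2, _, p2 = sex_ttest({"male": [4, 5, 6], "female": [1, 2, 3]})
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestFitModel:
    def test_perfect_fit(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0], "x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        res = fit_model(df, ModelSpec(outcome="y", exposure="x", transform_policy="none"))
        assert res.beta_std == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_hand_normal_equations(self):
        # x=[1,2,3], y=[1,2,4]: R^2=27/28, adj=1-2(1-R^2), F=27, beta=r
        df = pd.DataFrame({"y": [1.0, 2.0, 4.0], "x": [1.0, 2.0, 3.0]})
        res = fit_model(df, ModelSpec(outcome="y", exposure="x", transform_policy="none"))
        r2 = 4.5 / (14 / 3)
        assert res.beta_std == pytest.approx(np.sqrt(r2), rel=1e-9)
        assert res.adj_r2 == pytest.approx(1 - (1 - r2) * 2, rel=1e-9)
        assert res.f_stat == pytest.approx(27.0, rel=1e-9)
        assert res.df1 == 1 and res.df2 == 1

    def test_planted_beta_recovery(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        betas = []
        for _ in range(500):
            x = rng.normal(0, 1, 57)
            z = (x - x.mean()) / x.std(ddof=1)
            y = 0.35 * z + np.sqrt(1 - 0.35**2) * rng.normal(0, 1, 57)
            df = pd.DataFrame({"y": y, "x": x})
            betas.append(
                fit_model(
                    df, ModelSpec(outcome="y", exposure="x", transform_policy="none")
                ).beta_std
            )
        assert abs(np.mean(betas) - 0.35) < 0.05

    def test_model0_f_equals_correlation_t_squared(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.4 * x + rng.normal(0, 1, 40)
        res = fit_model(
            pd.DataFrame({"y": y, "x": x}),
            ModelSpec(outcome="y", exposure="x", transform_policy="none"),
        )
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt((len(x) - 2) / (1 - r**2))
        assert res.f_stat == pytest.approx(t**2, rel=1e-9)

    def test_statsmodels_oracle_with_covariate(self, rng):
        import statsmodels.api as sm

        n = 50
        x = rng.normal(0, 1, n)
        cov = rng.normal(40, 5, n)
        y = 0.3 * x + 0.05 * cov + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x, "age": cov})
        res = fit_model(
            df, ModelSpec(outcome="y", exposure="x", covariate="age", transform_policy="none")
        )
        yz = (y - y.mean()) / y.std(ddof=1)
        xz = (x - x.mean()) / x.std(ddof=1)
        X = sm.add_constant(np.column_stack([xz, cov]))
        fit = sm.OLS(yz, X).fit()
        assert res.beta_std == pytest.approx(fit.params[1], rel=1e-9)
        assert res.f_stat == pytest.approx(fit.tvalues[1] ** 2, rel=1e-9)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-9)
        assert res.adj_r2 == pytest.approx(fit.rsquared_adj, rel=1e-9)
        assert res.df2 == n - 3

    def test_sex_covariate_coding(self, rng):
        n = 40
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        x = rng.normal(0, 1, n)
        y = x * 0.5 + (sex == "male") * 1.0 + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x, "sex": sex})
        res = fit_model(
            df, ModelSpec(outcome="y", exposure="x", covariate="sex", transform_policy="none")
        )
        assert np.isfinite(res.beta_std)
        assert res.df2 == n - 3

    def test_auto_policy_logs_lognormal_outcome(self, rng):
        x = rng.normal(0, 1, 60)
        y = np.exp(1.5 * rng.normal(0, 1, 60))
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_model(df, ModelSpec(outcome="y", exposure="x", transform_policy="auto"))
        assert res.outcome_log_transformed


class TestPhenotypeAnova:
    def test_identical_groups_f_zero(self):
        df = pd.DataFrame(
            {"y": [5.0] * 8, "phenotype": ["MHNW", "MUNW", "MHOO", "MUOO"] * 2}
        )
        f, df1, df2, p = phenotype_anova(df, "y")
        assert f == 0.0
        assert p == 1.0
        assert df1 == 3

    def test_two_group_t_equivalence(self):
        df = pd.DataFrame(
            {"y": [1.0, 2, 3, 4, 5, 6], "phenotype": ["A"] * 3 + ["B"] * 3}
        )
        f, df1, df2, p = phenotype_anova(df, "y")
        assert f == pytest.approx(13.5, rel=1e-9)  # t^2 with t = 3.674
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_orthogonal_covariate_small_change(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        groups = np.repeat(["A", "B", "C", "D"], 25)
        y = rng.normal(0, 1, 100) + (groups == "A") * 1.0
        cov = rng.normal(50, 5, 100)  # independent of groups
        df = pd.DataFrame({"y": y, "phenotype": groups, "age": cov})
        f0, *_ = phenotype_anova(df, "y")
        f1, *_ = phenotype_anova(df, "y", covariate="age")
        assert abs(f1 - f0) / f0 < 0.10

    def test_single_group_raises(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "phenotype": ["A", "A"]})
        with pytest.raises(InsufficientDataError):
            phenotype_anova(df, "y")


class TestCalibration:
    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 57)
            y = rng.normal(0, 1, 57)
            res = fit_model(
                pd.DataFrame({"y": y, "x": x}),
                ModelSpec(outcome="y", exposure="x", transform_policy="none"),
            )
            rejections += res.p_value <= 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07

    def test_planted_negative_effect_sign_recovery(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        negative = 0
        for _ in range(500):
            x = rng.normal(0, 1, 57)
            z = (x - x.mean()) / x.std(ddof=1)
            ln_y = -0.33 * z + np.sqrt(1 - 0.33**2) * rng.normal(0, 1, 57)
            df = pd.DataFrame({"y": np.exp(ln_y), "x": x})
            res = fit_model(df, ModelSpec(outcome="y", exposure="x", transform_policy="auto"))
            negative += res.beta_std < 0
        assert negative / 500 >= 0.95


class TestReportTables:
    def test_empty_cohort_no_crash(self):
        df = pd.DataFrame({"sex": [], "y": [], "x": []})
        desc = descriptives_by_sex(df, ["y"])
        assert len(desc) == 1
        grid = association_grid(df, ["x"], ["y"], transform_policy="none")
        assert grid["n"].eq(0).all()

    def test_grid_shape(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "sex": np.where(rng.random(n) < 0.5, "male", "female"),
                "age": rng.normal(53, 5, n),
                "lean_mass": rng.normal(45, 8, n),
                "exp1": rng.normal(0, 1, n),
                "out1": rng.normal(0, 1, n),
                "out2": rng.normal(0, 1, n),
            }
        )
        grid = association_grid(df, ["exp1"], ["out1", "out2"], transform_policy="none")
        assert len(grid) == 2 * 4
        assert set(grid["model"]) == {0, 1, 2, 3}

    def test_all_missing_outcome_marked_na(self, rng):
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, 20), "y": [np.nan] * 20, "sex": ["male"] * 20,
             "age": rng.normal(50, 5, 20), "lean_mass": rng.normal(45, 5, 20)}
        )
        grid = association_grid(df, ["x"], ["y"], transform_policy="none")
        assert grid["n"].eq(0).all()
        assert grid["F"].isna().all()

    def test_phenotype_table_shape(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "phenotype": rng.choice(["MHNW", "MUNW", "MHOO", "MUOO"], n),
                "age": rng.normal(53, 5, n),
                "bmr": rng.normal(1300, 300, n),
            }
        )
        table = phenotype_comparison_table(df, ["bmr"])
        assert len(table) == 4
        assert table.loc[table.model == 0, "df1"].iloc[0] == 3
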