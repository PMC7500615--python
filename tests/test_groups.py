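import numpy as np
import pandas as pd
import pytest

from phenopass.groups import (fit_group_lmm, marginal_slopes, overall_year_trend,
                              pairwise_slope_tests, sex_group_analysis)


def make_group_data(seed, group_slopes, n_species=6, years=(2002, 2019),
                    intercept_sd=5.0, noise_sd=3.0, base=110.0):
    """Annual peak dates: species intercepts + group-specific year slopes."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, slope in group_slopes.items():
        for s in range(n_species):
            a = base + rng.normal(0, intercept_sd)
            for y in range(years[0], years[1] + 1):
                rows.append({
                    "species": f"{g}_{s}", "wintering_group": g, "year": y,
                    "value": a + slope * (y - years[0]) + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


def reml_profile_oracle(df, response, group_col="wintering_group",
                        species_col="species", year_center=2002):
    """Independent REML fit by profiling the variance ratio on a grid.

    For the random-intercept model V = sigma2 (I + theta Z Z'), both beta
    and sigma2 profile out in closed form; the restricted log-likelihood
    is maximized by scanning theta.
    """
    from phenopass.groups import _design_matrix
    levels = sorted(df[group_col].unique())
    X = _design_matrix(df, group_col, "year", year_center, levels).to_numpy()
    y = df[response].to_numpy(dtype=float)
    species = pd.Categorical(df[species_col])
    Z = np.eye(len(species.categories))[species.codes]
    n, p = X.shape

    def reml_ll(theta):
        V0 = np.eye(n) + theta * Z @ Z.T
        V0inv = np.linalg.inv(V0)
        XtVX = X.T @ V0inv @ X
        beta = np.linalg.solve(XtVX, X.T @ V0inv @ y)
        r = y - X @ beta
        sigma2 = r @ V0inv @ r / (n - p)
        _, ld_v = np.linalg.slogdet(V0)
        _, ld_x = np.linalg.slogdet(XtVX)
        return -0.5 * ((n - p) * np.log(sigma2) + ld_v + ld_x), beta, sigma2

    grid = np.geomspace(1e-4, 1e3, 400)
    lls = [reml_ll(t)[0] for t in grid]
    best = int(np.argmax(lls))
    # refine around the coarse optimum
    fine = np.geomspace(grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)], 400)
    lls = [reml_ll(t)[0] for t in fine]
    theta = fine[int(np.argmax(lls))]
    _, beta, sigma2 = reml_ll(theta)
    return beta, theta * sigma2, sigma2


class TestFitGroupLmm:
    def test_noiseless_common_slope_recovered_exactly(self):
        rows = []
        for gi, g in enumerate(["A", "B"]):
            for s in range(3):
                for y in range(2002, 2012):
                    rows.append({"species": f"{g}{s}", "wintering_group": g,
                                 "year": y,
                                 "value": 100 + 4 * s + 10 * gi - 0.6 * (y - 2002)})
        fit = fit_group_lmm(pd.DataFrame(rows), "value")
        assert fit.fe_params["year"] == pytest.approx(-0.6, abs=1e-6)
        assert fit.residual_var < 1e-4

    def test_single_group_reduces_to_intercept_plus_year(self):
        df = make_group_data(0, {"A": -0.5}, n_species=4, years=(2002, 2010))
        fit = fit_group_lmm(df, "value")
        assert list(fit.fe_params.index) == ["Intercept", "year"]
        slopes = marginal_slopes(fit)
        assert slopes.loc[0, "slope"] == fit.fe_params["year"]

    def test_singular_group_designs_rejected_by_name(self):
        df = make_group_data(1, {"A": -0.5, "B": 0.0}, n_species=2,
                             years=(2002, 2008))
        solo = df.loc[df["species"] != "B_1"].copy()
        with pytest.raises(ValueError, match="'B'"):
            fit_group_lmm(solo, "value")
        one_row = pd.concat([
            df.loc[df["wintering_group"] == "A"],
            df.loc[(df["species"] == "B_0") & (df["year"] == 2002)],
        ])
        with pytest.raises(ValueError, match="'B'"):
            fit_group_lmm(one_row, "value")

    def test_agrees_with_reml_profile_oracle(self):
        df = make_group_data(7, {"A": -0.8, "B": -0.1}, n_species=3,
                             years=(2002, 2011), intercept_sd=4.0, noise_sd=2.0)
        fit = fit_group_lmm(df, "value")
        beta, re_var, resid = reml_profile_oracle(df, "value")
        np.testing.assert_allclose(fit.fe_params.to_numpy(), beta, rtol=1e-4)
        assert fit.random_intercept_var == pytest.approx(re_var, rel=0.02)
        assert fit.residual_var == pytest.approx(resid, rel=0.02)

    def test_vanishing_species_variance_approaches_pooled_ols(self):
        import statsmodels.api as sm
        from phenopass.groups import _design_matrix
        df = make_group_data(3, {"A": -0.5, "B": 0.0}, n_species=5,
                             years=(2002, 2013), intercept_sd=0.0, noise_sd=3.0)
        fit = fit_group_lmm(df, "value")
        levels = sorted(df["wintering_group"].unique())
        X = _design_matrix(df, "wintering_group", "year", 2002, levels)
        ols = sm.OLS(df["value"].to_numpy(), X).fit()
        assert fit.random_intercept_var < 0.5
        np.testing.assert_allclose(fit.fe_params.to_numpy(), ols.params.to_numpy(),
                                   atol=0.05)


@pytest.fixture(scope="module")
def fit():
    df = make_group_data(11, {"A": -0.8, "B": -0.5, "C": -0.1})
    return fit_group_lmm(df, "value")


class TestMarginalSlopes:

    def test_reference_group_slope_is_year_coefficient(self, fit):
        s = marginal_slopes(fit).set_index("group")
        assert s.loc["A", "slope"] == pytest.approx(fit.fe_params["year"])

    def test_nonreference_slope_adds_interaction(self, fit):
        s = marginal_slopes(fit).set_index("group")
        expect = fit.fe_params["year"] + fit.fe_params["wintering_group[B]:year"]
        assert s.loc["B", "slope"] == pytest.approx(expect)

    def test_pairwise_difference_consistent_with_slopes(self, fit):
        s = marginal_slopes(fit).set_index("group")
        c = pairwise_slope_tests(fit)
        for _, row in c.iterrows():
            assert row["estimate"] == pytest.approx(
                s.loc[row["group_a"], "slope"] - s.loc[row["group_b"], "slope"])

    def test_identical_groups_give_zero_contrast_unit_p(self):
        df = make_group_data(5, {"A": -0.5}, n_species=4, years=(2002, 2012))
        mirror = df.copy()
        mirror["wintering_group"] = "B"
        mirror["species"] = mirror["species"].str.replace("A", "B")
        fit = fit_group_lmm(pd.concat([df, mirror], ignore_index=True), "value")
        c = pairwise_slope_tests(fit).iloc[0]
        assert c["estimate"] == pytest.approx(0.0, abs=1e-8)
        assert c["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_overall_year_trend_pools_groups(self):
        df = make_group_data(9, {"A": -0.6, "B": -0.6}, n_species=5)
        slope, t = overall_year_trend(df, "value")
        assert slope == pytest.approx(-0.6, abs=0.1)
        assert t < -5


class TestSexAnalysis:
    @staticmethod
    def _sex_metrics(seed, male_slope, female_slope, n_species=3):
        rng = np.random.default_rng(seed)
        rows = []
        meta_rows = []
        for g in ("Sahel", "Tropical"):
            for s in range(n_species):
                sp = f"{g}_{s}"
                meta_rows.append({"species": sp, "wintering_group": g,
                                  "dimorphic": True})
                a = 110 + rng.normal(0, 4)
                for sex, slope in (("male", male_slope), ("female", female_slope)):
                    for y in range(2002, 2020):
                        rows.append({
                            "species": sp, "sex": sex, "year": y,
                            "total_captures": 50, "excluded": False,
                            "peak_day": a + slope * (y - 2002) + rng.normal(0, 2),
                            "start_day": np.nan, "end_day": np.nan,
                            "window_days": np.nan,
                            "start_truncated": False, "end_truncated": False,
                        })
        return pd.DataFrame(rows), pd.DataFrame(meta_rows)

    def test_male_advance_detected_females_flat(self):
        metrics, meta = self._sex_metrics(2, male_slope=-0.7, female_slope=0.0)
        res = sex_group_analysis(metrics, meta)
        male_slopes = res.by_sex["male"].slopes
        assert (male_slopes["slope"] < -0.4).all()
        assert (male_slopes["p_value"] < 0.01).all()
        for g in ("Sahel", "Tropical"):
            fit = res.within_group[g].fit
            inter = fit.fe_params["sex[male]:year"]
            assert inter == pytest.approx(-0.7, abs=0.25)
            assert fit.tvalues["sex[male]:year"] < -3

    def test_identical_sexes_show_no_interaction(self):
        metrics, meta = self._sex_metrics(4, male_slope=-0.3, female_slope=-0.3)
        res = sex_group_analysis(metrics, meta)
        for g in ("Sahel", "Tropical"):
            t = res.within_group[g].fit.tvalues["sex[male]:year"]
            assert abs(t) < 2

    def test_single_dimorphic_species_per_group_is_singular(self):
        metrics, meta = self._sex_metrics(6, -0.5, 0.0, n_species=1)
        with pytest.raises(ValueError, match="fewer than two species"):
            sex_group_analysis(metrics, meta)

    def test_species_sex_table_has_one_row_per_species_sex(self):
        metrics, meta = self._sex_metrics(8, -0.5, 0.1)
        res = sex_group_analysis(metrics, meta)
        assert len(res.species_trends) == 12  # 6 species x 2 sexes
        assert set(res.species_trends["sex"]) == {"male", "female"}
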