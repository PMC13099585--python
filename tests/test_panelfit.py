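"""Within-estimator: characteristics, Winsorizing, FE absorption vs. a
direct dummy-variable oracle, heterogeneity, and the AC diagnostic."""

import numpy as np
import pandas as pd
import pytest

from forecastmort import basis, panelfit, synthdata as sd


class TestCountyCharacteristics:
    @staticmethod
    def _rec(temps, forecasts, county="A"):
        return pd.DataFrame(
            {
                "county_id": county,
                "date": pd.date_range("2005-01-01", periods=len(temps), freq="D"),
                "temp": np.asarray(temps, float),
                "forecast": np.asarray(forecasts, float),
            }
        )

    def test_constant_temp_perfect_forecast(self):
        ch = panelfit.compute_county_characteristics(self._rec([7.0] * 5, [7.0] * 5))
        assert ch.loc["A", "mu_T"] == 7.0
        assert ch.loc["A", "sigma_T"] == 0.0
        assert ch.loc["A", "rmse"] == 0.0

    def test_sigma_from_hand_arithmetic(self):
        ch = panelfit.compute_county_characteristics(self._rec([0, 2, 0], [0, 2, 0]))
        assert ch.loc["A", "sigma_T"] == pytest.approx(2.0)

    def test_constant_forecast_bias_gives_unit_rmse(self):
        t = np.array([3.0, 9.0, -2.0])
        ch = panelfit.compute_county_characteristics(self._rec(t, t + 1.0))
        assert ch.loc["A", "rmse"] == pytest.approx(1.0)

    def test_single_day_county_flagged(self):
        ch = panelfit.compute_county_characteristics(self._rec([5.0], [5.0]))
        assert ch.loc["A", "sigma_T_undefined"]
        assert np.isnan(ch.loc["A", "sigma_T"])


class TestWinsorize:
    def test_equal_weights_matches_brute_force_quantiles(self):
        v = np.arange(1.0, 101.0)
        clipped, (lo, hi) = panelfit.winsorize_weighted(v, None)
        lo_bf, hi_bf = basis.weighted_quantile(v, [0.05, 0.95])
        assert (lo, hi) == (lo_bf, hi_bf)
        assert clipped.min() == lo and clipped.max() == hi
        inside = (v >= lo) & (v <= hi)
        np.testing.assert_array_equal(clipped[inside], v[inside])

    def test_all_equal_unchanged(self):
        v = np.full(10, 3.3)
        clipped, _ = panelfit.winsorize_weighted(v)
        np.testing.assert_array_equal(clipped, v)

    def test_single_mass_point_clips_everything(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.0, 1.0, 0.0])
        clipped, _ = panelfit.winsorize_weighted(v, w)
        np.testing.assert_array_equal(clipped, [2.0, 2.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            panelfit.winsorize_weighted(np.array([]))


def _dummy_oracle(design, cluster="wfo_id"):
    """Direct (single-shot) weighted projection on explicit FE dummies,
    plus the brute-force clustered sandwich."""
    cols = basis.X_COLS + ["rain_above_median"]
    X = design[cols].to_numpy(float)
    y = design["mortality_rate"].to_numpy(float)
    w = design["weight"].to_numpy(float)
    t = design["t"].to_numpy(float)
    a, _ = pd.factorize(pd.MultiIndex.from_frame(design[["county_id", "month"]]))
    b, _ = pd.factorize(pd.MultiIndex.from_frame(design[["state_id", "year_month"]]))
    n, nA, nB = len(y), a.max() + 1, b.max() + 1
    D = np.zeros((n, 2 * nA + nB))
    D[np.arange(n), a] = 1.0
    D[np.arange(n), nA + a] = t
    D[np.arange(n), 2 * nA + b] = 1.0
    sw = np.sqrt(w)
    coef_D, *_ = np.linalg.lstsq(D * sw[:, None], np.column_stack([X, y]) * sw[:, None],
                                 rcond=None)
    R = np.column_stack([X, y]) - D @ coef_D
    Xt, yt = R[:, :-1], R[:, -1]
    beta, *_ = np.linalg.lstsq(Xt * sw[:, None], yt * sw, rcond=None)
    resid = yt - Xt @ beta
    K = X.shape[1] + np.linalg.matrix_rank(D * sw[:, None])
    codes, uniq = pd.factorize(design[cluster])
    G = len(uniq)
    scores = np.zeros((G, Xt.shape[1]))
    np.add.at(scores, codes, Xt * (w * resid)[:, None])
    bread = np.linalg.inv((Xt * w[:, None]).T @ Xt)
    c = (G / (G - 1)) * ((n - 1) / (n - K))
    vcov = c * bread @ (scores.T @ scores) @ bread
    return beta, vcov, K


class TestFitPanel:
    def test_exact_identification_zero_noise(self, small_records, small_counties,
                                             counties_df, truth_exact):
        monthly = sd.simulate_mortality(small_records, small_counties, truth_exact, seed=1)
        design, _ = basis.aggregate_monthly(small_records, monthly, counties_df,
                                            truth_exact.basis_spec)
        fit = panelfit.fit_panel(design)
        np.testing.assert_allclose(fit.beta, truth_exact.beta_true, atol=1e-8)

    def test_constant_mortality_absorbed_to_zero(self, small_design):
        d = small_design.copy()
        d.attrs["knots"] = small_design.attrs["knots"]
        d["mortality_rate"] = 55.0
        fit = panelfit.fit_panel(d)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-8)

    def test_matches_dummy_variable_oracle(self, small_design):
        fit = panelfit.fit_panel(small_design)
        beta_o, vcov_o, K_o = _dummy_oracle(small_design)
        scale = np.abs(beta_o[:13]) + 1e-12
        assert np.max(np.abs(fit.beta - beta_o[:13]) / scale) < 1e-8
        assert fit.dof_model == K_o
        vs = np.sqrt(np.outer(np.diag(vcov_o[:13, :13]), np.diag(vcov_o[:13, :13])))
        assert np.max(np.abs(fit.vcov - vcov_o[:13, :13]) / vs) < 1e-8

    def test_duplicated_row_with_half_weight_leaves_beta_unchanged(self, small_design):
        fit0 = panelfit.fit_panel(small_design)
        dup = small_design.iloc[[10]].copy()
        d = pd.concat([small_design, dup], ignore_index=True)
        d.loc[[10, len(d) - 1], "weight"] /= 2.0
        d.attrs["knots"] = small_design.attrs["knots"]
        fit1 = panelfit.fit_panel(d)
        np.testing.assert_allclose(fit0.beta, fit1.beta, rtol=1e-7, atol=1e-12)

    def test_vcov_invariant_to_within_cluster_row_order(self, small_design):
        fit0 = panelfit.fit_panel(small_design)
        perm = small_design.sample(frac=1.0, random_state=8)
        perm.attrs["knots"] = small_design.attrs["knots"]
        fit1 = panelfit.fit_panel(perm)
        np.testing.assert_allclose(fit0.vcov, fit1.vcov, rtol=1e-8)

    def test_single_cluster_refuses_inference(self, small_design):
        d = small_design.copy()
        d["wfo_id"] = "W000"
        d.attrs["knots"] = small_design.attrs["knots"]
        with pytest.warns(panelfit.SingleClusterWarning):
            fit = panelfit.fit_panel(d)
        assert fit.vcov is None
        assert fit.beta.shape == (13,)

    def test_collinear_design_names_offending_column(self, small_design):
        d = small_design.copy()
        d["rain_above_median"] = 1.0  # constant: absorbed by the FEs
        d.attrs["knots"] = small_design.attrs["knots"]
        with pytest.raises(ValueError, match="rain_above_median"):
            panelfit.fit_panel(d)


@pytest.fixture(scope="module")
def wide_panel():
    """A panel with enough WFO clusters for trustworthy clustered SEs."""
    counties = sd.generate_counties(60, 10, 12, seed=21)
    cdf = sd.counties_frame(counties)
    weather = sd.simulate_daily_weather(counties, range(2005, 2009), seed=22)
    rec = sd.simulate_forecast_errors(weather, counties, sd.DEFAULT_ERROR_PROCESS, seed=23)
    rec = basis.demean_errors(rec, "county").merge(cdf[["county_id", "wfo_id"]],
                                                   on="county_id")
    truth = sd.make_truth_surface()
    monthly = sd.simulate_mortality(rec, counties, truth, seed=24)
    design, _ = basis.aggregate_monthly(rec, monthly, cdf, truth.basis_spec)
    return design, rec


class TestHeterogeneousPanel:
    @staticmethod
    def _design_with_char_betas(small_design, small_records, gamma_mu, noise_sd=0.0,
                                seed=0):
        """Replace mortality with X . (beta + mu_T * gamma) per county."""
        chars = panelfit.compute_county_characteristics(small_records)
        pop = small_design.groupby("county_id")["weight"].first()
        clipped, _ = panelfit.winsorize_weighted(
            chars["mu_T"].reindex(pop.index).to_numpy(), pop.to_numpy()
        )
        mu = pd.Series(clipped, index=pop.index)
        rng = np.random.default_rng(seed)
        beta0 = rng.normal(scale=0.01, size=13)
        d = small_design.copy()
        X = d[basis.X_COLS].to_numpy(float)
        muv = mu.reindex(d["county_id"]).to_numpy()
        y = X @ beta0 + (X * muv[:, None]) @ gamma_mu
        if noise_sd > 0:
            y = y + rng.normal(scale=noise_sd, size=len(y))
        d["mortality_rate"] = y
        d.attrs["knots"] = small_design.attrs["knots"]
        return d, chars, beta0

    def test_zero_heterogeneity_recovers_zero_gammas_exactly(self, small_design,
                                                             small_records):
        d, chars, beta0 = self._design_with_char_betas(small_design, small_records,
                                                       np.zeros(13))
        het = panelfit.fit_heterogeneous_panel(d, chars, ("mu_T",))
        np.testing.assert_allclose(het.gammas["mu_T"], 0.0, atol=1e-8)
        np.testing.assert_allclose(het.beta_bar, beta0, atol=1e-8)

    def test_planted_gamma_recovered_under_noise(self, wide_panel):
        design, rec = wide_panel
        gamma = np.zeros(13)
        gamma[1] = 2e-4  # temperature-squared lethality rises with mean temp
        gamma[5] = 5e-3
        d, chars, _ = self._design_with_char_betas(design, rec, gamma,
                                                   noise_sd=2.0, seed=4)
        het = panelfit.fit_heterogeneous_panel(d, chars, ("mu_T",))
        se = np.sqrt(np.diag(het.vcov)[13:26])
        assert np.all(np.abs(het.gammas["mu_T"] - gamma) < 3 * se)

    def test_constant_characteristic_unidentified(self, small_design, small_records):
        chars = panelfit.compute_county_characteristics(small_records)
        chars["mu_T"] = 12.0
        with pytest.raises(ValueError, match="unidentified"):
            panelfit.fit_heterogeneous_panel(small_design, chars, ("mu_T",),
                                             winsorize=False)

    def test_missing_characteristics_rejected(self, small_design, small_records):
        chars = panelfit.compute_county_characteristics(small_records).iloc[:-2]
        with pytest.raises(ValueError, match="missing"):
            panelfit.fit_heterogeneous_panel(small_design, chars, ("mu_T",))


class TestPredictSurface:
    def _fit(self, beta, knots=sd.DEFAULT_KNOTS):
        return panelfit.FitResult(beta=np.asarray(beta, float), rain_coef=0.0, vcov=None,
                                  n_obs=0, n_clusters=2, dof_model=0, knots=tuple(knots))

    def test_zero_coefficients_zero_everywhere(self):
        fit = self._fit(np.zeros(13))
        T = np.linspace(-10, 40, 7)
        np.testing.assert_array_equal(panelfit.predict_surface(fit, T, T * 0), 0.0)

    def test_unit_vector_on_linear_term_returns_temperature(self):
        beta = np.zeros(13)
        beta[0] = 1.0
        fit = self._fit(beta)
        T = np.array([-3.0, 0.0, 21.5])
        np.testing.assert_allclose(panelfit.predict_surface(fit, T, T * 0), T)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(size=13)
        fit = self._fit(beta)
        T = rng.uniform(-10, 40, 50)
        e = rng.normal(0, 1.5, 50)
        expected = basis.build_daily_design(T, e, fit.basis_spec) @ beta
        np.testing.assert_allclose(panelfit.predict_surface(fit, T, e), expected)

    def test_out_of_band_characteristics_clipped_with_warning(self):
        het = panelfit.HeterogeneousFitResult(
            beta_bar=np.zeros(13), gammas={"mu_T": np.eye(13)[0]}, rain_coef=0.0,
            vcov=None, n_obs=0, n_clusters=2, dof_model=0, knots=sd.DEFAULT_KNOTS,
            winsor_bands={"mu_T": (5.0, 20.0)}, dims=("mu_T",),
        )
        T = np.array([1.0])
        with pytest.warns(UserWarning, match="Winsorized band"):
            hi = panelfit.predict_surface(het, T, T * 0, {"mu_T": 99.0})
        at_band = panelfit.predict_surface(het, T, T * 0, {"mu_T": 20.0})
        np.testing.assert_allclose(hi, at_band)


class TestACAssociation:
    @staticmethod
    def _chars(n, rng):
        return pd.DataFrame(
            {"mu_T": rng.uniform(5, 25, n), "sigma_T": rng.uniform(1, 4, n),
             "rmse": rng.uniform(0.8, 2.0, n)},
            index=[f"C{i:03d}" for i in range(n)],
        )

    def test_residuals_orthogonal_to_characteristics(self):
        rng = np.random.default_rng(0)
        ch = self._chars(150, rng)
        ac = pd.Series(rng.uniform(0, 1, 150), index=ch.index)
        mort = pd.Series(rng.normal(size=150), index=ch.index)
        res = panelfit.residualized_ac_association(mort, ac, ch, trim_pct=(0, 100),
                                                   n_drop_lowest=0)
        Z = ch.to_numpy()
        for v in (res.ac_resid, res.mort_resid):
            corr = np.abs(np.corrcoef(np.column_stack([v[:, None], Z]), rowvar=False)[0, 1:])
            assert corr.max() < 1e-10

    def test_null_association_flat_lowess(self):
        rng = np.random.default_rng(1)
        ch = self._chars(200, rng)
        ac = pd.Series(rng.uniform(0, 1, 200), index=ch.index)
        mort = pd.Series(rng.normal(size=200), index=ch.index)
        res = panelfit.residualized_ac_association(mort, ac, ch)
        span = res.lowess_y.max() - res.lowess_y.min()
        assert span < 0.8 * res.mort_resid.std()

    def test_planted_positive_dependence_recovered(self):
        rng = np.random.default_rng(2)
        ch = self._chars(200, rng)
        ac = pd.Series(rng.uniform(0, 1, 200), index=ch.index)
        mort = pd.Series(2.0 * ac.to_numpy() + rng.normal(scale=0.2, size=200),
                         index=ch.index)
        res = panelfit.residualized_ac_association(mort, ac, ch)
        assert res.lowess_y[-1] > res.lowess_y[0]
        slope = np.polyfit(res.lowess_x, res.lowess_y, 1)[0]
        assert slope > 1.0

    def test_too_few_counties_refused(self):
        rng = np.random.default_rng(3)
        ch = self._chars(8, rng)
        ac = pd.Series(rng.uniform(0, 1, 8), index=ch.index)
        mort = pd.Series(rng.normal(size=8), index=ch.index)
        with pytest.raises(ValueError, match="10 counties"):
            panelfit.residualized_ac_association(mort, ac, ch)


def test_hot_day_error_mortality_weighted_binning(small_records, truth):
    fit = panelfit.FitResult(beta=truth.beta_true, rain_coef=0.0, vcov=None, n_obs=0,
                             n_clusters=2, dof_model=0,
                             knots=truth.basis_spec.error_knots)
    rates = panelfit.county_hot_day_error_mortality(fit, small_records)
    cid = rates.index[0]
    g = small_records[(small_records["county_id"] == cid) & (small_records["temp"] > 20)]
    T, e = g["temp"].to_numpy(), g["error_demeaned"].to_numpy()
    excess = (panelfit.predict_surface(fit, T, e)
              - panelfit.predict_surface(fit, T, 0 * e))
    bins = np.floor(T - 20).astype(int)
    per_bin = pd.DataFrame({"b": bins, "x": excess}).groupby("b")["x"].agg(["mean", "size"])
    expected = np.average(per_bin["mean"], weights=per_bin["size"])
    assert rates.loc[cid] == pytest.approx(expected, rel=1e-12)
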