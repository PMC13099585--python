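"""Excess-mortality projection under climate and forecast scenarios.

A fitted response surface evaluated at projected temperatures and
scenario-consistent forecast errors yields daily excess mortality rates
relative to each county's minimum-mortality temperature (MMT) at zero
error.  Rates are scaled by base-year population, summed to annual
deaths, and averaged over six-year windows; lives saved by a forecast
scenario are the difference against the constant-accuracy baseline,
with confidence intervals propagated from the clustered covariance of
the regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import N_BASIS, build_daily_design
from .panelfit import FitResult, HeterogeneousFitResult, predict_surface

__all__ = [
    "ResponseFunction",
    "MortalityProjection",
    "LivesSaved",
    "bias_adjust_climate",
    "find_mmt",
    "excess_mortality_rate",
    "evolve_characteristics",
    "project_mortality",
    "lives_saved",
]

MMT_SEARCH_RANGE = (10.0, 35.0)
MMT_CAP = 29.5
MMT_GRID_STEP = 0.1


def _mmt_grid() -> np.ndarray:
    lo, hi = MMT_SEARCH_RANGE
    return np.round(np.arange(lo, hi + 1e-9, MMT_GRID_STEP), 6)


def _grid_argmin(curve: np.ndarray) -> int:
    # ties break toward the lower temperature (first occurrence)
    return int(np.argmin(curve))


def find_mmt(fit, characteristics=None, cap: float = MMT_CAP, refine: bool = True) -> float:
    """Temperature in [10, 35] degC minimizing the zero-error surface.

    Grid search at 0.1 degC with local parabolic refinement.  Under a
    heterogeneous fit, a surface with no interior minimum (argmin on the
    search boundary) is assigned the cap instead of the boundary value.
    """
    grid = _mmt_grid()
    curve = predict_surface(fit, grid, np.zeros_like(grid), characteristics)
    i = _grid_argmin(curve)
    heterogeneous = isinstance(fit, HeterogeneousFitResult)
    if i == 0 or i == len(grid) - 1:
        return cap if heterogeneous else float(grid[i])
    if refine:
        # parabola through the three bracketing grid points
        x0, x1, x2 = grid[i - 1 : i + 2]
        y0, y1, y2 = curve[i - 1 : i + 2]
        denom = (y0 - 2 * y1 + y2)
        if denom > 0:
            return float(x1 + 0.5 * MMT_GRID_STEP * (y0 - y2) / denom)
    return float(grid[i])


@dataclass
class ResponseFunction:
    """A fitted surface plus per-county MMTs ready for projection."""

    fit: FitResult | HeterogeneousFitResult
    characteristics: pd.DataFrame | None = None
    mmt: pd.Series | float = field(default=np.nan)
    mmt_cap: float = MMT_CAP

    @classmethod
    def build(cls, fit, county_ids=None, characteristics=None, cap: float = MMT_CAP):
        if isinstance(fit, HeterogeneousFitResult):
            if characteristics is None:
                raise ValueError("heterogeneous fit requires characteristics")
            ids = list(county_ids) if county_ids is not None else list(characteristics.index)
            mmt = pd.Series(
                {cid: find_mmt(fit, characteristics.loc[cid], cap=cap) for cid in ids}
            )
        else:
            mmt = find_mmt(fit, cap=cap)
        return cls(fit=fit, characteristics=characteristics, mmt=mmt, mmt_cap=cap)

    def mmt_of(self, county_id) -> float:
        if isinstance(self.mmt, pd.Series):
            return float(self.mmt.loc[county_id])
        return float(self.mmt)

    def chars_of(self, county_id):
        if self.characteristics is None:
            return None
        return self.characteristics.loc[county_id]


def excess_mortality_rate(response: ResponseFunction, county_id, T, e) -> np.ndarray:
    """Daily excess deaths per 100,000: f(T, e) - f(MMT, 0)."""
    ch = response.chars_of(county_id)
    T = np.asarray(T, float)
    e = np.asarray(e, float)
    mmt = response.mmt_of(county_id)
    ref = predict_surface(response.fit, np.array([mmt]), np.array([0.0]), ch)[0]
    return predict_surface(response.fit, T, e, ch) - ref


def bias_adjust_climate(
    observed_annual_means: pd.DataFrame,
    projected_annual_means: pd.DataFrame,
    projected_daily: pd.DataFrame,
    anchor_year: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove systematic model-minus-observation offsets from a projection.

    Per county, quadratic-in-year trends are fitted to the observed and
    projected annual mean temperature series; the difference between the
    two trend predictions at the anchor year (default: first projected
    year) is subtracted from every projected daily temperature.  Returns
    the adjusted daily panel and the per-county adjustments.
    """
    def _trend_pred(df: pd.DataFrame, anchor: float) -> pd.Series:
        out = {}
        for cid, g in df.groupby("county_id"):
            yrs = g["year"].to_numpy(float)
            if len(np.unique(yrs)) < 3:
                raise ValueError(f"county {cid}: need >= 3 years for a quadratic trend")
            coefs = np.polyfit(yrs - anchor, g["temp_mean"].to_numpy(float), 2)
            out[cid] = float(coefs[-1])  # value at the anchor
        return pd.Series(out)

    if anchor_year is None:
        anchor_year = int(projected_annual_means["year"].min())
    obs = _trend_pred(observed_annual_means, anchor_year)
    proj = _trend_pred(projected_annual_means, anchor_year)
    adj = (proj - obs).dropna()
    missing = set(projected_daily["county_id"]) - set(adj.index)
    if missing:
        raise ValueError(f"no trend adjustment for counties: {sorted(missing)[:5]}")
    out = projected_daily.copy()
    out["temp"] = out["temp"] - adj.reindex(out["county_id"]).to_numpy(float)
    return out, adj


def evolve_characteristics(
    chars_current: pd.DataFrame,
    chars_baseline_period: pd.DataFrame,
    chars_endcentury_period: pd.DataFrame,
    insample_bands: dict[str, tuple[float, float]],
) -> tuple[pd.DataFrame, list]:
    """End-century county characteristics under a scenario.

    Each characteristic is multiplied by the scenario-implied ratio of
    end-century to baseline-period values and then clipped to the
    in-sample Winsorized 5th-95th band, preventing far-out-of-sample
    extrapolation of the linear heterogeneity.  Counties with a zero
    baseline but nonzero end-century value are excluded and listed.
    """
    evolved = chars_current.copy()
    excluded: list = []
    for dim, (lo, hi) in insample_bands.items():
        base = chars_baseline_period[dim]
        end = chars_endcentury_period[dim]
        bad = (base == 0) & (end != 0)
        excluded.extend(evolved.index[bad.reindex(evolved.index, fill_value=False)])
        ratio = (end / base).replace([np.inf, -np.inf], np.nan)
        evolved[dim] = np.clip(
            chars_current[dim] * ratio.reindex(evolved.index), lo, hi
        )
    excluded = sorted(set(excluded))
    return evolved.drop(index=excluded), excluded


# ---------------------------------------------------------------------------
# annual aggregation with sufficient statistics for coefficient draws


def _augment(X: np.ndarray, fit, characteristics, county_ids) -> np.ndarray:
    """Stack X with characteristic interactions to match the fit's
    coefficient vector layout [beta, gamma_dim1, ...]."""
    if not isinstance(fit, HeterogeneousFitResult):
        return X
    blocks = [X]
    for dim in fit.dims:
        lo, hi = fit.winsor_bands.get(dim, (-np.inf, np.inf))
        vals = characteristics[dim].reindex(county_ids).clip(lo, hi).to_numpy(float)
        blocks.append(X * vals[:, None])
    return np.column_stack(blocks)


def _coef_vector(fit) -> np.ndarray:
    if isinstance(fit, HeterogeneousFitResult):
        return np.concatenate([fit.beta_bar] + [fit.gammas[d] for d in fit.dims])
    return fit.beta


@dataclass
class MortalityProjection:
    """Annual excess deaths for one climate x forecast scenario pair.

    Stores basis sufficient statistics so deaths can be re-evaluated in
    closed form for any coefficient draw (the totals are linear in the
    coefficients for a fixed MMT, which is re-searched per draw).
    """

    scenario_climate: str
    scenario_forecast: str
    years: np.ndarray
    total_by_year: pd.Series
    hot_by_year: pd.Series
    mean_annual: float
    mean_annual_hot: float
    # sufficient statistics
    A_all: np.ndarray  # (nyears, k) population-scaled basis sums
    A_hot: np.ndarray
    day_weight: pd.DataFrame  # county x year: pop/1e5 * ndays
    hot_day_weight: pd.DataFrame
    response: ResponseFunction

    def deaths_for_coefs(self, coef_full: np.ndarray) -> tuple[float, float]:
        """Six-year-average annual deaths (all days, hot days) for a
        coefficient vector, re-searching the MMT."""
        fit = self.response.fit
        grid = _mmt_grid()
        G = build_daily_design(grid, np.zeros_like(grid), fit.basis_spec)
        counties = self.day_weight.index
        Ga = np.stack(
            [
                _augment(G, fit, self.response.characteristics,
                         pd.Index([cid]).repeat(len(grid)))
                for cid in counties
            ]
        ) if isinstance(fit, HeterogeneousFitResult) else None
        if Ga is None:
            curve = G @ coef_full
            i = _grid_argmin(curve)
            if i == 0 or i == len(grid) - 1:
                mmt = np.full(len(counties), float(grid[i]))
            else:
                mmt = np.full(len(counties), float(grid[i]))
            Xm = build_daily_design(mmt, np.zeros_like(mmt), fit.basis_spec)
            ref_rate = Xm @ coef_full  # per county
        else:
            curves = Ga @ coef_full  # (C, n_grid)
            idx = np.argmin(curves, axis=1)
            mmt = grid[idx]
            boundary = (idx == 0) | (idx == len(grid) - 1)
            mmt = np.where(boundary, self.response.mmt_cap, mmt)
            Xm = _augment(
                build_daily_design(mmt, np.zeros_like(mmt), fit.basis_spec),
                fit, self.response.characteristics, counties,
            )
            ref_rate = Xm @ coef_full
        ref_rate = pd.Series(ref_rate, index=counties)
        total = self.A_all @ coef_full - (self.day_weight.mul(ref_rate, axis=0)).sum().to_numpy()
        hot = self.A_hot @ coef_full - (self.hot_day_weight.mul(ref_rate, axis=0)).sum().to_numpy()
        return float(np.mean(total)), float(np.mean(hot))


def project_mortality(
    panel: pd.DataFrame,
    response: ResponseFunction,
    populations: pd.Series,
    hot_threshold: float = 20.0,
    scenario_climate: str = "",
    scenario_forecast: str = "",
) -> MortalityProjection:
    """Aggregate daily excess mortality to annual deaths.

    ``panel`` holds county-day projected temperature and the scenario's
    drawn forecast error; daily rates are multiplied by base-year county
    population / 100,000 and summed within years.  Hot-day totals keep
    days whose realized (projected) temperature strictly exceeds the
    threshold.
    """
    required = {"county_id", "date", "temp", "error"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    if panel["error"].isna().any():
        raise ValueError("panel contains missing error draws (misaligned panels?)")
    pop = populations.reindex(pd.unique(panel["county_id"]))
    if pop.isna().any():
        raise ValueError(f"populations missing for: {list(pop.index[pop.isna()])[:5]}")

    fit = response.fit
    df = panel.copy()
    df["year"] = pd.DatetimeIndex(df["date"]).year
    T = df["temp"].to_numpy(float)
    e = df["error"].to_numpy(float)
    X = _augment(
        build_daily_design(T, e, fit.basis_spec), fit, response.characteristics,
        pd.Index(df["county_id"]),
    )
    k = X.shape[1]
    w = (pop / 1e5).reindex(df["county_id"]).to_numpy(float)
    hot = T > hot_threshold

    years = np.sort(df["year"].unique())
    ycodes = pd.Categorical(df["year"], categories=years).codes
    A_all = np.zeros((len(years), k))
    A_hot = np.zeros((len(years), k))
    np.add.at(A_all, ycodes, X * w[:, None])
    np.add.at(A_hot, ycodes[hot], (X * w[:, None])[hot])

    day_weight = (
        df.assign(_w=w).pivot_table(index="county_id", columns="year", values="_w",
                                    aggfunc="sum", fill_value=0.0)
    )
    hot_day_weight = (
        df.loc[hot].assign(_w=w[hot]).pivot_table(index="county_id", columns="year",
                                                  values="_w", aggfunc="sum", fill_value=0.0)
    ).reindex(index=day_weight.index, columns=day_weight.columns, fill_value=0.0)

    proj = MortalityProjection(
        scenario_climate=scenario_climate,
        scenario_forecast=scenario_forecast,
        years=years,
        total_by_year=pd.Series(dtype=float),
        hot_by_year=pd.Series(dtype=float),
        mean_annual=np.nan,
        mean_annual_hot=np.nan,
        A_all=A_all,
        A_hot=A_hot,
        day_weight=day_weight,
        hot_day_weight=hot_day_weight,
        response=response,
    )
    coef = _coef_vector(fit)
    # per-year point estimates with the fitted MMT (not re-searched)
    ref = pd.Series(
        {
            cid: predict_surface(
                fit, np.array([response.mmt_of(cid)]), np.array([0.0]),
                response.chars_of(cid),
            )[0]
            for cid in day_weight.index
        }
    )
    total = A_all @ coef - day_weight.mul(ref, axis=0).sum().to_numpy()
    hot_t = A_hot @ coef - hot_day_weight.mul(ref, axis=0).sum().to_numpy()
    proj.total_by_year = pd.Series(total, index=years)
    proj.hot_by_year = pd.Series(hot_t, index=years)
    proj.mean_annual = float(np.mean(total))
    proj.mean_annual_hot = float(np.mean(hot_t))
    return proj


@dataclass
class LivesSaved:
    """Lives saved by a forecast scenario vs. the constant baseline."""

    scenario_climate: str
    scenario_forecast: str
    all_days: float
    hot_days: float
    all_days_ci: tuple[float, float] | None
    hot_days_ci: tuple[float, float] | None
    n_draws: int


def lives_saved(
    result_scenario: MortalityProjection,
    result_baseline: MortalityProjection,
    fit,
    n_draws: int = 1000,
    seed: int = 0,
) -> LivesSaved:
    """Baseline-minus-scenario annual deaths with 95% CIs.

    CIs re-evaluate both projections at coefficient draws from a
    multivariate normal centered at the estimates with the clustered
    covariance; the same draws are used for both scenarios so the
    difference is stabilized.  Only regression uncertainty is
    propagated.
    """
    if not np.array_equal(result_scenario.years, result_baseline.years):
        raise ValueError("mismatched climate panels: different projection years")
    if not result_scenario.day_weight.round(9).equals(result_baseline.day_weight.round(9)):
        raise ValueError("mismatched climate panels: day weights differ")
    point_all = result_baseline.mean_annual - result_scenario.mean_annual
    point_hot = result_baseline.mean_annual_hot - result_scenario.mean_annual_hot
    vcov = getattr(fit, "vcov", None)
    ci_all = ci_hot = None
    if vcov is not None and n_draws > 0:
        rng = np.random.default_rng(seed)
        coef = _coef_vector(fit)
        draws = rng.multivariate_normal(coef, vcov, size=n_draws, method="svd")
        diffs_all = np.empty(n_draws)
        diffs_hot = np.empty(n_draws)
        for b in range(n_draws):
            a0, h0 = result_baseline.deaths_for_coefs(draws[b])
            a1, h1 = result_scenario.deaths_for_coefs(draws[b])
            diffs_all[b] = a0 - a1
            diffs_hot[b] = h0 - h1
        ci_all = tuple(np.percentile(diffs_all, [2.5, 97.5]))
        ci_hot = tuple(np.percentile(diffs_hot, [2.5, 97.5]))
    return LivesSaved(
        scenario_climate=result_scenario.scenario_climate,
        scenario_forecast=result_scenario.scenario_forecast,
        all_days=point_all,
        hot_days=point_hot,
        all_days_ci=ci_all,
        hot_days_ci=ci_hot,
        n_draws=n_draws if vcov is not None else 0,
    )
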