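"""Synthetic county panels, expert responses, and climate paths.

The real analysis draws on restricted county mortality data, archived
day-ahead forecasts, gridded weather observations and climate-model
output.  This module generates fully synthetic stand-ins with the
statistical structure the downstream estimators assume, so the whole
chain — design construction, fixed-effects estimation, conditional
error modelling, elicitation aggregation and projection — can be
exercised and verified by parameter recovery at desk scale.

Conventions: a "noleap" 365-day calendar (Feb 29 never appears), so a
calendar day can be shifted across years without ambiguity; all
temperatures are daily means in degrees Celsius; the forecast error is
forecast minus realization, so positive errors mean the forecast ran
too warm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .basis import BasisSpec, build_daily_design, N_BASIS

__all__ = [
    "CountyProfile",
    "TruthSurface",
    "ExpertResponse",
    "ClimateScenarioSpec",
    "ErrorProcess",
    "generate_counties",
    "simulate_daily_weather",
    "simulate_forecast_errors",
    "make_truth_surface",
    "simulate_mortality",
    "impute_missing_mortality",
    "simulate_expert_responses",
    "historical_accuracy_pairs",
    "make_climate_scenario",
    "counties_frame",
]

# default error-spline knots (degC), typical of observed day-ahead
# forecast-error distributions at the 5/35/65/95th percentiles
DEFAULT_KNOTS = (-1.7, -0.4, 0.3, 1.8)


@dataclass(frozen=True)
class CountyProfile:
    """Static attributes of one synthetic county."""

    county_id: str
    state_id: str
    wfo_id: str
    population_base: float  # base-year persons, used as regression weight
    mean_temp: float  # climatological annual mean, degC
    seasonal_amp: float  # amplitude of the seasonal sinusoid, degC
    day_to_day_sd: float  # stationary SD of the AR(1) daily anomaly, degC
    error_sd0: float  # initial forecast-error SD, degC
    ac_takeup: float  # air-conditioning take-up fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.population_base <= 0:
            raise ValueError("population_base must be positive")
        if not 0.0 <= self.ac_takeup <= 1.0:
            raise ValueError("ac_takeup must lie in [0, 1]")


def generate_counties(
    n_counties: int,
    n_states: int,
    n_wfos: int,
    seed: int,
    mean_temp_range: tuple[float, float] = (2.0, 24.0),
    error_sd0_range: tuple[float, float] = (0.8, 2.0),
) -> list[CountyProfile]:
    """Draw heterogeneous county profiles partitioned into states and WFOs.

    Every state and every weather forecast office (WFO) receives at least
    one county; remaining counties are assigned uniformly at random.
    Deterministic given ``seed``.
    """
    if n_counties < 1 or n_states < 1 or n_wfos < 1:
        raise ValueError("counts must be positive")
    if n_counties < n_states or n_counties < n_wfos:
        raise ValueError("need at least as many counties as states and WFOs")
    rng = np.random.default_rng(seed)

    def _partition(n_groups: int) -> np.ndarray:
        ids = np.concatenate(
            [np.arange(n_groups), rng.integers(0, n_groups, size=n_counties - n_groups)]
        )
        return rng.permutation(ids)

    state_of = _partition(n_states)
    wfo_of = _partition(n_wfos)
    profiles = []
    for i in range(n_counties):
        profiles.append(
            CountyProfile(
                county_id=f"C{i:04d}",
                state_id=f"S{state_of[i]:03d}",
                wfo_id=f"W{wfo_of[i]:03d}",
                population_base=float(np.round(rng.lognormal(mean=10.5, sigma=1.0))) + 1.0,
                mean_temp=float(rng.uniform(*mean_temp_range)),
                seasonal_amp=float(rng.uniform(6.0, 14.0)),
                day_to_day_sd=float(rng.uniform(1.5, 4.0)),
                error_sd0=float(rng.uniform(*error_sd0_range)),
                ac_takeup=float(rng.uniform(0.1, 0.95)),
            )
        )
    return profiles


def counties_frame(counties: Sequence[CountyProfile]) -> pd.DataFrame:
    """Static county table (one row per county)."""
    return pd.DataFrame([vars(c) for c in counties])


def _noleap_dates(years: Sequence[int]) -> pd.DatetimeIndex:
    idx = pd.date_range(f"{min(years)}-01-01", f"{max(years)}-12-31", freq="D")
    return idx[~((idx.month == 2) & (idx.day == 29))]


def simulate_daily_weather(
    counties: Sequence[CountyProfile],
    years: Sequence[int],
    seed: int,
    ar_coef: float = 0.7,
    precip_wet_prob: float = 0.35,
) -> pd.DataFrame:
    """County-day realized weather: seasonal sinusoid plus AR(1) anomaly.

    ``temp = mean_temp + seasonal_amp * cos(2*pi*(doy - 207)/365)`` plus a
    stationary AR(1) anomaly whose marginal SD is ``day_to_day_sd`` (the
    seasonal peak near day 207 mimics a late-July maximum).  Precipitation
    is an intermittent gamma process in millimetres.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("years must be nonempty")
    rng = np.random.default_rng(seed)
    dates = _noleap_dates(years)
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    # in a noleap calendar day-of-year from pandas still counts Feb 29 slots
    doy = doy - (dates.is_leap_year & (doy > 59)).astype(float)
    season = np.cos(2.0 * np.pi * (doy - 207.0) / 365.0)

    frames = []
    for c in counties:
        innov_sd = c.day_to_day_sd * np.sqrt(max(1.0 - ar_coef**2, 1e-12))
        eps = rng.normal(0.0, innov_sd, size=n)
        anom = signal.lfilter([1.0], [1.0, -ar_coef], eps)
        temp = c.mean_temp + c.seasonal_amp * season + anom
        wet = rng.random(n) < precip_wet_prob
        precip = np.where(wet, rng.gamma(shape=1.2, scale=5.0, size=n), 0.0)
        frames.append(
            pd.DataFrame(
                {"county_id": c.county_id, "date": dates, "temp": temp, "precip": precip}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _const(v: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda T: np.full_like(np.asarray(T, float), v)


def _default_mean_curve(T):
    # too-warm forecasts on cold days, too-cool on hot days
    return 0.3 - 0.02 * np.asarray(T, float)


def _default_skew_curve(T):
    # skew-normal shape: positive skew when cold, negative when hot.
    # |shape| ~ 3 at the temperature extremes gives moment skewness ~ 0.6
    return np.clip((15.0 - np.asarray(T, float)) / 5.0, -4.0, 4.0)


@dataclass(frozen=True)
class ErrorProcess:
    """Conditional law of day-ahead forecast errors given temperature.

    ``sd_curve`` is a temperature-shape multiplier applied to each
    county's ``error_sd0``; the SD additionally shrinks (or grows) by
    ``sd_annual_trend`` proportionally per year.  Excess kurtosis on hot
    days comes from a two-point scale mixture (``tail_prob`` of days get
    their standardized draw inflated by ``tail_scale``, with the overall
    variance renormalized), which keeps all moments available in closed
    form.
    """

    mean_curve: Callable = _default_mean_curve
    sd_curve: Callable = _const(1.0)
    sd_annual_trend: float = -0.02
    skew_curve: Callable = _const(0.0)
    tail_prob: float = 0.0
    tail_scale: float = 2.5
    tail_temp_threshold: float = 25.0
    year0: int | None = None  # defaults to first year in the records

    def __post_init__(self) -> None:
        if abs(self.sd_annual_trend) >= 1.0:
            raise ValueError("|sd_annual_trend| must be < 1 (proportional per-year change)")
        if not 0.0 <= self.tail_prob < 1.0:
            raise ValueError("tail_prob must lie in [0, 1)")


DEFAULT_ERROR_PROCESS = ErrorProcess(
    skew_curve=_default_skew_curve, tail_prob=0.05, sd_annual_trend=-0.02
)


def simulate_forecast_errors(
    records: pd.DataFrame,
    counties: Sequence[CountyProfile],
    error_process: ErrorProcess = DEFAULT_ERROR_PROCESS,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill forecast and error columns with draws from the conditional law.

    Conditional on temperature and year, errors have mean
    ``mean_curve(T)`` and SD ``error_sd0 * sd_curve(T) *
    (1 + sd_annual_trend)^(year - year0)``; the standardized draw is
    skew-normal with shape ``skew_curve(T)`` (rescaled to zero mean, unit
    variance) and hot days receive the variance-preserving tail mixture.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    T = out["temp"].to_numpy(float)
    year = pd.DatetimeIndex(out["date"]).year.to_numpy()
    year0 = error_process.year0 if error_process.year0 is not None else int(year.min())

    sd0 = pd.Series({c.county_id: c.error_sd0 for c in counties})
    sd_c = sd0.reindex(out["county_id"]).to_numpy(float)
    if np.any(~np.isfinite(sd_c)):
        raise ValueError("records reference counties without profiles")

    shape = np.asarray(error_process.sd_curve(T), float)
    if np.any(shape < 0):
        raise ValueError("sd_curve must be nonnegative")
    sd = sd_c * shape * (1.0 + error_process.sd_annual_trend) ** (year - year0)

    alpha = np.asarray(error_process.skew_curve(T), float)
    n = len(out)
    if np.allclose(alpha, 0.0):
        z = rng.standard_normal(n)
    else:
        u0 = rng.standard_normal(n)
        v = rng.standard_normal(n)
        delta = alpha / np.sqrt(1.0 + alpha**2)
        sn = delta * np.abs(u0) + np.sqrt(1.0 - delta**2) * v
        m = delta * np.sqrt(2.0 / np.pi)
        z = (sn - m) / np.sqrt(1.0 - m**2)

    p, s = error_process.tail_prob, error_process.tail_scale
    if p > 0:
        hot = T > error_process.tail_temp_threshold
        inflate = hot & (rng.random(n) < p)
        norm = np.sqrt(1.0 - p + p * s**2)
        z = np.where(hot, np.where(inflate, z * s, z) / norm, z)

    err = np.asarray(error_process.mean_curve(T), float) + sd * z
    out["error"] = err
    out["forecast"] = out["temp"] + err
    return out


@dataclass(frozen=True)
class TruthSurface:
    """Known data-generating response surface plus nuisance scales.

    ``beta_true`` acts on the 13-column daily basis; the nuisance scales
    parameterize i.i.d. normal county-season intercepts, county-season
    linear trends (per month index), state-time shocks, and observation
    noise.  ``mmt_true`` is the argmin over [10, 35] degC of the implied
    zero-error temperature curve.
    """

    beta_true: np.ndarray
    basis_spec: BasisSpec
    rain_coef: float = 0.0
    baseline_rate: float = 75.0  # monthly deaths per 100,000, absorbed by FEs
    fe_scale_county_month: float = 8.0
    fe_scale_state_time: float = 3.0
    trend_scale: float = 0.01
    noise_sd: float = 5.0
    mmt_true: float = float("nan")

    def __post_init__(self) -> None:
        b = np.asarray(self.beta_true, float)
        if b.shape != (N_BASIS,):
            raise ValueError(f"beta_true must have length {N_BASIS}")
        object.__setattr__(self, "beta_true", b)

    def temp_curve(self, T) -> np.ndarray:
        """Daily excess-rate curve at zero forecast error."""
        X = build_daily_design(np.asarray(T, float), np.zeros_like(np.asarray(T, float)),
                               self.basis_spec)
        return X @ self.beta_true


def make_truth_surface(
    mmt: float = 27.8,
    temp_curv: float = 4.0e-4,
    error_coef: float = 0.015,
    error_temp_gain: float = 2.0e-3,
    knots: Sequence[float] = DEFAULT_KNOTS,
    **nuisance,
) -> TruthSurface:
    """Construct a plausible U-shaped truth surface in the 13-basis.

    The target is ``temp_curv*(T-mmt)^2 + (error_coef +
    error_temp_gain*(max(T,0)/10)^2) * e^2`` (deaths per 100,000 per
    day): mortality is U-shaped in temperature with minimum near ``mmt``,
    convex in the forecast error with minimum at zero, and error
    lethality grows on hot days.  The target is projected onto the basis
    by least squares over a (T, e) grid, and ``mmt_true`` is recomputed
    from the projected curve.
    """
    spec = BasisSpec(error_knots=tuple(knots))
    Tg, eg = np.meshgrid(np.linspace(-15.0, 40.0, 56), np.linspace(-4.0, 4.0, 41))
    Tg, eg = Tg.ravel(), eg.ravel()
    err_target = (error_coef + error_temp_gain * (np.maximum(Tg, 0.0) / 10.0) ** 2) * eg**2
    X = build_daily_design(Tg, eg, spec)
    # error effect lives in the 9 spline/interaction columns only
    beta_err, *_ = np.linalg.lstsq(X[:, 4:], err_target, rcond=None)
    # the spline columns are nonzero at e = 0, which would tilt the
    # zero-error temperature curve; compensate in the polynomial so the
    # planted vertex is exact.  The e = 0 slice of the error block is
    # a0 + a1*T + a2*T^2 with coefficients from the basis at e = 0.
    from .basis import spline_basis

    N0 = spline_basis(np.array(0.0), spec.error_knots)  # (3,)
    a1 = float(N0 @ beta_err[3:6])
    a2 = float(N0 @ beta_err[6:9])
    beta_poly = np.array([-2.0 * mmt * temp_curv - a1, temp_curv - a2, 0.0, 0.0])
    beta = np.concatenate([beta_poly, beta_err])
    ts = TruthSurface(beta_true=beta, basis_spec=spec, mmt_true=float(mmt), **nuisance)
    return ts


def simulate_mortality(
    records: pd.DataFrame,
    counties: Sequence[CountyProfile],
    truth: TruthSurface,
    seed: int,
    return_components: bool = False,
):
    """County-month mortality rates implied by the truth surface.

    Daily excess rates ``basis(T, e_demeaned) . beta_true`` are summed
    within county-months (daily mortality is latent; only monthly sums
    are emitted) and augmented with the baseline level, a rainfall term,
    i.i.d. county-season intercepts, county-season linear trends in the
    consecutive month index, state-time shocks, and observation noise.
    """
    if "error_demeaned" not in records.columns:
        raise ValueError("records must carry demeaned errors (run demean_errors first)")
    rng = np.random.default_rng(seed)
    rec = records.copy()
    contrib = build_daily_design(
        rec["temp"].to_numpy(float), rec["error_demeaned"].to_numpy(float), truth.basis_spec
    ) @ truth.beta_true
    rec["_signal"] = contrib
    rec["year_month"] = pd.DatetimeIndex(rec["date"]).to_period("M")
    monthly = (
        rec.groupby(["county_id", "year_month"], sort=True)[["_signal", "precip"]]
        .sum()
        .rename(columns={"_signal": "signal", "precip": "precip_total"})
        .reset_index()
    )
    med = monthly.groupby("county_id")["precip_total"].transform("median")
    monthly["rain_above_median"] = (monthly["precip_total"] > med).astype(float)
    monthly["month"] = monthly["year_month"].dt.month
    t0 = monthly["year_month"].min()
    monthly["t"] = (monthly["year_month"] - t0).map(lambda d: d.n).astype(int)
    smap = pd.Series({c.county_id: c.state_id for c in counties})
    monthly["state_id"] = smap.reindex(monthly["county_id"]).to_numpy()

    def _group_draw(keys: pd.DataFrame, scale: float) -> np.ndarray:
        codes, _ = pd.factorize(pd.MultiIndex.from_frame(keys), sort=True)
        draws = rng.normal(0.0, 1.0, size=codes.max() + 1)
        return scale * draws[codes]

    lam = _group_draw(monthly[["county_id", "month"]], truth.fe_scale_county_month)
    alph = _group_draw(monthly[["county_id", "month"]], truth.trend_scale)
    rho = _group_draw(monthly[["state_id", "year_month"]], truth.fe_scale_state_time)
    eps = rng.normal(0.0, truth.noise_sd, size=len(monthly)) if truth.noise_sd > 0 else 0.0

    monthly["mortality_rate"] = (
        truth.baseline_rate
        + monthly["signal"]
        + truth.rain_coef * monthly["rain_above_median"]
        + lam
        + alph * monthly["t"]
        + rho
        + eps
    )
    cols = ["county_id", "year_month", "mortality_rate"]
    if return_components:
        comp = monthly.copy()
        comp["fe_county_month"] = lam
        comp["trend_component"] = alph * monthly["t"]
        comp["fe_state_time"] = rho
        comp["noise"] = eps if np.ndim(eps) else np.zeros(len(monthly))
        return monthly[cols].copy(), comp
    return monthly[cols].copy()


def impute_missing_mortality(
    monthly: pd.DataFrame,
    suppression_mask: pd.Series | np.ndarray,
    counties: Sequence[CountyProfile] | pd.DataFrame,
) -> pd.DataFrame:
    """Replace suppressed county-month rates with state-month donor rates.

    The donor is the population-weighted mean rate over unsuppressed
    counties in the same state-month; a state-month with every county
    suppressed has no donor and raises.  An ``imputed`` flag records
    which cells were filled.
    """
    cdf = counties if isinstance(counties, pd.DataFrame) else counties_frame(counties)
    cmap = cdf.set_index("county_id")
    out = monthly.copy()
    mask = np.asarray(suppression_mask, bool)
    if mask.shape != (len(out),):
        raise ValueError("suppression_mask must align with the monthly table rows")
    out["state_id"] = cmap["state_id"].reindex(out["county_id"]).to_numpy()
    out["_w"] = cmap["population_base"].reindex(out["county_id"]).to_numpy(float)
    out["imputed"] = mask

    obs = out.loc[~mask]
    donor = (
        obs.assign(_wr=obs["mortality_rate"] * obs["_w"])
        .groupby(["state_id", "year_month"])[["_wr", "_w"]]
        .sum()
    )
    donor_rate = donor["_wr"] / donor["_w"]

    need = out.loc[mask, ["state_id", "year_month"]]
    key = pd.MultiIndex.from_frame(need)
    missing = ~key.isin(donor_rate.index)
    if missing.any():
        bad = key[missing][0]
        raise ValueError(f"no unsuppressed donor counties in state-month {bad}")
    out.loc[mask, "mortality_rate"] = donor_rate.reindex(key).to_numpy()
    return out.drop(columns=["state_id", "_w"])


@dataclass(frozen=True)
class ExpertResponse:
    """One expert's elicitation record.

    Percentile triplets (p01, p50, p99) are best-case / median /
    worst-case accuracy per horizon; for accuracy metrics smaller is
    better, so p01 <= p50 <= p99.  ``truth_params`` holds the known
    skew-normal (log-scale) law used to generate the record, for
    round-trip tests.
    """

    expert_id: str
    metric: str  # one of MSE, RMSE, MAE
    acc_2005: float
    acc_2020: float
    horizons: Mapping[int, tuple[float, float, float]]
    truth_params: Mapping[int, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.metric not in ("MSE", "RMSE", "MAE"):
            raise ValueError("metric must be MSE, RMSE or MAE")
        for h, (p01, p50, p99) in self.horizons.items():
            if not (0 < p01 <= p50 <= p99):
                raise ValueError(f"horizon {h}: need 0 < p01 <= p50 <= p99")


MAE_LINE = (0.05, 1.22)  # RMSE = a + b * MAE used for the synthetic world


def historical_accuracy_pairs(
    n: int = 40, seed: int = 0, noise_sd: float = 0.02, line: tuple[float, float] = MAE_LINE
) -> pd.DataFrame:
    """Annual (MAE, RMSE) pairs scattered around a known line."""
    rng = np.random.default_rng(seed)
    a, b = line
    mae = rng.uniform(0.6, 1.8, size=n)
    rmse = a + b * mae + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"mae": mae, "rmse": rmse})


def simulate_expert_responses(
    n_experts: int,
    seed: int,
    truth_laws: Mapping[int, Sequence[tuple[float, float, float]]] | None = None,
    mae_fraction: float = 0.3,
    mse_fraction: float = 0.1,
) -> list[ExpertResponse]:
    """Experts whose percentile triplets are exact quantiles of known laws.

    Each expert's multiplicative RMSE change at horizon h follows
    ``exp(skew-normal(xi, omega, alpha))``; their reported accuracies are
    their 2020 accuracy scaled by the 1st/50th/99th quantiles of that
    law.  A configurable subset reports in MAE (mapped through the known
    linear MAE-RMSE relation) or in MSE (squared RMSE).
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = MAE_LINE
    responses = []
    for i in range(n_experts):
        rmse_2020 = float(rng.uniform(1.0, 2.0))
        rmse_2005 = rmse_2020 / float(rng.uniform(0.6, 0.75))
        laws = {}
        for h, log_center in ((2050, np.log(0.8)), (2100, np.log(0.55))):
            if truth_laws is not None:
                xi, omega, alpha = truth_laws[h][i]
            else:
                xi = float(rng.normal(log_center, 0.15))
                omega = float(rng.uniform(0.15, 0.45))
                alpha = float(rng.uniform(-2.5, 2.5))
            laws[h] = (xi, omega, alpha)
        horizons = {}
        for h, (xi, omega, alpha) in laws.items():
            q = stats.skewnorm.ppf([0.01, 0.5, 0.99], alpha, loc=xi, scale=omega)
            horizons[h] = tuple(rmse_2020 * np.exp(q))
        u = rng.random()
        if u < mae_fraction:
            metric = "MAE"
            conv = lambda r: (r - a) / b
        elif u < mae_fraction + mse_fraction:
            metric = "MSE"
            conv = lambda r: r**2
        else:
            metric = "RMSE"
            conv = lambda r: r
        responses.append(
            ExpertResponse(
                expert_id=f"E{i:03d}",
                metric=metric,
                acc_2005=conv(rmse_2005),
                acc_2020=conv(rmse_2020),
                horizons={h: tuple(conv(np.asarray(v))) for h, v in horizons.items()},
                truth_params=laws,
            )
        )
    return responses


def parameter_recovery_experiment(
    n_replicates: int = 20,
    n_counties: int = 200,
    n_states: int = 20,
    n_wfos: int = 58,
    n_years: int = 10,
    seed: int = 0,
    truth: TruthSurface | None = None,
) -> dict:
    """Monte-Carlo check that the estimation chain recovers the truth.

    Each replicate simulates a fresh county panel from a known response
    surface, runs the full design-construction and within-estimation
    chain, and records whether every coefficient lies within 3 clustered
    SEs of the truth and whether each 95% CI covers it.  Returns the
    per-replicate hit indicators, coverage rates, z-statistics, and the
    final replicate's fit.

    The default cluster count is half the study region's 116 forecast
    offices: scaling counties down without scaling offices down as far
    keeps enough clusters for the sandwich variance to be well-behaved.
    """
    from . import basis as _basis
    from . import panelfit as _panelfit
    from . import projection as _projection

    truth = truth if truth is not None else make_truth_surface()
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=(n_replicates, 4))
    within3, covered, zstats, mmts = [], [], [], []
    for r in range(n_replicates):
        s = rep_seeds[r]
        counties = generate_counties(n_counties, n_states, n_wfos, int(s[0]))
        weather = simulate_daily_weather(counties, range(2005, 2005 + n_years), int(s[1]))
        rec = simulate_forecast_errors(weather, counties, DEFAULT_ERROR_PROCESS, int(s[2]))
        rec = _basis.demean_errors(rec, "county")
        monthly = simulate_mortality(rec, counties, truth, int(s[3]))
        design, _ = _basis.aggregate_monthly(rec, monthly, counties_frame(counties),
                                             truth.basis_spec)
        fit = _panelfit.fit_panel(design)
        z = (fit.beta - truth.beta_true) / fit.se
        zstats.append(z)
        within3.append(bool(np.all(np.abs(z) < 3.0)))
        covered.append(np.abs(z) < 1.96)
        mmts.append(_projection.find_mmt(fit))
    return {
        "mmt_estimates": np.array(mmts),
        "within3": np.array(within3),
        "within3_rate": float(np.mean(within3)),
        "coverage": float(np.mean(covered)),
        "zstats": np.array(zstats),
        "truth": truth,
        "last_fit": fit,
    }


@dataclass(frozen=True)
class ClimateScenarioSpec:
    """An end-century warming scenario relative to a reference period."""

    name: str
    warming_delta: float  # degC added by the start of the evaluation window
    eval_years: tuple[int, ...] = tuple(range(2095, 2101))
    reference_years: tuple[int, ...] = tuple(range(2015, 2021))

    def __post_init__(self) -> None:
        for ys in (self.eval_years, self.reference_years):
            if list(ys) != list(range(min(ys), min(ys) + len(ys))):
                raise ValueError("year windows must be consecutive")


def make_climate_scenario(records: pd.DataFrame, spec: ClimateScenarioSpec) -> pd.DataFrame:
    """Future county-day temperatures under a warming scenario.

    The i-th evaluation year copies the i-th reference year's daily
    temperatures (a no-change scenario with ``warming_delta = 0`` is an
    exact copy), plus a linear ramp that starts after the reference
    window and reaches ``warming_delta`` at the first evaluation year, so
    the full delta applies throughout the evaluation window.
    """
    years = pd.DatetimeIndex(records["date"]).year
    ref = sorted(spec.reference_years)
    ev = sorted(spec.eval_years)
    if len(ev) != len(ref):
        raise ValueError("eval and reference windows must have equal length")
    missing = set(ref) - set(years)
    if missing:
        raise ValueError(f"reference years missing from records: {sorted(missing)}")
    ramp_start, ramp_end = ref[-1], ev[0]
    frames = []
    for ry, ey in zip(ref, ev):
        block = records.loc[years == ry, ["county_id", "date", "temp"]].copy()
        block["date"] = block["date"] + pd.DateOffset(years=ey - ry)
        frac = 1.0 if ramp_end == ramp_start else np.clip(
            (ey - ramp_start) / (ramp_end - ramp_start), 0.0, 1.0
        )
        block["temp"] = block["temp"] + spec.warming_delta * frac
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["scenario"] = spec.name
    return out
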