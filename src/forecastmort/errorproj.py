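"""Conditional forecast-error modelling and scenario-consistent simulation.

Three-stage procedure: (1) the conditional mean of day-ahead errors is a
population-weighted linear regression on a natural cubic spline of
temperature (boundary knots -15/35 degC, internal knots every 5 degC)
plus WFO intercepts; (2) the conditional variance of mean-deviations is
a Gamma GLM with log link on the same spline, WFO intercepts, and a
linear annual trend (the log link keeps extrapolated variances positive
and encodes proportional year-on-year accuracy gains); (3) historical
errors are standardized by the fitted mean/SD and pooled into 5 degC
realized-temperature bins, from which future standardized errors are
resampled so higher conditional moments (skewness, fat tails) carry into
the projections.

Forecast-accuracy scenarios rescale the variance trend: the adjusted
trend is solved so that the implied national RMSE over an end-century
climate panel hits an elicitation-derived target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .basis import natural_spline_basis

__all__ = [
    "TEMP_SPLINE_KNOTS",
    "ErrorMeanModel",
    "ErrorVarianceModel",
    "StandardizedErrorPool",
    "ScenarioTrend",
    "fit_error_mean",
    "fit_error_variance",
    "standardize_errors",
    "implied_national_rmse",
    "calibrate_scenario_trend",
    "sample_future_errors",
]

TEMP_SPLINE_KNOTS = tuple(float(k) for k in range(-15, 36, 5))

SCENARIO_NAMES = ("constant", "slowed", "central", "accelerated", "zero_error")


def _temp_spline(T) -> np.ndarray:
    return natural_spline_basis(np.asarray(T, float), TEMP_SPLINE_KNOTS)


def _wfo_dummies(wfo: np.ndarray, levels: np.ndarray) -> np.ndarray:
    codes = pd.Categorical(wfo, categories=levels).codes
    if np.any(codes < 0):
        raise ValueError("records contain WFOs unseen at fit time")
    D = np.zeros((len(wfo), len(levels)))
    D[np.arange(len(wfo)), codes] = 1.0
    return D


def _weights_for(records: pd.DataFrame, weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(records))
    w = pd.Series(weights).reindex(records["county_id"]).to_numpy(float)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("invalid or missing county weights")
    return w


@dataclass
class ErrorMeanModel:
    """Conditional mean of forecast errors given temperature and WFO."""

    spline_coef: np.ndarray
    wfo_levels: np.ndarray
    wfo_intercepts: np.ndarray

    def predict(self, T, wfo) -> np.ndarray:
        S = _temp_spline(T)
        D = _wfo_dummies(np.asarray(wfo), self.wfo_levels)
        return S @ self.spline_coef + D @ self.wfo_intercepts


def fit_error_mean(records: pd.DataFrame, weights=None) -> ErrorMeanModel:
    """Weighted least squares of the (demeaned) error on spline(T) + WFO."""
    T = records["temp"].to_numpy(float)
    if T.min() > TEMP_SPLINE_KNOTS[-1] or T.max() < TEMP_SPLINE_KNOTS[0]:
        import warnings

        warnings.warn("temperature support entirely outside the spline knot range; "
                      "predictions are pure extrapolation")
    e = records["error_demeaned" if "error_demeaned" in records else "error"].to_numpy(float)
    w = _weights_for(records, weights)
    levels = np.array(sorted(pd.unique(records["wfo_id"])))
    X = np.column_stack([_temp_spline(T), _wfo_dummies(records["wfo_id"].to_numpy(), levels)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], e * sw, rcond=None)
    k = len(TEMP_SPLINE_KNOTS) - 1
    return ErrorMeanModel(spline_coef=coef[:k], wfo_levels=levels, wfo_intercepts=coef[k:])


@dataclass
class ErrorVarianceModel:
    """Gamma GLM (log link) for squared mean-deviations of errors.

    The linear predictor is ``h_sigma(T) + WFO + delta * (year -
    year_ref)``; scenario adjustments replace ``delta`` from
    ``last_sample_year`` forward only, leaving the in-sample fit intact.
    """

    spline_coef: np.ndarray
    wfo_levels: np.ndarray
    wfo_intercepts: np.ndarray
    delta: float  # per-year log-variance trend
    delta_se: float
    year_ref: int
    last_sample_year: int
    coef_se: np.ndarray = field(default=None, repr=False)

    def log_variance(self, T, wfo, year, delta_override: float | None = None) -> np.ndarray:
        S = _temp_spline(T)
        D = _wfo_dummies(np.asarray(wfo), self.wfo_levels)
        year = np.asarray(year, float)
        eta = S @ self.spline_coef + D @ self.wfo_intercepts
        if delta_override is None:
            return eta + self.delta * (year - self.year_ref)
        yl = self.last_sample_year
        trend = np.where(
            year <= yl,
            self.delta * (year - self.year_ref),
            self.delta * (yl - self.year_ref) + delta_override * (year - yl),
        )
        return eta + trend

    def sigma(self, T, wfo, year, delta_override: float | None = None) -> np.ndarray:
        return np.exp(0.5 * self.log_variance(T, wfo, year, delta_override))


def fit_error_variance(
    records: pd.DataFrame, mean_model: ErrorMeanModel, weights=None
) -> ErrorVarianceModel:
    """Fit the log-link Gamma GLM of squared mean-deviations."""
    T = records["temp"].to_numpy(float)
    e = records["error_demeaned" if "error_demeaned" in records else "error"].to_numpy(float)
    wfo = records["wfo_id"].to_numpy()
    year = pd.DatetimeIndex(records["date"]).year.to_numpy(float)
    mu = mean_model.predict(T, wfo)
    y = (e - mu) ** 2
    if np.all(y <= 0):
        raise ValueError("all squared deviations are zero; variance model is degenerate")
    y = np.maximum(y, 1e-12)
    w = _weights_for(records, weights)
    year_ref = int(year.min())
    X = np.column_stack(
        [_temp_spline(T), _wfo_dummies(wfo, mean_model.wfo_levels), year - year_ref]
    )
    # log-linear LS start values stabilize the IRLS
    sw = np.sqrt(w)
    start, *_ = np.linalg.lstsq(X * sw[:, None], np.log(y) * sw, rcond=None)
    glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()), var_weights=w)
    res = glm.fit(start_params=start, maxiter=200)
    k = len(TEMP_SPLINE_KNOTS) - 1
    nw = len(mean_model.wfo_levels)
    return ErrorVarianceModel(
        spline_coef=res.params[:k],
        wfo_levels=mean_model.wfo_levels,
        wfo_intercepts=res.params[k : k + nw],
        delta=float(res.params[-1]),
        delta_se=float(res.bse[-1]),
        year_ref=year_ref,
        last_sample_year=int(year.max()),
        coef_se=np.asarray(res.bse),
    )


@dataclass
class StandardizedErrorPool:
    """Standardized errors grouped by 5 degC realized-temperature bin.

    Bin key is the lower edge (a multiple of 5); intervals are half-open
    [lo, lo+5) with open-ended extremes handled by nearest-nonempty-bin
    fallback at sampling time.
    """

    bins: dict[int, np.ndarray]

    @staticmethod
    def bin_of(T) -> np.ndarray:
        return (np.floor(np.asarray(T, float) / 5.0) * 5).astype(int)

    def lookup(self, key: int) -> tuple[int, np.ndarray]:
        """Return (resolved key, pool); falls back to the nearest nonempty bin."""
        if key in self.bins:
            return key, self.bins[key]
        keys = np.array(sorted(self.bins))
        if keys.size == 0:
            raise ValueError("empty standardized-error pool")
        near = int(keys[np.argmin(np.abs(keys - key))])
        return near, self.bins[near]

    @property
    def all_values(self) -> np.ndarray:
        return np.concatenate([self.bins[k] for k in sorted(self.bins)])


def standardize_errors(
    records: pd.DataFrame, mean_model: ErrorMeanModel, var_model: ErrorVarianceModel
) -> StandardizedErrorPool:
    """Pool ((e - mu_hat) / sigma_hat) by 5 degC temperature bin."""
    T = records["temp"].to_numpy(float)
    e = records["error_demeaned" if "error_demeaned" in records else "error"].to_numpy(float)
    wfo = records["wfo_id"].to_numpy()
    year = pd.DatetimeIndex(records["date"]).year.to_numpy(float)
    mu = mean_model.predict(T, wfo)
    sigma = var_model.sigma(T, wfo, year)
    z = (e - mu) / sigma
    keys = StandardizedErrorPool.bin_of(T)
    order = np.argsort(keys, kind="stable")
    bins = {
        int(k): z[order][sl]
        for k, sl in zip(*_runs(keys[order]))
    }
    return StandardizedErrorPool(bins=bins)


def _runs(sorted_keys: np.ndarray):
    uniq, starts = np.unique(sorted_keys, return_index=True)
    stops = np.append(starts[1:], len(sorted_keys))
    return uniq, [slice(a, b) for a, b in zip(starts, stops)]


@dataclass(frozen=True)
class ScenarioTrend:
    """A forecast-accuracy scenario expressed as an adjusted variance trend."""

    name: str
    delta_adjusted: float
    target_rmse_2100: float
    calibration: dict = field(default_factory=dict)

    @property
    def zero_error(self) -> bool:
        return self.name == "zero_error"


def implied_national_rmse(
    var_model: ErrorVarianceModel,
    mean_model: ErrorMeanModel,
    climate_panel: pd.DataFrame,
    weights=None,
    delta_override: float | None = None,
) -> float:
    """Population-weighted RMSE about zero implied over a climate panel.

    RMSE is measured about zero error, so both the conditional bias and
    the conditional SD contribute: sqrt(weighted mean of sigma^2 + mu^2).
    """
    if len(climate_panel) == 0:
        raise ValueError("empty climate panel")
    T = climate_panel["temp"].to_numpy(float)
    wfo = climate_panel["wfo_id"].to_numpy()
    year = pd.DatetimeIndex(climate_panel["date"]).year.to_numpy(float)
    mu = mean_model.predict(T, wfo)
    s2 = np.exp(var_model.log_variance(T, wfo, year, delta_override))
    w = _weights_for(climate_panel, weights)
    return float(np.sqrt(np.average(s2 + mu**2, weights=w)))


def calibrate_scenario_trend(
    var_model: ErrorVarianceModel,
    mean_model: ErrorMeanModel,
    target_rmse_2100: float,
    future_climate: pd.DataFrame,
    weights=None,
    name: str = "central",
) -> ScenarioTrend:
    """Solve for the variance trend that hits a 2100 national-RMSE target.

    The implied RMSE is strictly increasing in the trend, so a bracketed
    one-dimensional root find suffices.  The ``constant`` scenario pins
    the trend at zero after the sample end, and ``zero_error`` bypasses
    calibration entirely.
    """
    if name == "zero_error":
        return ScenarioTrend(name=name, delta_adjusted=float("-inf"),
                             target_rmse_2100=0.0, calibration={"bypass": True})
    if name == "constant":
        rmse = implied_national_rmse(var_model, mean_model, future_climate, weights, 0.0)
        return ScenarioTrend(name=name, delta_adjusted=0.0, target_rmse_2100=rmse,
                             calibration={"pinned": True})
    if target_rmse_2100 <= 0:
        raise ValueError("target RMSE must be positive (use the zero_error scenario)")
    # the squared-bias floor bounds attainable RMSE from below
    T = future_climate["temp"].to_numpy(float)
    wfo = future_climate["wfo_id"].to_numpy()
    mu = mean_model.predict(T, wfo)
    w = _weights_for(future_climate, weights)
    floor = float(np.sqrt(np.average(mu**2, weights=w)))
    if target_rmse_2100 <= floor:
        raise ValueError(
            f"target {target_rmse_2100:.4g} degC unreachable: conditional-bias floor is "
            f"{floor:.4g} degC"
        )

    def gap(delta: float) -> float:
        return (
            implied_national_rmse(var_model, mean_model, future_climate, weights, delta)
            - target_rmse_2100
        )

    lo, hi = var_model.delta - 0.5, var_model.delta + 0.5
    for _ in range(60):
        if gap(lo) < 0:
            break
        lo -= 0.5
    for _ in range(60):
        if gap(hi) > 0:
            break
        hi += 0.5
    sol = optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14)
    resid = abs(gap(sol))
    if resid > 1e-6:
        raise RuntimeError(f"calibration residual {resid:.2e} degC exceeds tolerance")
    return ScenarioTrend(
        name=name,
        delta_adjusted=float(sol),
        target_rmse_2100=float(target_rmse_2100),
        calibration={"residual_degC": resid, "bracket": (lo, hi),
                     "delta_hat": var_model.delta},
    )


def sample_future_errors(
    future_climate: pd.DataFrame,
    mean_model: ErrorMeanModel,
    var_model: ErrorVarianceModel,
    scenario: ScenarioTrend,
    pool: StandardizedErrorPool,
    seed: int,
) -> pd.DataFrame:
    """Draw forecast errors for each future county-day.

    Each day resamples a standardized error uniformly with replacement
    from its 5 degC temperature bin (nearest nonempty bin as fallback)
    and reconstructs ``e = mu_hat + sigma_hat(scenario, year) * z``.
    """
    out = future_climate.copy()
    n = len(out)
    if scenario.zero_error:
        out["error"] = np.zeros(n)
        return out
    rng = np.random.default_rng(seed)
    T = out["temp"].to_numpy(float)
    wfo = out["wfo_id"].to_numpy()
    year = pd.DatetimeIndex(out["date"]).year.to_numpy(float)
    mu = mean_model.predict(T, wfo)
    sigma = var_model.sigma(T, wfo, year, delta_override=scenario.delta_adjusted)
    keys = StandardizedErrorPool.bin_of(T)
    z = np.empty(n)
    for key in np.unique(keys):
        mask = keys == key
        _, vals = pool.lookup(int(key))
        z[mask] = vals[rng.integers(0, len(vals), size=int(mask.sum()))]
    out["error"] = mu + sigma * z
    return out
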