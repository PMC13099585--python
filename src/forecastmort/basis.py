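"""Daily temperature x forecast-error design and monthly aggregation.

The mortality model is linear in a 13-dimensional daily basis: a
fourth-order polynomial in realized daily-mean temperature ``T`` (columns
1-4), a three-column natural cubic spline in the demeaned day-ahead
forecast error ``e`` (columns 5-7), and the spline interacted with ``T``
and ``T^2`` (columns 8-13).  Because mortality is observed monthly, the
daily basis is summed within each county-month; under additive daily
effects the monthly regression recovers the same coefficients as the
(unobservable) daily regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BasisSpec",
    "demean_errors",
    "resolve_knots",
    "natural_spline_basis",
    "spline_basis",
    "build_daily_basis",
    "build_daily_design",
    "aggregate_monthly",
    "weighted_quantile",
]

N_BASIS = 13

DEMEAN_LEVELS = ("county", "county-month", "county-month-tempbin", "none")


@dataclass(frozen=True)
class BasisSpec:
    """Configuration of the daily design.

    ``error_knots`` may be given directly in degrees Celsius, or resolved
    from percentile targets of the population-weighted forecast-error
    distribution (internal knots at the 35th/65th percentiles, boundary
    knots at the 5th/95th).
    """

    poly_degree: int = 4
    knot_percentiles: tuple[float, float, float, float] = (5.0, 35.0, 65.0, 95.0)
    error_knots: tuple[float, float, float, float] | None = None
    interaction_degree: int = 2

    def __post_init__(self) -> None:
        if self.error_knots is not None:
            k = np.asarray(self.error_knots, dtype=float)
            if k.size != 4 or np.any(np.diff(k) <= 0):
                raise ValueError("error_knots must be 4 strictly increasing values")

    @property
    def resolved(self) -> bool:
        return self.error_knots is not None


def weighted_quantile(values, quantiles, weights=None) -> np.ndarray:
    """Weighted empirical quantiles (Hazen plotting positions).

    With equal weights this agrees with ``np.percentile`` up to the usual
    O(1/n) difference between plotting-position conventions.
    """
    values = np.asarray(values, dtype=float)
    quantiles = np.atleast_1d(np.asarray(quantiles, dtype=float))
    if values.size == 0:
        raise ValueError("empty values")
    if np.any((quantiles < 0) | (quantiles > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    # Hazen positions: midpoint of each observation's weight mass
    p = (cw - 0.5 * w) / cw[-1]
    return np.interp(quantiles, p, v)


def demean_errors(records: pd.DataFrame, level: str = "county") -> pd.DataFrame:
    """Subtract group-level mean forecast errors.

    Demeaning adjusts for persistent offsets between the forecast and
    observation products.  ``level`` selects the grouping: ``county``
    (default), ``county-month`` (county x calendar month),
    ``county-month-tempbin`` (additionally by 5 degC realized-temperature
    bin), or ``none`` (raw errors pass through).
    """
    if level not in DEMEAN_LEVELS:
        raise ValueError(f"unknown demeaning level {level!r}; choose from {DEMEAN_LEVELS}")
    if "error" not in records.columns:
        raise ValueError("records must carry an 'error' column")
    out = records.copy()
    if level == "none":
        out["error_demeaned"] = out["error"].to_numpy(dtype=float)
    else:
        keys = [out["county_id"]]
        if level in ("county-month", "county-month-tempbin"):
            keys.append(pd.DatetimeIndex(out["date"]).month)
        if level == "county-month-tempbin":
            keys.append(np.floor(out["temp"].to_numpy(dtype=float) / 5.0).astype(int))
        grp = out.groupby(keys, sort=False)["error"]
        out["error_demeaned"] = out["error"] - grp.transform("mean")
    out.attrs["demean_level"] = level
    return out


def resolve_knots(
    records: pd.DataFrame,
    spec: BasisSpec,
    weights: pd.Series | dict | None = None,
    column: str = "error_demeaned",
) -> BasisSpec:
    """Replace percentile knot targets with weighted empirical quantiles.

    ``weights`` maps county_id to its regression weight (base-year
    population); every day in a county carries the county weight.  Specs
    that already carry numeric knots are returned unchanged.
    """
    if spec.resolved:
        return spec
    e = records[column].to_numpy(dtype=float)
    if weights is None:
        w = None
    else:
        wmap = pd.Series(weights)
        w = wmap.reindex(records["county_id"]).to_numpy(dtype=float)
        if np.any(~np.isfinite(w)):
            raise ValueError("weights missing for some counties")
    q = np.asarray(spec.knot_percentiles, dtype=float) / 100.0
    knots = weighted_quantile(e, q, w)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("resolved knots are not strictly increasing; too few distinct errors")
    return replace(spec, error_knots=tuple(float(k) for k in knots))


def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis without intercept, one column per knot
    minus one.

    With knots ``k_1 < ... < k_K`` the columns are ``N_1(x) = x`` and, for
    ``m = 1..K-2``, ``N_{m+1}(x) = d_m(x) - d_{K-1}(x)`` where
    ``d_j(x) = [(x-k_j)^3_+ - (x-k_K)^3_+] / (k_K - k_j)``.  The basis is
    exactly linear outside the boundary knots (zero second derivative),
    so extrapolation beyond the support of the data is linear.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValueError("need at least 3 increasing knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = knots.size
    xk = x[..., None] - knots  # (..., K)
    t3 = np.where(xk > 0, xk**3, 0.0)
    d = (t3[..., :-1] - t3[..., -1:]) / (knots[-1] - knots[:-1])  # d_1..d_{K-1}
    cols = np.concatenate([x[..., None], d[..., :-1] - d[..., -1:]], axis=-1)
    return cols


def spline_basis(e, knots) -> np.ndarray:
    """Three-column error spline for 4 knots (2 boundary + 2 internal)."""
    knots = np.asarray(knots, dtype=float)
    if knots.size != 4:
        raise ValueError("the error spline uses exactly 4 knots")
    return natural_spline_basis(e, knots)


def build_daily_design(T, e_demeaned, spec: BasisSpec) -> np.ndarray:
    """Vectorized 13-column daily design for arrays of (T, e)."""
    if not spec.resolved:
        raise ValueError("knots not resolved; call resolve_knots first")
    T = np.asarray(T, dtype=float)
    e = np.asarray(e_demeaned, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(e))):
        raise ValueError("non-finite temperature or error")
    N = spline_basis(e, spec.error_knots)  # (..., 3)
    poly = np.stack([T, T**2, T**3, T**4], axis=-1)
    inter = np.concatenate([N * T[..., None], N * (T**2)[..., None]], axis=-1)
    X = np.concatenate([poly, N, inter], axis=-1)
    assert X.shape[-1] == N_BASIS
    return X


def build_daily_basis(T: float, e_demeaned: float, spec: BasisSpec) -> np.ndarray:
    """Single-day 13-vector: (T..T^4, N1..N3, Nj*T, Nj*T^2)."""
    return build_daily_design(np.asarray(T, float), np.asarray(e_demeaned, float), spec)


@dataclass
class AggregationReport:
    """County-months present in one input but not the other."""

    mortality_without_weather: pd.DataFrame = field(default_factory=pd.DataFrame)
    weather_without_mortality: pd.DataFrame = field(default_factory=pd.DataFrame)


X_COLS = [f"X{i}" for i in range(1, N_BASIS + 1)]


def aggregate_monthly(
    records: pd.DataFrame,
    mortality: pd.DataFrame,
    counties: pd.DataFrame,
    spec: BasisSpec,
    rain_reference: str = "county",
) -> tuple[pd.DataFrame, AggregationReport]:
    """Sum the daily basis within county-months and join mortality.

    Parameters
    ----------
    records : county-day table with temp, error_demeaned, precip.
    mortality : county-month table with columns county_id, year_month
        (pandas Period[M] or parseable), mortality_rate.
    counties : static table with county_id, state_id, wfo_id,
        population_base.
    spec : resolved basis spec.
    rain_reference : grouping for the rainfall median ("county",
        "state" or "national"); the indicator flags county-months whose
        total precipitation exceeds the group's median county-month total.

    Returns the monthly design (one row per matched county-month, with
    X1..X13, mortality_rate, rain_above_median, weight, fixed-effect keys
    and the consecutive month index ``t``) plus an exceptions report of
    unmatched county-months.
    """
    if "error_demeaned" not in records.columns:
        raise ValueError("records must carry demeaned errors")
    rec = records.copy()
    X = build_daily_design(
        rec["temp"].to_numpy(float), rec["error_demeaned"].to_numpy(float), spec
    )
    for j, c in enumerate(X_COLS):
        rec[c] = X[:, j]
    rec["year_month"] = pd.DatetimeIndex(rec["date"]).to_period("M")

    agg = rec.groupby(["county_id", "year_month"], sort=True)[X_COLS + ["precip"]].sum()
    agg = agg.rename(columns={"precip": "precip_total"}).reset_index()

    if rain_reference == "county":
        med = agg.groupby("county_id")["precip_total"].transform("median")
    elif rain_reference in ("state", "national"):
        cmap = counties.set_index("county_id")
        if rain_reference == "state":
            st = cmap["state_id"].reindex(agg["county_id"]).to_numpy()
            med = agg.assign(_s=st).groupby("_s")["precip_total"].transform("median")
        else:
            med = pd.Series(agg["precip_total"].median(), index=agg.index)
    else:
        raise ValueError(f"unknown rain_reference {rain_reference!r}")
    agg["rain_above_median"] = (agg["precip_total"] > med).astype(float)

    mort = mortality.copy()
    mort["year_month"] = pd.PeriodIndex(mort["year_month"], freq="M")
    merged = agg.merge(mort, on=["county_id", "year_month"], how="outer", indicator=True)
    report = AggregationReport(
        mortality_without_weather=merged.loc[
            merged["_merge"] == "right_only", ["county_id", "year_month"]
        ].reset_index(drop=True),
        weather_without_mortality=merged.loc[
            merged["_merge"] == "left_only", ["county_id", "year_month"]
        ].reset_index(drop=True),
    )
    design = merged.loc[merged["_merge"] == "both"].drop(columns="_merge").copy()

    cmap = counties.set_index("county_id")
    design["state_id"] = cmap["state_id"].reindex(design["county_id"]).to_numpy()
    design["wfo_id"] = cmap["wfo_id"].reindex(design["county_id"]).to_numpy()
    design["weight"] = cmap["population_base"].reindex(design["county_id"]).to_numpy(float)
    if np.any(~np.isfinite(design["weight"])) or np.any(design["weight"] <= 0):
        raise ValueError("missing or non-positive population weight for some county")
    design["month"] = design["year_month"].dt.month
    t0 = design["year_month"].min()
    design["t"] = (design["year_month"] - t0).map(lambda d: d.n).astype(int)
    design.attrs["knots"] = spec.error_knots
    return design.reset_index(drop=True), report
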