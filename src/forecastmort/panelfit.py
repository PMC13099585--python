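"""Weighted within-estimation of the mortality response surface.

The estimating equation regresses county-month mortality rates on the
summed 13-column daily basis, controlling for a rainfall indicator,
county-season (county x calendar month) intercepts, county-season
linear trends in a consecutive month index, and state x year-month
shocks, weighted by base-year county population.  Standard errors are
clustered at the weather-forecast-office (WFO) level.

The high-dimensional fixed effects are absorbed by weighted alternating
projections (the method of reghdfe): each variable is repeatedly
projected off the span of the county-season {intercept, trend} cells and
the state-time cells until convergence, after which the coefficients
come from weighted least squares on the residualized data.  Degrees of
freedom absorbed by the effects are counted exactly for the intercept
sets via the connected-components rule for two-way fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import N_BASIS, X_COLS, build_daily_design, weighted_quantile, BasisSpec

__all__ = [
    "FitResult",
    "HeterogeneousFitResult",
    "SingleClusterWarning",
    "compute_county_characteristics",
    "winsorize_weighted",
    "fit_panel",
    "fit_heterogeneous_panel",
    "predict_surface",
    "county_hot_day_error_mortality",
    "residualized_ac_association",
]

CHAR_DIMS = ("mu_T", "sigma_T", "rmse")


class SingleClusterWarning(UserWarning):
    """Raised when clustered inference is impossible (one cluster)."""


# ---------------------------------------------------------------------------
# county characteristics


def compute_county_characteristics(records: pd.DataFrame) -> pd.DataFrame:
    """Per-county mean temperature, day-to-day variability, and forecast RMSE.

    ``sigma_T`` is the root-mean-square one-day temperature change over
    adjacent calendar days (the RMSE of a naive persistence forecast);
    counties without at least one adjacent-day pair get NaN and a flag.
    ``rmse`` is the RMS of (forecast - temperature) about zero.
    """
    rows = []
    for cid, g in records.sort_values("date").groupby("county_id", sort=True):
        temp = g["temp"].to_numpy(float)
        dates = pd.DatetimeIndex(g["date"])
        gap = np.diff(dates.to_julian_date())
        adj = np.isclose(gap, 1.0)
        if adj.any():
            d = np.diff(temp)[adj]
            sigma = float(np.sqrt(np.mean(d**2)))
            flagged = False
        else:
            sigma, flagged = float("nan"), True
        err = (g["forecast"] - g["temp"]).to_numpy(float)
        rows.append(
            {
                "county_id": cid,
                "mu_T": float(np.mean(temp)),
                "sigma_T": sigma,
                "rmse": float(np.sqrt(np.mean(err**2))),
                "sigma_T_undefined": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("county_id")


def winsorize_weighted(values, weights=None, p_lo: float = 5.0, p_hi: float = 95.0):
    """Clip values at their weighted lower/upper percentiles.

    Returns ``(clipped, (lo, hi))``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    lo, hi = weighted_quantile(v, [p_lo / 100.0, p_hi / 100.0], weights)
    return np.clip(v, lo, hi), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# fixed-effect absorption


def _segment_sums(codes: np.ndarray, n_groups: int, M: np.ndarray) -> np.ndarray:
    out = np.zeros((n_groups, M.shape[1]))
    np.add.at(out, codes, M)
    return out


class _Absorber:
    """Weighted projection onto county-season {1, t} cells and
    state-time cells, applied alternately until convergence."""

    def __init__(self, design: pd.DataFrame, tol: float = 1e-13, max_iter: int = 2000):
        self.w = design["weight"].to_numpy(float)
        self.t = design["t"].to_numpy(float)
        self.a_codes, a_idx = pd.factorize(
            pd.MultiIndex.from_frame(design[["county_id", "month"]]), sort=True
        )
        self.b_codes, b_idx = pd.factorize(
            pd.MultiIndex.from_frame(design[["state_id", "year_month"]]), sort=True
        )
        self.nA, self.nB = len(a_idx), len(b_idx)
        self.tol, self.max_iter = tol, max_iter
        # per-A-cell weighted moments of {1, t}
        w, t, a = self.w, self.t, self.a_codes
        self.Sw_a = np.bincount(a, w, minlength=self.nA)
        self.Swt_a = np.bincount(a, w * t, minlength=self.nA)
        self.Swtt_a = np.bincount(a, w * t * t, minlength=self.nA)
        self.det_a = self.Sw_a * self.Swtt_a - self.Swt_a**2
        scale = np.maximum(self.Sw_a * self.Swtt_a, 1e-300)
        self.slope_ok = self.det_a > 1e-10 * scale
        self.Sw_b = np.bincount(self.b_codes, w, minlength=self.nB)
        self.n_slope_groups = int(self.slope_ok.sum())
        # trend redundancy: t is constant within each state x year-month
        # cell, so per (state, calendar-month) group the sum of member
        # county trend columns lies in the span of the B dummies (plus
        # A intercepts) -- one lost rank per group with a slope column
        sm_codes, _ = pd.factorize(
            pd.MultiIndex.from_frame(design[["state_id", "month"]]), sort=True
        )
        a_to_sm = np.zeros(self.nA, dtype=int)
        a_to_sm[self.a_codes] = sm_codes
        self.n_trend_redundant = len(np.unique(a_to_sm[self.slope_ok]))

    def _project_a(self, M: np.ndarray) -> None:
        w, t, a = self.w, self.t, self.a_codes
        Swv = _segment_sums(a, self.nA, w[:, None] * M)
        Swtv = _segment_sums(a, self.nA, (w * t)[:, None] * M)
        det = np.where(self.slope_ok, self.det_a, 1.0)
        slope = np.where(
            self.slope_ok[:, None],
            (self.Sw_a[:, None] * Swtv - self.Swt_a[:, None] * Swv) / det[:, None],
            0.0,
        )
        intercept = (Swv - slope * self.Swt_a[:, None]) / self.Sw_a[:, None]
        M -= intercept[a] + slope[a] * t[:, None]

    def _project_b(self, M: np.ndarray) -> None:
        Swv = _segment_sums(self.b_codes, self.nB, self.w[:, None] * M)
        M -= (Swv / self.Sw_b[:, None])[self.b_codes]

    def absorb(self, M: np.ndarray) -> np.ndarray:
        M = np.array(M, dtype=float, copy=True)
        scale = np.maximum(np.sqrt(np.average(M**2, axis=0, weights=self.w)), 1e-300)
        for _ in range(self.max_iter):
            before = M.copy()
            self._project_a(M)
            self._project_b(M)
            delta = np.max(np.abs(M - before) / scale)
            if delta < self.tol:
                break
        return M

    def dof_absorbed(self) -> int:
        """Rank of the absorbed effect space: intercept sets via the
        connected-components rule, plus one per cell with an identified
        trend slope."""
        parent = np.arange(self.nA + self.nB)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ca, cb in zip(self.a_codes, self.b_codes):
            ra, rb = find(ca), find(self.nA + cb)
            if ra != rb:
                parent[rb] = ra
        n_comp = len({find(i) for i in range(self.nA + self.nB)})
        return (self.nA + self.nB - n_comp
                + self.n_slope_groups - self.n_trend_redundant)


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Estimated response-surface coefficients with clustered inference."""

    beta: np.ndarray  # 13 basis coefficients
    rain_coef: float
    vcov: np.ndarray | None  # 13 x 13 cluster-robust covariance
    n_obs: int
    n_clusters: int
    dof_model: int  # regressors + absorbed effects
    knots: tuple[float, float, float, float]
    fe_spec: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("inference unavailable (single cluster)")
        return np.sqrt(np.diag(self.vcov))

    @property
    def basis_spec(self) -> BasisSpec:
        return BasisSpec(error_knots=self.knots)


@dataclass
class HeterogeneousFitResult:
    """Response surface whose coefficients vary with county characteristics.

    ``beta_c = beta_bar + sum_dim char_dim(c) * gamma_dim`` for the
    included heterogeneity dimensions; characteristics were Winsorized
    before estimation and predictions clip to the same bands.
    """

    beta_bar: np.ndarray
    gammas: dict[str, np.ndarray]
    rain_coef: float
    vcov: np.ndarray | None  # full (13 * (1 + n_dims)) square covariance
    n_obs: int
    n_clusters: int
    dof_model: int
    knots: tuple[float, float, float, float]
    winsor_bands: dict[str, tuple[float, float]] = field(default_factory=dict)
    dims: tuple[str, ...] = ()

    @property
    def basis_spec(self) -> BasisSpec:
        return BasisSpec(error_knots=self.knots)

    def county_beta(self, characteristics: dict | pd.Series, clip: bool = True) -> np.ndarray:
        beta = self.beta_bar.copy()
        for dim in self.dims:
            val = float(characteristics[dim])
            if clip and dim in self.winsor_bands:
                lo, hi = self.winsor_bands[dim]
                if val < lo or val > hi:
                    warnings.warn(
                        f"characteristic {dim}={val:.4g} outside Winsorized band "
                        f"[{lo:.4g}, {hi:.4g}]; clipped",
                        stacklevel=2,
                    )
                    val = min(max(val, lo), hi)
            beta = beta + val * self.gammas[dim]
        return beta


def _weighted_ls_cluster(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    clusters: np.ndarray,
    dof_model: int,
    col_names: list[str],
    norms0: np.ndarray,
):
    """WLS on absorbed data plus one-way cluster-robust sandwich.

    ``norms0`` are the pre-absorption weighted column RMS values, used to
    flag regressors wiped out by the fixed effects; the system is solved
    with per-column scaling for conditioning and mapped back exactly.
    """
    norms = np.sqrt(np.average(X**2, axis=0, weights=w))
    dead = norms < 1e-8 * np.maximum(norms0, 1e-300)
    if dead.any():
        bad = [c for c, d in zip(col_names, dead) if d]
        raise ValueError(f"design collinear after fixed-effect absorption: {bad}")
    s = np.where(norms > 0, norms, 1.0)
    Xs = X / s
    XtWXs = (Xs * w[:, None]).T @ Xs
    eigvals = np.linalg.eigvalsh(XtWXs)
    if eigvals[0] <= 1e-11 * max(eigvals[-1], 1e-300):
        _, vecs = np.linalg.eigh(XtWXs)
        bad = [col_names[int(np.argmax(np.abs(vecs[:, 0])))]]
        raise ValueError(f"design collinear after fixed-effect absorption: {bad}")
    coef = np.linalg.solve(XtWXs, (Xs * w[:, None]).T @ y) / s
    XtWX_inv = ((np.linalg.inv(XtWXs) / s).T / s).T
    resid = y - X @ coef

    codes, uniq = pd.factorize(clusters, sort=True)
    G = len(uniq)
    if G < 2:
        warnings.warn(
            "only one cluster: point estimates returned, clustered inference refused",
            SingleClusterWarning,
        )
        return coef, resid, None, G
    n, k_total = len(y), dof_model
    scores = np.zeros((G, X.shape[1]))
    np.add.at(scores, codes, X * (w * resid)[:, None])
    meat = scores.T @ scores
    c = (G / (G - 1)) * ((n - 1) / (n - k_total))
    vcov = c * XtWX_inv @ meat @ XtWX_inv
    return coef, resid, vcov, G


def fit_panel(design: pd.DataFrame, cluster: str = "wfo_id") -> FitResult:
    """Estimate the 13 response-surface coefficients by the weighted
    within-estimator with WFO-clustered standard errors."""
    cols = X_COLS + ["rain_above_median"]
    ab = _Absorber(design)
    M = np.column_stack(
        [design[c].to_numpy(float) for c in cols]
        + [design["mortality_rate"].to_numpy(float)]
    )
    w = design["weight"].to_numpy(float)
    norms0 = np.sqrt(np.average(M[:, :-1] ** 2, axis=0, weights=w))
    M = ab.absorb(M)
    X, y = M[:, :-1], M[:, -1]
    dof_model = X.shape[1] + ab.dof_absorbed()
    coef, resid, vcov, G = _weighted_ls_cluster(
        X, y, w, design[cluster].to_numpy(), dof_model, cols, norms0
    )
    return FitResult(
        beta=coef[:N_BASIS],
        rain_coef=float(coef[N_BASIS]),
        vcov=None if vcov is None else vcov[:N_BASIS, :N_BASIS],
        n_obs=len(y),
        n_clusters=G,
        dof_model=dof_model,
        knots=tuple(design.attrs.get("knots") or (np.nan,) * 4),
        fe_spec={
            "absorbed": ["county x calendar-month", "county x calendar-month trend",
                          "state x year-month"],
            "cluster": cluster,
            "dof_absorbed": ab.dof_absorbed(),
        },
        residuals=resid,
    )


def fit_heterogeneous_panel(
    design: pd.DataFrame,
    characteristics: pd.DataFrame,
    dims: tuple[str, ...] = CHAR_DIMS,
    cluster: str = "wfo_id",
    winsorize: bool = True,
) -> HeterogeneousFitResult:
    """Let the 13 coefficients vary linearly with Winsorized county
    characteristics (annual mean temperature, day-to-day variability,
    forecast RMSE), added as 13-column interaction blocks."""
    if not dims:
        raise ValueError("dims must be nonempty")
    unknown = set(dims) - set(CHAR_DIMS)
    if unknown:
        raise ValueError(f"unknown heterogeneity dims: {sorted(unknown)}")
    missing = set(design["county_id"]) - set(characteristics.index)
    if missing:
        raise ValueError(f"characteristics missing for counties: {sorted(missing)[:5]}")

    pop = design.groupby("county_id")["weight"].first()
    chars = characteristics.loc[pop.index].copy()
    bands: dict[str, tuple[float, float]] = {}
    for dim in dims:
        vals = chars[dim].to_numpy(float)
        if winsorize:
            clipped, band = winsorize_weighted(vals, pop.to_numpy(float))
            chars[dim] = clipped
            bands[dim] = band
        if np.ptp(chars[dim].to_numpy(float)) <= 1e-12:
            raise ValueError(f"characteristic {dim} constant across counties: unidentified")

    cols = X_COLS + ["rain_above_median"]
    blocks = [np.column_stack([design[c].to_numpy(float) for c in cols])]
    names = list(cols)
    for dim in dims:
        cvals = chars[dim].reindex(design["county_id"]).to_numpy(float)
        blocks.append(blocks[0][:, :N_BASIS] * cvals[:, None])
        names += [f"{c}:{dim}" for c in X_COLS]
    Xfull = np.column_stack(blocks)

    ab = _Absorber(design)
    w = design["weight"].to_numpy(float)
    norms0 = np.sqrt(np.average(Xfull**2, axis=0, weights=w))
    M = ab.absorb(np.column_stack([Xfull, design["mortality_rate"].to_numpy(float)]))
    X, y = M[:, :-1], M[:, -1]
    dof_model = X.shape[1] + ab.dof_absorbed()
    coef, resid, vcov, G = _weighted_ls_cluster(
        X, y, w, design[cluster].to_numpy(), dof_model, names, norms0
    )
    gammas = {}
    offset = N_BASIS + 1
    keep = list(range(N_BASIS))
    for j, dim in enumerate(dims):
        sl = slice(offset + j * N_BASIS, offset + (j + 1) * N_BASIS)
        gammas[dim] = coef[sl]
        keep += list(range(sl.start, sl.stop))
    return HeterogeneousFitResult(
        beta_bar=coef[:N_BASIS],
        gammas=gammas,
        rain_coef=float(coef[N_BASIS]),
        vcov=None if vcov is None else vcov[np.ix_(keep, keep)],
        n_obs=len(y),
        n_clusters=G,
        dof_model=dof_model,
        knots=tuple(design.attrs.get("knots") or (np.nan,) * 4),
        winsor_bands=bands,
        dims=tuple(dims),
    )


def predict_surface(fit, T, e, characteristics=None) -> np.ndarray:
    """Fitted daily excess-rate contribution x(T, e) . beta_c.

    For a heterogeneous fit, per-county characteristics are required and
    are clipped to the in-sample Winsorized bands.
    """
    X = build_daily_design(np.asarray(T, float), np.asarray(e, float), fit.basis_spec)
    if isinstance(fit, HeterogeneousFitResult):
        if characteristics is None:
            raise ValueError("heterogeneous fit requires county characteristics")
        beta = fit.county_beta(characteristics)
    else:
        if characteristics is not None:
            raise ValueError("characteristics supplied for a homogeneous fit")
        beta = fit.beta
    return X @ beta


# ---------------------------------------------------------------------------
# air-conditioning diagnostic


def county_hot_day_error_mortality(
    fit, records: pd.DataFrame, characteristics: pd.DataFrame | None = None,
    threshold: float = 20.0
) -> pd.Series:
    """Average daily excess mortality attributable to forecast errors on
    hot days, per county.

    For each county, days with T > threshold are grouped into 1 degC
    bins; the error-attributable excess ``f(T, e) - f(T, 0)`` is averaged
    within bins and combined with weights proportional to the bin
    day-counts per year.
    """
    hot = records.loc[records["temp"] > threshold]
    out = {}
    for cid, g in hot.groupby("county_id", sort=True):
        ch = None if characteristics is None else characteristics.loc[cid]
        T = g["temp"].to_numpy(float)
        e = g["error_demeaned"].to_numpy(float)
        excess = predict_surface(fit, T, e, ch) - predict_surface(
            fit, T, np.zeros_like(T), ch
        )
        bins = np.floor(T - threshold).astype(int)
        df = pd.DataFrame({"bin": bins, "x": excess})
        per_bin = df.groupby("bin")["x"].agg(["mean", "size"])
        out[cid] = float(np.average(per_bin["mean"], weights=per_bin["size"]))
    return pd.Series(out, name="hot_day_error_mortality")


@dataclass
class ACAssociation:
    """Residualized AC take-up vs. error-mortality pairs and lowess fit."""

    ac_resid: np.ndarray
    mort_resid: np.ndarray
    lowess_x: np.ndarray
    lowess_y: np.ndarray
    county_ids: np.ndarray


def residualized_ac_association(
    county_error_mortality: pd.Series,
    ac_takeup: pd.Series,
    characteristics: pd.DataFrame,
    trim_pct: tuple[float, float] = (2.5, 97.5),
    n_drop_lowest: int = 4,
    lowess_frac: float = 2.0 / 3.0,
    lowess_it: int = 3,
) -> ACAssociation:
    """Cross-sectional association between residualized AC take-up and
    residualized hot-day error mortality.

    Both variables are residualized on mean temperature, day-to-day
    variability and forecast RMSE (with intercept); counties outside the
    central AC-residual percentile band are trimmed and the lowest few
    mortality-residual counties (cold low-population outliers in the
    emulated setting) are dropped before lowess smoothing.
    """
    idx = county_error_mortality.index.intersection(ac_takeup.index).intersection(
        characteristics.index
    )
    Z = np.column_stack(
        [
            np.ones(len(idx)),
            characteristics.loc[idx, "mu_T"].to_numpy(float),
            characteristics.loc[idx, "sigma_T"].to_numpy(float),
            characteristics.loc[idx, "rmse"].to_numpy(float),
        ]
    )
    if np.any(~np.isfinite(Z)):
        raise ValueError("characteristics contain non-finite values")

    def _resid(v: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
        return v - Z @ coef

    ac_r = _resid(ac_takeup.loc[idx].to_numpy(float))
    mort_r = _resid(county_error_mortality.loc[idx].to_numpy(float))

    lo, hi = np.percentile(ac_r, trim_pct)
    keep = (ac_r >= lo) & (ac_r <= hi)
    order = np.argsort(mort_r)
    lowest = set(order[:n_drop_lowest].tolist())
    keep &= ~np.isin(np.arange(len(idx)), list(lowest))
    if keep.sum() < 10:
        raise ValueError("fewer than 10 counties remain after trimming")
    smoothed = sm.nonparametric.lowess(
        mort_r[keep], ac_r[keep], frac=lowess_frac, it=lowess_it, return_sorted=True
    )
    return ACAssociation(
        ac_resid=ac_r[keep],
        mort_resid=mort_r[keep],
        lowess_x=smoothed[:, 0],
        lowess_y=smoothed[:, 1],
        county_ids=np.asarray(idx)[keep],
    )
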