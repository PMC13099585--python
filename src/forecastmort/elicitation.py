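"""Expert elicitation: percentile triplets to accuracy distributions.

Each expert reports best-case / median / worst-case future forecast
accuracy (1st / 50th / 99th percentiles, in their preferred metric) for
2050 and 2100, anchored by their reported 2020 accuracy.  Responses are
converted to RMSE, normalized to multiplicative changes, and each
expert's change distribution is modelled as a skew-lognormal — the
exponential of a skew-normal(xi, omega, alpha) — calibrated so its
theoretical percentiles reproduce the reported triplet.  Experts are
pooled into a mixture (equal weights by default, or exponential
performance weights based on hindcast skill), whose quantiles define
accuracy scenarios; an annual RMSE trajectory with constant percentage
change connects the observed record to each 2100 target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthdata import ExpertResponse

__all__ = [
    "SkewLognormalFit",
    "MixtureDistribution",
    "AccuracyScenario",
    "fit_mae_rmse_line",
    "convert_mae_to_rmse",
    "normalize_changes",
    "fit_skew_lognormal",
    "build_mixture",
    "performance_weights",
    "scenario_targets",
    "extrapolate_accuracy_path",
]

SCENARIO_PERCENTILES = {"accelerated": 10.0, "central": 50.0, "slowed": 90.0}


def fit_mae_rmse_line(historical_pairs: pd.DataFrame) -> tuple[float, float]:
    """OLS line RMSE = a + b * MAE from historical office-year pairs."""
    mae = historical_pairs["mae"].to_numpy(float)
    rmse = historical_pairs["rmse"].to_numpy(float)
    if len(mae) < 2 or np.ptp(mae) <= 1e-12:
        raise ValueError("need >= 2 historical pairs with MAE variation")
    b, a = np.polyfit(mae, rmse, 1)
    return float(a), float(b)


def convert_mae_to_rmse(
    response: ExpertResponse, historical_pairs: pd.DataFrame
) -> ExpertResponse:
    """Map a response to RMSE units.

    MAE responses go through the fitted linear MAE-RMSE relation;
    MSE responses through a square root; RMSE responses pass unchanged.
    """
    if response.metric == "RMSE":
        return response
    if response.metric == "MSE":
        conv = lambda x: float(np.sqrt(x))
    else:
        a, b = fit_mae_rmse_line(historical_pairs)
        conv = lambda x: a + b * float(x)
    return replace(
        response,
        metric="RMSE",
        acc_2005=conv(response.acc_2005),
        acc_2020=conv(response.acc_2020),
        horizons={h: tuple(conv(v) for v in trip) for h, trip in response.horizons.items()},
    )


def normalize_changes(response: ExpertResponse) -> dict[int, tuple[float, float, float]]:
    """Percentile triplets of multiplicative accuracy change per horizon.

    Changes are the reported accuracies divided by the 2020 anchor;
    since smaller accuracy values are better, the best case maps to the
    smallest change.  Changes above 1 (expected degradation) are valid.
    """
    if response.acc_2020 is None or response.acc_2020 <= 0:
        raise ValueError(f"expert {response.expert_id}: missing 2020 anchor; excluded")
    return {
        h: tuple(p / response.acc_2020 for p in trip)
        for h, trip in response.horizons.items()
    }


@dataclass(frozen=True)
class SkewLognormalFit:
    """exp(skew-normal(xi, omega, alpha)) calibrated to a percentile triplet."""

    xi: float
    omega: float
    alpha: float
    residuals: tuple[float, float, float] = (0.0, 0.0, 0.0)  # log-scale fit errors
    feasible: bool = True

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = stats.skewnorm.cdf(np.log(x[pos]), self.alpha, self.xi, self.omega)
        return out

    def ppf(self, q) -> np.ndarray:
        return np.exp(stats.skewnorm.ppf(np.asarray(q, float), self.alpha, self.xi, self.omega))


_ALPHA_MAX = 50.0


def _pct_ratio(alpha: float) -> float:
    z = stats.skewnorm.ppf([0.01, 0.5, 0.99], alpha)
    return (z[1] - z[0]) / (z[2] - z[0])


def fit_skew_lognormal(p01: float, p50: float, p99: float) -> SkewLognormalFit:
    """Solve (xi, omega, alpha) so the law's 1st/50th/99th percentiles
    match the reported triplet.

    On the log scale the three percentile equations reduce to one
    equation in alpha for the inner/outer spread ratio, after which
    omega and xi follow linearly.  Triplets more asymmetric than any
    skew-normal can produce get the nearest-feasible shape (|alpha|
    capped) with the residuals recorded.
    """
    if not (0 < p01 <= p50 <= p99):
        raise ValueError("need 0 < p01 <= p50 <= p99")
    if p01 == p99:
        raise ValueError("degenerate triplet (all percentiles equal)")
    L = np.log([p01, p50, p99])
    r_target = (L[1] - L[0]) / (L[2] - L[0])

    r_lo, r_hi = _pct_ratio(_ALPHA_MAX), _pct_ratio(-_ALPHA_MAX)
    feasible = True
    if r_target <= r_lo:
        alpha = _ALPHA_MAX
        feasible = False
    elif r_target >= r_hi:
        alpha = -_ALPHA_MAX
        feasible = False
    else:
        alpha = optimize.brentq(
            lambda a: _pct_ratio(a) - r_target, -_ALPHA_MAX, _ALPHA_MAX,
            xtol=1e-13, rtol=1e-15,
        )
    z = stats.skewnorm.ppf([0.01, 0.5, 0.99], alpha)
    omega = (L[2] - L[0]) / (z[2] - z[0])
    xi = L[1] - omega * z[1]
    fitted = xi + omega * z
    return SkewLognormalFit(
        xi=float(xi), omega=float(omega), alpha=float(alpha),
        residuals=tuple(float(f - l) for f, l in zip(fitted, L)), feasible=feasible,
    )


@dataclass(frozen=True)
class MixtureDistribution:
    """Equal- or performance-weighted mixture of expert change laws."""

    components: tuple[SkewLognormalFit, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("mixture needs at least one component")
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        object.__setattr__(self, "weights", w / w.sum())

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))

    def ppf(self, q) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, float))
        lo = min(float(c.ppf(1e-9)) for c in self.components)
        hi = max(float(c.ppf(1 - 1e-9)) for c in self.components)
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            out[i] = optimize.brentq(
                lambda x: float(self.cdf(np.array([x]))[0]) - qi,
                lo * 0.5 + 1e-12, hi * 2.0, xtol=1e-12, rtol=1e-14,
            )
        return out if out.size > 1 else out


def build_mixture(
    fits: list[SkewLognormalFit], weights: np.ndarray | None = None
) -> MixtureDistribution:
    """Pool expert laws; equal weights unless performance weights given."""
    if weights is None:
        weights = np.full(len(fits), 1.0 / max(len(fits), 1))
    return MixtureDistribution(components=tuple(fits), weights=np.asarray(weights, float))


def performance_weights(
    reported_changes, observed_change: float, lam: float = 20.0
) -> np.ndarray:
    """Exponential hindcast-skill weights, w_i proportional to
    exp(-lam * (y_i - y_obs)^2), normalized to sum 1."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    y = np.asarray(reported_changes, float)
    sq = lam * (y - observed_change) ** 2
    w = np.exp(-(sq - sq.min()))  # shift prevents underflow of every weight
    return w / w.sum()


@dataclass(frozen=True)
class AccuracyScenario:
    """A future-accuracy scenario pinned to a mixture percentile in 2100."""

    name: str
    percentile: float
    target_change_2100: float  # multiplicative RMSE change vs. 2020
    rmse_2100: float  # degC
    trajectory: pd.Series | None = None  # year -> RMSE
    annual_rate: float | None = None  # fitted (1 + r*) - 1 percentage change


def scenario_targets(
    mixture: MixtureDistribution,
    base_rmse_2020: float,
    percentiles: dict[str, float] = SCENARIO_PERCENTILES,
) -> list[AccuracyScenario]:
    """2100 RMSE targets at the mixture's 10th/50th/90th percentiles.

    The accelerated scenario improves to the optimistic 10th percentile,
    the slowed scenario only to the 90th; targets scale the observed
    2020 national RMSE by the corresponding mixture quantile.
    """
    if base_rmse_2020 <= 0:
        raise ValueError("base RMSE must be positive")
    out = []
    for name, pct in percentiles.items():
        change = float(mixture.ppf(pct / 100.0)[0])
        out.append(
            AccuracyScenario(
                name=name, percentile=pct, target_change_2100=change,
                rmse_2100=base_rmse_2020 * change,
            )
        )
    return out


def extrapolate_accuracy_path(
    historical_rmse: pd.Series, target_2100: float, end_year: int = 2100
) -> tuple[float, float, pd.Series]:
    """Constant-percentage-change RMSE path hitting the 2100 target.

    A constant annual percentage change fitted to the history (least
    squares on log first differences) describes the observed record; the
    scenario rescales that rate to r* so that
    ``RMSE(last_year) * (1 + r*)^(2100 - last_year) = target``, which
    keeps every extrapolated value strictly positive.  Returns
    ``(r_hat, r_star, trajectory)``.
    """
    hist = historical_rmse.sort_index()
    if len(hist) < 3:
        raise ValueError("need at least 3 historical years")
    if target_2100 <= 0:
        raise ValueError("target must be positive; use the zero_error scenario instead")
    log_diff = np.diff(np.log(hist.to_numpy(float)))
    step = np.diff(hist.index.to_numpy(float))
    r_hat = float(np.exp(np.sum(log_diff * step) / np.sum(step**2)) - 1.0)
    last_year = int(hist.index[-1])
    last_rmse = float(hist.iloc[-1])
    r_star = float((target_2100 / last_rmse) ** (1.0 / (end_year - last_year)) - 1.0)
    years = np.arange(last_year, end_year + 1)
    traj = pd.Series(last_rmse * (1.0 + r_star) ** (years - last_year), index=years)
    return r_hat, r_star, traj
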