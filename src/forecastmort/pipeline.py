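"""End-to-end pipeline: simulate, fit, error models, elicitation, projection.

Each stage reads the artifacts of upstream stages from ``out_dir``,
writes its own artifacts plus a manifest (inputs, outputs, seed,
duration, config hash), and is idempotent: re-running with an unchanged
configuration hash skips work.  Stage seeds are derived from the master
seed so the whole run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import basis, elicitation, errorproj, panelfit, projection, synthdata

logger = logging.getLogger("forecastmort")

STAGES = ("simulate", "fit", "errors", "elicit", "project")

DEFAULT_CONFIG: dict = {
    "out_dir": "artifacts",
    "seed": 1,
    "synth": {
        "n_counties": 20,
        "n_states": 5,
        "n_wfos": 4,
        "year_start": 2005,
        "year_end": 2008,
        "sd_annual_trend": -0.02,
        "tail_prob": 0.05,
        "mmt_true": 27.8,
        "noise_sd": 5.0,
        "n_experts": 11,
    },
    "basis": {"demean_level": "county", "knot_percentiles": [5.0, 35.0, 65.0, 95.0]},
    "fit": {"cluster": "wfo_id", "heterogeneity": []},
    "elicit": {"lam": 20.0, "weighting": "equal"},
    "project": {
        "window": 3,
        "eval_end": 2100,
        "climate_deltas": {"no_change": 0.0, "moderate": 1.6, "intermediate": 2.7, "high": 3.8},
        "forecast_scenarios": ["constant", "slowed", "central", "accelerated", "zero_error"],
        "hot_threshold": 20.0,
        "n_ci_draws": 200,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(overrides: dict | None = None) -> dict:
    return _merge(DEFAULT_CONFIG, overrides or {})


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_seed(config: dict, stage: str) -> int:
    h = hashlib.sha256(f"{config['seed']}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class StageContext:
    config: dict
    out_dir: Path
    hash: str

    def path(self, name: str) -> Path:
        return self.out_dir / name

    def manifest_path(self, stage: str) -> Path:
        return self.out_dir / f"manifest_{stage}.json"

    def up_to_date(self, stage: str) -> bool:
        p = self.manifest_path(stage)
        if not p.exists():
            return False
        try:
            return json.loads(p.read_text()).get("config_hash") == self.hash
        except json.JSONDecodeError:
            return False

    def write_manifest(self, stage: str, inputs: list[str], outputs: list[str],
                       seed: int, t0: float) -> None:
        self.manifest_path(stage).write_text(
            json.dumps(
                {
                    "stage": stage,
                    "config_hash": self.hash,
                    "inputs": inputs,
                    "outputs": outputs,
                    "seed": seed,
                    "duration_s": round(time.time() - t0, 3),
                },
                indent=2,
            )
        )

    def require(self, stage: str, names: list[str]) -> None:
        missing = [n for n in names if not self.path(n).exists()]
        if missing:
            raise FileNotFoundError(
                f"stage '{stage}' needs upstream artifacts {missing}; "
                f"run the earlier stages first"
            )


def make_context(config: dict) -> StageContext:
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return StageContext(config=config, out_dir=out, hash=config_hash(config))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(ctx: StageContext, force: bool = False) -> None:
    if ctx.up_to_date("simulate") and not force:
        logger.info("simulate: up to date, skipping")
        return
    t0 = time.time()
    cfg = ctx.config["synth"]
    seed = _stage_seed(ctx.config, "simulate")
    counties = synthdata.generate_counties(
        cfg["n_counties"], cfg["n_states"], cfg["n_wfos"], seed
    )
    years = range(cfg["year_start"], cfg["year_end"] + 1)
    weather = synthdata.simulate_daily_weather(counties, years, seed + 1)
    process = synthdata.ErrorProcess(
        skew_curve=synthdata._default_skew_curve,
        tail_prob=cfg["tail_prob"],
        sd_annual_trend=cfg["sd_annual_trend"],
    )
    records = synthdata.simulate_forecast_errors(weather, counties, process, seed + 2)
    records = basis.demean_errors(records, ctx.config["basis"]["demean_level"])
    truth = synthdata.make_truth_surface(mmt=cfg["mmt_true"], noise_sd=cfg["noise_sd"])
    monthly = synthdata.simulate_mortality(records, counties, truth, seed + 3)
    experts = synthdata.simulate_expert_responses(cfg["n_experts"], seed + 4)

    cdf = synthdata.counties_frame(counties)
    cdf.to_csv(ctx.path("counties.csv"), index=False)
    records.to_parquet(ctx.path("records.parquet"), index=False)
    monthly.assign(year_month=monthly["year_month"].astype(str)).to_csv(
        ctx.path("monthly.csv"), index=False
    )
    rows = []
    for r in experts:
        for h, (p01, p50, p99) in r.horizons.items():
            rows.append(
                {"expert_id": r.expert_id, "metric": r.metric, "acc_2005": r.acc_2005,
                 "acc_2020": r.acc_2020, "horizon": h, "p01": p01, "p50": p50, "p99": p99}
            )
    pd.DataFrame(rows).to_csv(ctx.path("experts.csv"), index=False)
    json.dump(
        {"beta_true": truth.beta_true.tolist(), "mmt_true": truth.mmt_true,
         "knots": list(truth.basis_spec.error_knots)},
        ctx.path("truth.json").open("w"), indent=2,
    )
    ctx.write_manifest(
        "simulate", [], ["counties.csv", "records.parquet", "monthly.csv", "experts.csv",
                          "truth.json"], seed, t0,
    )


def _read_experts(path: Path) -> list[synthdata.ExpertResponse]:
    """Read the long-format expert CSV (one row per expert-horizon)."""
    df = pd.read_csv(path)
    out = []
    for eid, g in df.groupby("expert_id", sort=True):
        horizons = {
            int(r["horizon"]): (float(r["p01"]), float(r["p50"]), float(r["p99"]))
            for _, r in g.iterrows()
        }
        first = g.iloc[0]
        out.append(
            synthdata.ExpertResponse(
                expert_id=str(eid), metric=str(first["metric"]),
                acc_2005=float(first["acc_2005"]), acc_2020=float(first["acc_2020"]),
                horizons=horizons,
            )
        )
    return out


def _load_panel(ctx: StageContext):
    counties = pd.read_csv(ctx.path("counties.csv"))
    records = pd.read_parquet(ctx.path("records.parquet"))
    monthly = pd.read_csv(ctx.path("monthly.csv"))
    return counties, records, monthly


def stage_fit(ctx: StageContext, force: bool = False) -> None:
    if ctx.up_to_date("fit") and not force:
        logger.info("fit: up to date, skipping")
        return
    ctx.require("fit", ["counties.csv", "records.parquet", "monthly.csv"])
    t0 = time.time()
    counties, records, monthly = _load_panel(ctx)
    weights = counties.set_index("county_id")["population_base"]
    spec = basis.resolve_knots(
        records,
        basis.BasisSpec(knot_percentiles=tuple(ctx.config["basis"]["knot_percentiles"])),
        weights,
    )
    design, report = basis.aggregate_monthly(records, monthly, counties, spec)
    if len(report.mortality_without_weather):
        logger.warning("%d county-months had mortality but no weather rows",
                       len(report.mortality_without_weather))
    fit = panelfit.fit_panel(design, cluster=ctx.config["fit"]["cluster"])
    chars = panelfit.compute_county_characteristics(records)
    payload = {
        "beta": fit.beta.tolist(),
        "rain_coef": fit.rain_coef,
        "vcov": None if fit.vcov is None else fit.vcov.tolist(),
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
        "dof_model": fit.dof_model,
        "knots": list(fit.knots),
        "fe_spec": fit.fe_spec,
        "config_hash": ctx.hash,
    }
    dims = tuple(ctx.config["fit"]["heterogeneity"])
    if dims:
        het = panelfit.fit_heterogeneous_panel(design, chars, dims,
                                               cluster=ctx.config["fit"]["cluster"])
        payload["heterogeneous"] = {
            "dims": list(het.dims),
            "beta_bar": het.beta_bar.tolist(),
            "gammas": {d: g.tolist() for d, g in het.gammas.items()},
            "winsor_bands": het.winsor_bands,
            "vcov": None if het.vcov is None else het.vcov.tolist(),
        }
    json.dump(payload, ctx.path("fit.json").open("w"), indent=2)
    chars.to_csv(ctx.path("characteristics.csv"))
    ctx.write_manifest("fit", ["records.parquet", "monthly.csv"],
                       ["fit.json", "characteristics.csv"], -1, t0)


def _load_fit(ctx: StageContext) -> panelfit.FitResult:
    payload = json.loads(ctx.path("fit.json").read_text())
    return panelfit.FitResult(
        beta=np.array(payload["beta"]),
        rain_coef=payload["rain_coef"],
        vcov=None if payload["vcov"] is None else np.array(payload["vcov"]),
        n_obs=payload["n_obs"],
        n_clusters=payload["n_clusters"],
        dof_model=payload["dof_model"],
        knots=tuple(payload["knots"]),
        fe_spec=payload["fe_spec"],
    )


def stage_errors(ctx: StageContext, force: bool = False) -> None:
    if ctx.up_to_date("errors") and not force:
        logger.info("errors: up to date, skipping")
        return
    ctx.require("errors", ["counties.csv", "records.parquet"])
    t0 = time.time()
    counties = pd.read_csv(ctx.path("counties.csv"))
    records = pd.read_parquet(ctx.path("records.parquet"))
    records = records.merge(counties[["county_id", "wfo_id"]], on="county_id", how="left")
    weights = counties.set_index("county_id")["population_base"]
    mean_model = errorproj.fit_error_mean(records, weights)
    var_model = errorproj.fit_error_variance(records, mean_model, weights)
    pool = errorproj.standardize_errors(records, mean_model, var_model)
    np.savez(
        ctx.path("error_pool.npz"),
        **{f"bin_{k}": v for k, v in pool.bins.items()},
    )
    json.dump(
        {
            "mean": {"spline_coef": mean_model.spline_coef.tolist(),
                     "wfo_levels": mean_model.wfo_levels.tolist(),
                     "wfo_intercepts": mean_model.wfo_intercepts.tolist()},
            "variance": {"spline_coef": var_model.spline_coef.tolist(),
                          "wfo_intercepts": var_model.wfo_intercepts.tolist(),
                          "delta": var_model.delta, "delta_se": var_model.delta_se,
                          "year_ref": var_model.year_ref,
                          "last_sample_year": var_model.last_sample_year},
            "config_hash": ctx.hash,
        },
        ctx.path("error_models.json").open("w"), indent=2,
    )
    ctx.write_manifest("errors", ["records.parquet"],
                       ["error_models.json", "error_pool.npz"], -1, t0)


def _load_error_models(ctx: StageContext):
    payload = json.loads(ctx.path("error_models.json").read_text())
    levels = np.array(payload["mean"]["wfo_levels"])
    mean_model = errorproj.ErrorMeanModel(
        spline_coef=np.array(payload["mean"]["spline_coef"]),
        wfo_levels=levels,
        wfo_intercepts=np.array(payload["mean"]["wfo_intercepts"]),
    )
    v = payload["variance"]
    var_model = errorproj.ErrorVarianceModel(
        spline_coef=np.array(v["spline_coef"]), wfo_levels=levels,
        wfo_intercepts=np.array(v["wfo_intercepts"]), delta=v["delta"],
        delta_se=v["delta_se"], year_ref=v["year_ref"],
        last_sample_year=v["last_sample_year"],
    )
    with np.load(ctx.path("error_pool.npz")) as z:
        pool = errorproj.StandardizedErrorPool(
            bins={int(k.split("_", 1)[1]): z[k] for k in z.files}
        )
    return mean_model, var_model, pool


def stage_elicit(ctx: StageContext, force: bool = False) -> None:
    if ctx.up_to_date("elicit") and not force:
        logger.info("elicit: up to date, skipping")
        return
    ctx.require("elicit", ["experts.csv", "counties.csv", "records.parquet"])
    t0 = time.time()
    experts = _read_experts(ctx.path("experts.csv"))
    pairs = synthdata.historical_accuracy_pairs(seed=_stage_seed(ctx.config, "elicit"))
    counties = pd.read_csv(ctx.path("counties.csv"))
    records = pd.read_parquet(ctx.path("records.parquet"))

    fits, changes_2005_2020 = [], []
    for r in experts:
        r = elicitation.convert_mae_to_rmse(r, pairs)
        changes = elicitation.normalize_changes(r)
        fits.append(elicitation.fit_skew_lognormal(*changes[2100]))
        changes_2005_2020.append(r.acc_2020 / r.acc_2005)

    w = counties.set_index("county_id")["population_base"]
    wrec = w.reindex(records["county_id"]).to_numpy(float)
    years = pd.DatetimeIndex(records["date"]).year
    last = years.max()
    err = records["error_demeaned"].to_numpy(float)
    base_rmse = float(np.sqrt(np.average(err[years == last] ** 2,
                                         weights=wrec[years == last])))
    hist = records.assign(_y=years, _w=wrec, _e2=err**2 * wrec)
    by_year = hist.groupby("_y").agg(num=("_e2", "sum"), den=("_w", "sum"))
    hist_rmse = np.sqrt(by_year["num"] / by_year["den"])
    obs_change = float(hist_rmse.iloc[-1] / hist_rmse.iloc[0])

    if ctx.config["elicit"]["weighting"] == "performance":
        weights = elicitation.performance_weights(
            changes_2005_2020, obs_change, ctx.config["elicit"]["lam"]
        )
    else:
        weights = None
    mixture = elicitation.build_mixture(fits, weights)
    scenarios = elicitation.scenario_targets(mixture, base_rmse)
    payload = {"base_rmse_2020": base_rmse, "observed_change": obs_change,
               "historical_rmse": {int(k): float(v) for k, v in hist_rmse.items()},
               "scenarios": {}, "config_hash": ctx.hash}
    for s in scenarios:
        r_hat, r_star, traj = elicitation.extrapolate_accuracy_path(
            hist_rmse, s.rmse_2100, ctx.config["project"]["eval_end"]
        )
        payload["scenarios"][s.name] = {
            "percentile": s.percentile, "target_change_2100": s.target_change_2100,
            "rmse_2100": s.rmse_2100, "r_hat": r_hat, "r_star": r_star,
            "trajectory": {int(y): float(v) for y, v in traj.items()},
        }
    json.dump(payload, ctx.path("scenarios.json").open("w"), indent=2)
    ctx.write_manifest("elicit", ["experts.csv", "records.parquet"], ["scenarios.json"],
                       _stage_seed(ctx.config, "elicit"), t0)


def stage_project(ctx: StageContext, force: bool = False) -> None:
    if ctx.up_to_date("project") and not force:
        logger.info("project: up to date, skipping")
        return
    ctx.require(
        "project",
        ["counties.csv", "records.parquet", "fit.json", "error_models.json",
         "error_pool.npz", "scenarios.json"],
    )
    t0 = time.time()
    pcfg = ctx.config["project"]
    seed = _stage_seed(ctx.config, "project")
    counties = pd.read_csv(ctx.path("counties.csv"))
    records = pd.read_parquet(ctx.path("records.parquet"))
    records = records.merge(counties[["county_id", "wfo_id"]], on="county_id", how="left")
    fit = _load_fit(ctx)
    mean_model, var_model, pool = _load_error_models(ctx)
    scen_payload = json.loads(ctx.path("scenarios.json").read_text())
    weights = counties.set_index("county_id")["population_base"]

    years = pd.DatetimeIndex(records["date"]).year
    win = pcfg["window"]
    ref_years = tuple(range(int(years.max()) - win + 1, int(years.max()) + 1))
    eval_years = tuple(range(pcfg["eval_end"] - win + 1, pcfg["eval_end"] + 1))

    wfo_map = counties.set_index("county_id")["wfo_id"]
    response = projection.ResponseFunction.build(fit)

    # forecast-scenario trends calibrated on the intermediate-warming panel
    calib_name = ("intermediate" if "intermediate" in pcfg["climate_deltas"]
                  else list(pcfg["climate_deltas"])[-1])
    calib_spec = synthdata.ClimateScenarioSpec(
        name=calib_name, warming_delta=pcfg["climate_deltas"][calib_name],
        eval_years=eval_years, reference_years=ref_years,
    )
    calib_panel = synthdata.make_climate_scenario(records, calib_spec)
    calib_panel["wfo_id"] = wfo_map.reindex(calib_panel["county_id"]).to_numpy()
    trends = {}
    for name in pcfg["forecast_scenarios"]:
        if name in ("constant", "zero_error"):
            trends[name] = errorproj.calibrate_scenario_trend(
                var_model, mean_model, 1.0, calib_panel, weights, name=name
            )
        else:
            target = scen_payload["scenarios"][name]["rmse_2100"]
            trends[name] = errorproj.calibrate_scenario_trend(
                var_model, mean_model, target, calib_panel, weights, name=name
            )

    rows = []
    for cname, delta in pcfg["climate_deltas"].items():
        spec = synthdata.ClimateScenarioSpec(
            name=cname, warming_delta=delta, eval_years=eval_years,
            reference_years=ref_years,
        )
        panel = synthdata.make_climate_scenario(records, spec)
        panel["wfo_id"] = wfo_map.reindex(panel["county_id"]).to_numpy()
        projections = {}
        for fname, trend in trends.items():
            drawn = errorproj.sample_future_errors(
                panel, mean_model, var_model, trend, pool, seed
            )
            projections[fname] = projection.project_mortality(
                drawn, response, weights, pcfg["hot_threshold"],
                scenario_climate=cname, scenario_forecast=fname,
            )
        base = projections["constant"]
        for fname, proj in projections.items():
            ls = projection.lives_saved(proj, base, fit, pcfg["n_ci_draws"], seed)
            rows += [
                {"scenario_climate": cname, "scenario_forecast": fname,
                 "metric": "annual_deaths_all", "value": proj.mean_annual,
                 "lo95": np.nan, "hi95": np.nan},
                {"scenario_climate": cname, "scenario_forecast": fname,
                 "metric": "annual_deaths_hot", "value": proj.mean_annual_hot,
                 "lo95": np.nan, "hi95": np.nan},
                {"scenario_climate": cname, "scenario_forecast": fname,
                 "metric": "lives_saved_all", "value": ls.all_days,
                 "lo95": ls.all_days_ci[0] if ls.all_days_ci else np.nan,
                 "hi95": ls.all_days_ci[1] if ls.all_days_ci else np.nan},
                {"scenario_climate": cname, "scenario_forecast": fname,
                 "metric": "lives_saved_hot", "value": ls.hot_days,
                 "lo95": ls.hot_days_ci[0] if ls.hot_days_ci else np.nan,
                 "hi95": ls.hot_days_ci[1] if ls.hot_days_ci else np.nan},
            ]
    results = pd.DataFrame(rows)
    results.to_csv(ctx.path("results.csv"), index=False)
    json.dump(
        {"config_hash": ctx.hash, "seed": seed, "reference_years": list(ref_years),
         "eval_years": list(eval_years), "mmt": response.mmt_of(None)
         if not isinstance(response.mmt, pd.Series) else response.mmt.to_dict()},
        ctx.path("projection_provenance.json").open("w"), indent=2,
    )
    ctx.write_manifest(
        "project",
        ["fit.json", "error_models.json", "scenarios.json"],
        ["results.csv", "projection_provenance.json"], seed, t0,
    )


def run(stage: str, config: dict, force: bool = False) -> StageContext:
    """Run one stage or the whole chain; returns the stage context."""
    ctx = make_context(config)
    funcs = {
        "simulate": stage_simulate,
        "fit": stage_fit,
        "errors": stage_errors,
        "elicit": stage_elicit,
        "project": stage_project,
    }
    if stage == "all":
        for s in STAGES:
            funcs[s](ctx, force=force)
    elif stage in funcs:
        funcs[stage](ctx, force=force)
    else:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return ctx
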