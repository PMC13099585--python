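"""Shared fixtures: a small synthetic panel built once per session."""

import numpy as np
import pandas as pd
import pytest

from forecastmort import basis, panelfit, synthdata as sd


@pytest.fixture(scope="session")
def small_counties():
    return sd.generate_counties(20, 5, 4, seed=11)


@pytest.fixture(scope="session")
def counties_df(small_counties):
    return sd.counties_frame(small_counties)


@pytest.fixture(scope="session")
def small_records(small_counties, counties_df):
    weather = sd.simulate_daily_weather(small_counties, range(2005, 2009), seed=12)
    rec = sd.simulate_forecast_errors(weather, small_counties,
                                      sd.DEFAULT_ERROR_PROCESS, seed=13)
    rec = basis.demean_errors(rec, "county")
    return rec.merge(counties_df[["county_id", "wfo_id"]], on="county_id")


@pytest.fixture(scope="session")
def truth():
    return sd.make_truth_surface()


@pytest.fixture(scope="session")
def truth_exact():
    """Truth surface with every nuisance component switched off."""
    return sd.make_truth_surface(noise_sd=0.0, fe_scale_county_month=0.0,
                                 fe_scale_state_time=0.0, trend_scale=0.0)


@pytest.fixture(scope="session")
def small_design(small_records, small_counties, counties_df, truth):
    monthly = sd.simulate_mortality(small_records, small_counties, truth, seed=14)
    design, report = basis.aggregate_monthly(small_records, monthly, counties_df,
                                             truth.basis_spec)
    assert len(report.mortality_without_weather) == 0
    return design


@pytest.fixture(scope="session")
def small_fit(small_design):
    return panelfit.fit_panel(small_design)


@pytest.fixture(scope="session")
def pop_weights(counties_df):
    return counties_df.set_index("county_id")["population_base"]
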