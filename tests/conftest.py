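import numpy as np
import pandas as pd
import pytest

from airh2m.io import CovariatePanel, OutcomePanel, PollutantPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_panel(rng):
    """10-day, 3-pollutant panel with two missing cells."""
    T, P = 10, 3
    vals = rng.normal(10, 3, (T, P)) * np.array([1.0, 5.0, 0.2])
    mask = np.ones((T, P), bool)
    mask[2, 0] = mask[7, 2] = False
    vals = np.where(mask, vals, np.nan)
    return PollutantPanel(
        dates=pd.date_range("2011-01-01", periods=T, freq="D"),
        values=vals, observed_mask=mask,
        names=["co", "no2", "so2"], units=["mg/m3", "ug/m3", "ug/m3"],
    )


@pytest.fixture
def small_covariates(small_panel, rng):
    T = small_panel.n_days
    return CovariatePanel(
        temperature=rng.normal(11, 5, T),
        rel_humidity=rng.uniform(50, 95, T),
        holiday_indicator=small_panel.dates.dayofweek >= 5,
        time_index=np.arange(1, T + 1, dtype=float),
    )


@pytest.fixture
def small_outcome(rng, small_panel):
    return OutcomePanel(counts=rng.poisson(37, small_panel.n_days))


@pytest.fixture
def long_panel_csv(tmp_path, rng):
    """60-day panel, long enough for the default spline knot counts."""
    T = 60
    dates = pd.date_range("2012-01-01", periods=T, freq="D")
    df = pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "no2": np.round(rng.uniform(15, 60, T), 1),
        "o3": np.round(rng.uniform(10, 70, T), 1),
        "temperature": np.round(rng.normal(10, 4, T), 1),
        "rel_humidity": np.round(rng.uniform(55, 95, T), 1),
        "count": rng.poisson(37, T),
    })
    path = tmp_path / "panel_long.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def panel_csv(tmp_path, rng):
    """A well-formed daily CSV with one blank pollutant cell."""
    T = 6
    dates = pd.date_range("2012-03-01", periods=T, freq="D")
    df = pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "no2": np.round(rng.uniform(15, 60, T), 1),
        "o3": np.round(rng.uniform(10, 70, T), 1),
        "temperature": np.round(rng.normal(10, 4, T), 1),
        "rel_humidity": np.round(rng.uniform(55, 95, T), 1),
        "count": rng.poisson(37, T),
    })
    df.loc[3, "no2"] = np.nan
    path = tmp_path / "panel.csv"
    df.to_csv(path, index=False)
    return path
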