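"""Date-indexed panel containers and readers for multi-pollutant time-series studies.

The model consumes three aligned daily panels: measured pollutant
concentrations (with missingness), meteorological confounders, and the
health-outcome counts.  Everything here is deliberately dumb plumbing:
missing concentrations are *preserved* — imputation is the sampler's job,
because the latent-process model bridges gaps using the cross-pollutant
correlation and temporal dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PollutantPanel",
    "CovariatePanel",
    "OutcomePanel",
    "PanelFormatError",
    "PanelAlignmentError",
    "DegeneratePollutantError",
    "load_panel",
    "write_panel",
    "standardize",
    "destandardize",
    "holiday_indicator",
]


class PanelFormatError(ValueError):
    """A required column is absent or unparseable."""


class PanelAlignmentError(ValueError):
    """Dates are duplicated, unordered, or non-contiguous."""


class DegeneratePollutantError(ValueError):
    """A pollutant has too few observed values (or zero spread) to standardize."""


@dataclass
class PollutantPanel:
    """T x P measured concentrations with a missingness mask.

    ``values`` stays on the original units; ``center``/``scale`` record the
    standardization applied (identity until :func:`standardize` is called)
    so that latent concentrations can be mapped back to interpretable units.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray          # T x P, NaN where missing
    observed_mask: np.ndarray   # T x P bool
    names: list[str]
    units: list[str] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise PanelFormatError("values and observed_mask shapes differ")
        if self.values.shape[1] != len(self.names):
            raise PanelFormatError("number of names does not match columns")
        if not self.units:
            self.units = [""] * len(self.names)
        _check_contiguous_dates(self.dates)
        # the mask must be false exactly where values is missing
        if np.any(self.observed_mask & ~np.isfinite(self.values)):
            raise PanelFormatError("observed cells contain non-finite values")
        self.values = np.where(self.observed_mask, self.values, np.nan)
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=float)
            if np.any(self.scale <= 0):
                raise DegeneratePollutantError("scale must be positive")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_pollutants(self) -> int:
        return self.values.shape[1]

    def iqr(self) -> np.ndarray:
        """Inter-quartile range per pollutant over observed cells only."""
        out = np.empty(self.n_pollutants)
        for p in range(self.n_pollutants):
            col = self.values[self.observed_mask[:, p], p]
            out[p] = np.percentile(col, 75) - np.percentile(col, 25)
        return out


@dataclass
class CovariatePanel:
    """Daily meteorology plus calendar covariates, aligned to the pollutant panel."""

    temperature: np.ndarray     # degrees C
    rel_humidity: np.ndarray    # percent
    holiday_indicator: np.ndarray  # bool, weekend/holiday
    time_index: np.ndarray      # 1..T

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.rel_humidity = np.asarray(self.rel_humidity, dtype=float)
        self.holiday_indicator = np.asarray(self.holiday_indicator, dtype=bool)
        self.time_index = np.asarray(self.time_index, dtype=float)
        n = {len(self.temperature), len(self.rel_humidity),
             len(self.holiday_indicator), len(self.time_index)}
        if len(n) != 1:
            raise PanelAlignmentError("covariate series have unequal lengths")

    @property
    def n_days(self) -> int:
        return len(self.temperature)


@dataclass
class OutcomePanel:
    """Daily event counts and the fixed expected count E.

    E defaults to the average count over the study period, so that the
    Poisson rate multiplier is a relative risk against the period mean.
    """

    counts: np.ndarray
    expected: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise PanelFormatError("counts must be nonnegative")
        self.counts = self.counts.astype(int)
        if self.expected == 0.0:
            self.expected = float(np.mean(self.counts))
        if self.expected <= 0:
            raise PanelFormatError("expected count must be positive")

    @property
    def n_days(self) -> int:
        return len(self.counts)


def _check_contiguous_dates(dates: pd.DatetimeIndex) -> None:
    if len(dates) == 0:
        raise PanelAlignmentError("empty date index")
    if dates.has_duplicates:
        raise PanelAlignmentError("duplicate dates")
    deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if len(deltas) and not np.all(deltas == 1):
        raise PanelAlignmentError("dates must be strictly increasing daily with no gaps")


DEFAULT_LAYOUT = {
    "date": "date",
    "temperature": "temperature",
    "rel_humidity": "rel_humidity",
    "count": "count",
}


def load_panel(
    path,
    layout: dict | None = None,
    pollutants: list[str] | None = None,
    units: list[str] | None = None,
    extra_holidays=None,
    expected: float = 0.0,
) -> tuple[PollutantPanel, CovariatePanel, OutcomePanel]:
    """Read a daily CSV (or XLSX sheet) into the three aligned panels.

    Any column that is not the date, a covariate or the count is treated as
    a pollutant unless ``pollutants`` names them explicitly.  Blank cells in
    pollutant columns become missing with ``observed_mask`` false.
    """
    layout = {**DEFAULT_LAYOUT, **(layout or {})}
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    for key in ("date", "temperature", "rel_humidity", "count"):
        if layout[key] not in df.columns:
            raise PanelFormatError(f"required column '{layout[key]}' not found")
    reserved = {layout[k] for k in ("date", "temperature", "rel_humidity", "count")}
    if pollutants is None:
        pollutants = [c for c in df.columns if c not in reserved]
    if not pollutants:
        raise PanelFormatError("no pollutant columns found")

    dates = pd.DatetimeIndex(pd.to_datetime(df[layout["date"]]))
    order = np.argsort(dates.values)
    df = df.iloc[order].reset_index(drop=True)
    dates = dates[order]
    _check_contiguous_dates(dates)

    vals = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float) for c in pollutants]
    )
    mask = np.isfinite(vals)
    panel = PollutantPanel(
        dates=dates, values=vals, observed_mask=mask,
        names=list(pollutants), units=list(units) if units else [],
    )
    cov = CovariatePanel(
        temperature=pd.to_numeric(df[layout["temperature"]]).to_numpy(),
        rel_humidity=pd.to_numeric(df[layout["rel_humidity"]]).to_numpy(),
        holiday_indicator=holiday_indicator(dates, extra_holidays),
        time_index=np.arange(1, len(dates) + 1, dtype=float),
    )
    counts = pd.to_numeric(df[layout["count"]])
    if counts.isna().any():
        raise PanelFormatError("count column contains missing values")
    outcome = OutcomePanel(counts=counts.to_numpy(), expected=expected)
    return panel, cov, outcome


def write_panel(
    path,
    panel: PollutantPanel,
    covariates: CovariatePanel,
    outcome: OutcomePanel,
    layout: dict | None = None,
) -> None:
    """Inverse of :func:`load_panel` (round-trips values and mask bit-exactly)."""
    layout = {**DEFAULT_LAYOUT, **(layout or {})}
    df = pd.DataFrame({layout["date"]: panel.dates.strftime("%Y-%m-%d")})
    for j, name in enumerate(panel.names):
        col = panel.values[:, j].copy()
        df[name] = col
    df[layout["temperature"]] = covariates.temperature
    df[layout["rel_humidity"]] = covariates.rel_humidity
    df[layout["count"]] = outcome.counts
    df.to_csv(path, index=False)


def standardize(panel: PollutantPanel) -> PollutantPanel:
    """Per-pollutant z-scoring of observed cells (sample sd, n-1 denominator).

    Pollutants sit on wildly different scales (mg/m3 vs counts/cm3); putting
    them on a common scale makes the latent process covariance comparable
    across pollutants.  Center and scale are stored for back-transformation
    so health effects stay interpretable per original unit.
    """
    center = np.empty(panel.n_pollutants)
    scale = np.empty(panel.n_pollutants)
    newvals = panel.values.copy()
    for p in range(panel.n_pollutants):
        obs = panel.values[panel.observed_mask[:, p], p]
        if len(obs) < 2:
            raise DegeneratePollutantError(
                f"pollutant '{panel.names[p]}' has fewer than 2 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd <= 0:
            raise DegeneratePollutantError(
                f"pollutant '{panel.names[p]}' has zero spread")
        center[p], scale[p] = mu, sd
        newvals[:, p] = (panel.values[:, p] - mu) / sd
    return replace(panel, values=newvals, center=center, scale=scale)


def destandardize(panel: PollutantPanel) -> PollutantPanel:
    """Undo :func:`standardize` using the recorded center/scale."""
    if panel.center is None or panel.scale is None:
        raise ValueError("panel carries no standardization parameters")
    vals = panel.values * panel.scale + panel.center
    return replace(panel, values=vals, center=None, scale=None)


def holiday_indicator(dates, extra_holidays=None) -> np.ndarray:
    """True on Saturdays, Sundays and any supplied public-holiday dates.

    The health model distinguishes workdays from weekend/holiday days via a
    single linear term; public holidays are jurisdiction-specific and are
    supplied through configuration rather than hard-coded.
    """
    dates = pd.DatetimeIndex(dates)
    ind = dates.dayofweek >= 5
    if extra_holidays is not None:
        extra = pd.DatetimeIndex(pd.to_datetime(list(extra_holidays)))
        ind = ind | dates.isin(extra)
    return np.asarray(ind, dtype=bool)
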