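"""Monthly time-series preprocessing for state-space causal inference.

Raw monitoring samples are reduced to regular monthly series, then made
stationary in three steps: removal of the long-term linear trend, month-wise
standardization against the monthly climatology (deseasonalization), and
rescaling to zero mean and unit variance.  The output is the anomaly series
that the cross-mapping stage consumes; missing months are carried through
every step as missing, never interpolated, because interpolated values would
inject artificial dynamics into the delay embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MonthlySeries",
    "MonthlyClimatology",
    "ProcessedSeries",
    "aggregate_monthly",
    "detrend_linear",
    "deseasonalize",
    "rescale",
    "preprocess",
]


@dataclass
class MonthlySeries:
    """One variable's regular monthly series at one site.

    The index is contiguous calendar months starting at ``start``; missing
    months hold NaN.  ``values[i]`` belongs to the month ``start`` plus ``i``
    months.

    Parameters
    ----------
    site, variable :
        Identifiers; free-form strings.
    start :
        ``(year, month)`` of the first index position, ``month`` in 1..12.
    values :
        Float array; NaN marks a missing month.
    """

    site: str
    variable: str
    start: tuple[int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        y, m = self.start
        if not 1 <= m <= 12:
            raise ValidationError(f"start month must be in 1..12, got {m}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the month has an observation."""
        return ~np.isnan(self.values)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of every index position."""
        _, m0 = self.start
        return (m0 - 1 + np.arange(len(self.values))) % 12 + 1

    @property
    def years(self) -> np.ndarray:
        y0, m0 = self.start
        return y0 + (m0 - 1 + np.arange(len(self.values))) // 12

    def replace_values(self, values: np.ndarray) -> "MonthlySeries":
        return MonthlySeries(self.site, self.variable, self.start, np.asarray(values, float))

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns site, year, month, variable, value."""
        return pd.DataFrame(
            {
                "site": self.site,
                "year": self.years,
                "month": self.months,
                "variable": self.variable,
                "value": self.values,
            }
        )


@dataclass
class MonthlyClimatology:
    """Per-calendar-month mean, sample standard deviation and count."""

    mean: np.ndarray  # length 12, index = month - 1; NaN if month absent
    sd: np.ndarray
    count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": np.arange(1, 13), "mean": self.mean, "sd": self.sd, "n": self.count}
        )


@dataclass
class ProcessedSeries(MonthlySeries):
    """A detrended, deseasonalized, rescaled monthly anomaly series.

    ``steps`` records the provenance of transformations applied, in order.
    """

    steps: tuple[str, ...] = field(default=())


def aggregate_monthly(
    raw: pd.DataFrame,
    *,
    site: str = "",
    variable: str = "",
    date_col: str = "date",
    value_col: str = "value",
) -> MonthlySeries:
    """Average dated samples into a contiguous monthly series.

    All samples falling in the same (year, month) are averaged arithmetically;
    months between the first and last sampled month with no samples are kept
    in the index and marked missing.

    Parameters
    ----------
    raw :
        Frame with a datetime-like column ``date_col`` and numeric
        ``value_col``.
    """
    if raw is None or len(raw) == 0:
        raise ValidationError("aggregate_monthly: empty input")
    dates = pd.to_datetime(raw[date_col])
    vals = pd.to_numeric(raw[value_col])
    per = pd.PeriodIndex(dates, freq="M")
    grouped = pd.Series(vals.to_numpy(), index=per).groupby(level=0).mean()
    full = pd.period_range(grouped.index.min(), grouped.index.max(), freq="M")
    series = grouped.reindex(full)
    start = (full[0].year, full[0].month)
    return MonthlySeries(site, variable, start, series.to_numpy(dtype=float))


def _fit_time_ols(values: np.ndarray) -> np.ndarray:
    """OLS residuals of values on the time index; NaNs preserved."""
    t = np.arange(len(values), dtype=float)
    obs = ~np.isnan(values)
    X = np.column_stack([np.ones(obs.sum()), t[obs]])
    coef, *_ = np.linalg.lstsq(X, values[obs], rcond=None)
    resid = np.full_like(values, np.nan)
    resid[obs] = values[obs] - X @ coef
    return resid


def detrend_linear(series: MonthlySeries) -> MonthlySeries:
    """Residuals of an ordinary least-squares fit of value on time.

    Time is the contiguous monthly index t = 0, 1, 2, ...; missing rows are
    excluded from the fit and remain missing in the output.
    """
    if series.n_obs < 3:
        raise ValidationError("detrend_linear: need at least 3 non-missing values")
    return series.replace_values(_fit_time_ols(series.values))


def _climatology(values: np.ndarray, months: np.ndarray) -> MonthlyClimatology:
    mean = np.full(12, np.nan)
    sd = np.full(12, np.nan)
    count = np.zeros(12, dtype=int)
    for m in range(1, 13):
        v = values[(months == m) & ~np.isnan(values)]
        count[m - 1] = len(v)
        if len(v) >= 1:
            mean[m - 1] = v.mean()
        if len(v) >= 2:
            sd[m - 1] = v.std(ddof=1)
    return MonthlyClimatology(mean, sd, count)


def deseasonalize(series: MonthlySeries) -> tuple[MonthlySeries, MonthlyClimatology]:
    """Standardize each value against its calendar month's climatology.

    Output for month m is (value - mean_m) / sd_m with the sample (n-1)
    standard deviation.  A month with zero variance yields 0 (zero anomaly in
    the vanishing-variance limit); a represented month with fewer than two
    observations is an error because its sd is undefined.
    """
    months = series.months
    values = series.values
    clim = _climatology(values, months)
    represented = np.unique(months[~np.isnan(values)])
    for m in represented:
        if clim.count[m - 1] < 2:
            raise ValidationError(
                f"deseasonalize: calendar month {m} has fewer than 2 observations"
            )
    out = np.full_like(values, np.nan)
    for m in represented:
        sel = (months == m) & ~np.isnan(values)
        s = clim.sd[m - 1]
        if s == 0:
            logger.warning(
                "deseasonalize: month %d of %s/%s has zero variance; anomalies set to 0",
                m, series.site, series.variable,
            )
            out[sel] = 0.0
        else:
            out[sel] = (values[sel] - clim.mean[m - 1]) / s
    return series.replace_values(out), clim


def rescale(series: MonthlySeries, steps: tuple[str, ...] = ()) -> ProcessedSeries:
    """Z-score over non-missing values: zero mean, unit sample variance."""
    obs = series.mask
    v = series.values[obs]
    if len(np.unique(v)) < 2:
        raise ValidationError("rescale: need at least 2 distinct non-missing values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("rescale: zero variance")
    out = np.full_like(series.values, np.nan)
    out[obs] = (v - v.mean()) / sd
    return ProcessedSeries(
        series.site, series.variable, series.start, out, steps=steps + ("rescale",)
    )


def preprocess(series: MonthlySeries) -> ProcessedSeries:
    """Full stationarization: detrend, deseasonalize, rescale.

    The long-term linear trend and the twelve monthly means are estimated in
    a single least-squares fit (regressors: intercept, time, month
    indicators), after which residuals are scaled by their calendar month's
    sample standard deviation and finally z-scored overall.  Joint estimation
    makes the output exactly invariant to adding any affine function of time
    plus any fixed 12-periodic signal to the input, which is the operational
    content of trend removal and seasonal adjustment; estimating the two
    sequentially leaves a small leakage term because a periodic signal is not
    exactly orthogonal to time on a finite record.
    """
    if len(series) < 24:
        raise ValidationError("preprocess: need at least 24 months for deseasonalization")
    values = series.values
    months = series.months
    obs = ~np.isnan(values)
    if obs.sum() < 14:
        raise ValidationError("preprocess: too few observations")
    represented = np.unique(months[obs])
    for m in represented:
        if ((months == m) & obs).sum() < 2:
            raise ValidationError(
                f"preprocess: calendar month {m} has fewer than 2 observations"
            )
    t = np.arange(len(values), dtype=float)
    # design: month indicators (absorbing the intercept) + centered time
    dummies = np.stack([(months == m).astype(float) for m in represented], axis=1)
    X = np.column_stack([dummies, t - t.mean()])
    coef, *_ = np.linalg.lstsq(X[obs], values[obs], rcond=None)
    resid = np.full_like(values, np.nan)
    resid[obs] = values[obs] - X[obs] @ coef
    deseason = series.replace_values(resid)
    anom, _ = deseasonalize(deseason)  # per-month means of resid are 0; divides by sd
    out = rescale(anom, steps=("detrend", "deseasonalize"))
    if out.n_obs != series.n_obs:
        raise AssertionError("preprocess must preserve the missing mask")
    return out
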