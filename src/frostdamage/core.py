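"""Core frost-damage-index (FDI) primitives.

The FDI is the cold-side analogue of growing degree days: over a
measurement interval it accumulates the hourly temperature deficit below a
base temperature,

    FDI(t_n; T_base) = sum_{t in (t_{n-1}, t_n]} min(T_t - T_base, 0)

so it is nonpositive, in units of degC*h, and additive over adjacent
intervals.  Canopy-cover (CC) decline is modelled as proportional to it,
``dCC = s * FDI`` with a nonnegative, potentially genotype-specific
sensitivity ``s``.  Before the FDI is computed the hourly temperature
trajectory may be smoothed (two-sided moving average) and shifted forward
by a lag, accounting for the delay between a frost event and visible
canopy damage.

This module holds the carriers of those series and the elementary
operations on them; parameter estimation lives in
:mod:`frostdamage.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "CoverageError",
    "InsufficientDataError",
    "TemperatureSeries",
    "CanopyCoverSeries",
    "DeltaCCSeries",
    "FDISeries",
    "FDIParams",
    "smooth_temperature",
    "lag_temperature",
    "compute_fdi",
    "fdi_series",
    "delta_cc",
    "interpolate_daily",
    "select_negative",
    "predict_delta_cc",
]

HOUR = pd.Timedelta(hours=1)
DAY = pd.Timedelta(days=1)


class CoverageError(ValueError):
    """A requested interval is not covered by the temperature series."""


class InsufficientDataError(ValueError):
    """Too few observations to perform the requested operation."""


def _as_datetime_index(ts) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(ts)
    if idx.tz is not None:
        idx = idx.tz_localize(None)
    return idx


@dataclass(frozen=True)
class TemperatureSeries:
    """Hourly air-temperature trajectory.

    Parameters
    ----------
    timestamps : datetime sequence
        Strictly increasing; nominally hourly.  Gaps are recorded in
        :attr:`gaps` but never silently filled.
    values : array of float
        Air temperature in degC per timestamp.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    gaps: tuple = field(default=(), compare=False)

    def __post_init__(self):
        idx = _as_datetime_index(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if idx.size != vals.size:
            raise ValueError("timestamps and values differ in length")
        if idx.size == 0:
            raise ValueError("empty temperature series")
        diffs = np.diff(idx.asi8)
        if idx.size > 1 and not (diffs > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        gaps = []
        if idx.size > 1:
            hourly = diffs == HOUR.value
            if hourly.mean() < 0.99:
                raise ValueError(
                    "temperature series is not hourly: "
                    f"only {hourly.mean():.1%} of steps are 1 h"
                )
            for i in np.flatnonzero(~hourly):
                gaps.append((idx[i], idx[i + 1]))
        object.__setattr__(self, "timestamps", idx)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gaps", tuple(gaps))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_complete(self) -> bool:
        """True when there is a sample at every hour of the span."""
        return not self.gaps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temp_c": self.values})


@dataclass(frozen=True)
class CanopyCoverSeries:
    """Canopy cover of one observation unit (a sowing row) over time."""

    unit_id: str
    genotype: str
    dates: pd.DatetimeIndex
    cc: np.ndarray

    def __post_init__(self):
        idx = _as_datetime_index(self.dates)
        vals = np.asarray(self.cc, dtype=float)
        if idx.size != vals.size:
            raise ValueError("dates and cc differ in length")
        if idx.size > 1 and not (np.diff(idx.asi8) > 0).all():
            raise ValueError("dates must be strictly increasing")
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise ValueError("cc values must lie in [0, 1]")
        object.__setattr__(self, "dates", idx)
        object.__setattr__(self, "cc", vals)

    def __len__(self) -> int:
        return len(self.cc)


@dataclass(frozen=True)
class DeltaCCSeries:
    """Canopy-cover differences per interval (negative = damage)."""

    unit_id: str
    genotype: str
    interval_ends: pd.DatetimeIndex
    delta_cc: np.ndarray
    daily: bool = False

    def __post_init__(self):
        idx = _as_datetime_index(self.interval_ends)
        vals = np.asarray(self.delta_cc, dtype=float)
        if idx.size != vals.size:
            raise ValueError("interval_ends and delta_cc differ in length")
        if idx.size > 1 and not (np.diff(idx.asi8) > 0).all():
            raise ValueError("interval_ends must be strictly increasing")
        object.__setattr__(self, "interval_ends", idx)
        object.__setattr__(self, "delta_cc", vals)

    def __len__(self) -> int:
        return len(self.delta_cc)


@dataclass(frozen=True)
class FDISeries:
    """FDI per measurement interval, in degC*h; every value is <= 0."""

    interval_ends: pd.DatetimeIndex
    fdi: np.ndarray

    def __post_init__(self):
        idx = _as_datetime_index(self.interval_ends)
        vals = np.asarray(self.fdi, dtype=float)
        if idx.size != vals.size:
            raise ValueError("interval_ends and fdi differ in length")
        if vals.size and (vals > 1e-9).any():
            raise ValueError("FDI values must be <= 0")
        object.__setattr__(self, "interval_ends", idx)
        object.__setattr__(self, "fdi", np.minimum(vals, 0.0))

    def __len__(self) -> int:
        return len(self.fdi)


SensitivityLike = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class FDIParams:
    """Crop/genotype parameters of the frost-damage model.

    t_base
        Threshold temperature (degC) below which damage accrues.
    lag_days
        Whole days the temperature trajectory is shifted forward, so that
        damage observed on day d is driven by temperature on day d - lag.
    smooth_hours
        Span of the two-sided moving average applied to the hourly
        trajectory (total window of ``smooth_hours + 1`` samples).
    sensitivity
        Nonnegative scaling from FDI (degC*h) to dCC (fraction); a single
        global value or a mapping genotype -> value.
    """

    t_base: float
    lag_days: int = 0
    smooth_hours: int = 0
    sensitivity: SensitivityLike = 0.0

    def __post_init__(self):
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")
        if self.smooth_hours < 0:
            raise ValueError("smooth_hours must be >= 0")
        if isinstance(self.sensitivity, Mapping):
            bad = {g: s for g, s in self.sensitivity.items() if s is not None and s < 0}
        else:
            bad = self.sensitivity < 0
        if bad:
            raise ValueError("sensitivity must be >= 0")

    def sensitivity_for(self, genotype: str | None = None) -> float:
        if isinstance(self.sensitivity, Mapping):
            if genotype not in self.sensitivity:
                raise KeyError(
                    f"genotype {genotype!r} not present in sensitivity map"
                )
            return float(self.sensitivity[genotype])
        return float(self.sensitivity)

    def replace(self, **kw) -> "FDIParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# temperature preprocessing


def smooth_temperature(series: TemperatureSeries, window_hours: int) -> TemperatureSeries:
    """Two-sided moving average of the hourly trajectory.

    ``window_hours`` is the total span of the centred window, i.e. the
    average runs over ``window_hours + 1`` consecutive samples (an odd,
    symmetric window for the even spans used on the fitting grid).  At the
    series edges the window shrinks to the available samples.  A span of 0
    returns the series unchanged.
    """
    if window_hours < 0:
        raise ValueError("window_hours must be >= 0")
    if window_hours == 0:
        return series
    smoothed = (
        pd.Series(series.values)
        .rolling(window_hours + 1, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return TemperatureSeries(series.timestamps, smoothed)


def lag_temperature(series: TemperatureSeries, lag_days: int) -> TemperatureSeries:
    """Shift the trajectory forward by whole days.

    The temperature measured at time t indexes time ``t + lag``, so damage
    observed on day d is attributed to temperature ``lag`` days earlier.
    """
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    if lag_days == 0:
        return series
    return TemperatureSeries(series.timestamps + lag_days * DAY, series.values)


def _interval_values(
    series: TemperatureSeries,
    t_prev: pd.Timestamp,
    t_now: pd.Timestamp,
    allow_gaps: bool,
    max_gap_hours: int,
) -> np.ndarray:
    """Hourly values on the half-open interval (t_prev, t_now]."""
    expected = pd.date_range(t_prev + HOUR, t_now, freq="h")
    if expected.empty:
        raise ValueError("interval shorter than one hour")
    pos = series.timestamps.get_indexer(expected)
    missing = pos < 0
    if not missing.any():
        return series.values[pos]
    runs = []
    start = None
    for i, m in enumerate(missing):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(missing) - 1))
    spans = ", ".join(f"{expected[a]}..{expected[b]}" for a, b in runs)
    longest = max(b - a + 1 for a, b in runs)
    if not allow_gaps:
        raise CoverageError(
            f"temperature series does not cover ({t_prev}, {t_now}]: missing {spans}"
        )
    if longest > max_gap_hours:
        raise CoverageError(
            f"gap of {longest} h exceeds max_gap_hours={max_gap_hours}: missing {spans}"
        )
    # linear infill of short gaps from the full series
    t_all = series.timestamps.asi8.astype(float)
    t_exp = expected.asi8.astype(float)
    if t_exp[0] < t_all[0] or t_exp[-1] > t_all[-1]:
        raise CoverageError(
            f"temperature series does not span ({t_prev}, {t_now}]"
        )
    return np.interp(t_exp, t_all, series.values)


def compute_fdi(
    series: TemperatureSeries,
    t_base: float,
    t_prev,
    t_now,
    *,
    allow_gaps: bool = False,
    max_gap_hours: int = 3,
) -> float:
    """FDI over the half-open interval (t_prev, t_now], in degC*h.

    Missing hours inside the interval raise :class:`CoverageError` unless
    ``allow_gaps`` is set, in which case gaps of at most ``max_gap_hours``
    are filled by linear interpolation.
    """
    t_prev = pd.Timestamp(t_prev)
    t_now = pd.Timestamp(t_now)
    if not t_prev < t_now:
        raise ValueError("t_prev must precede t_now")
    vals = _interval_values(series, t_prev, t_now, allow_gaps, max_gap_hours)
    return float(np.minimum(vals - t_base, 0.0).sum())


def fdi_series(
    series: TemperatureSeries,
    t_base: float,
    schedule,
    *,
    allow_gaps: bool = False,
    max_gap_hours: int = 3,
) -> FDISeries:
    """FDI per consecutive interval of a sorted measurement schedule."""
    sched = _as_datetime_index(schedule)
    if sched.size < 2:
        raise InsufficientDataError("schedule needs at least 2 time points")
    vals = [
        compute_fdi(
            series, t_base, sched[i - 1], sched[i],
            allow_gaps=allow_gaps, max_gap_hours=max_gap_hours,
        )
        for i in range(1, sched.size)
    ]
    return FDISeries(sched[1:], np.asarray(vals))


# ---------------------------------------------------------------------------
# canopy-cover traits


def delta_cc(cc: CanopyCoverSeries) -> DeltaCCSeries:
    """Raw CC differences between consecutive measurement dates."""
    if len(cc) < 2:
        raise InsufficientDataError("need at least 2 CC measurements")
    return DeltaCCSeries(
        cc.unit_id, cc.genotype, cc.dates[1:], np.diff(cc.cc), daily=False
    )


def interpolate_daily(cc: CanopyCoverSeries) -> DeltaCCSeries:
    """Daily CC differences after linear interpolation to calendar days.

    CC is interpolated linearly to every day between the first and last
    measurement and then first-differenced, which removes the bias of
    unequal measurement intervals.  The daily differences telescope: summed
    over an original interval they reproduce the raw interval difference.
    """
    if len(cc) < 2:
        raise InsufficientDataError("need at least 2 CC measurements")
    days = pd.date_range(cc.dates[0].normalize(), cc.dates[-1].normalize(), freq="D")
    daily_cc = np.interp(
        days.asi8.astype(float), cc.dates.asi8.astype(float), cc.cc
    )
    return DeltaCCSeries(
        cc.unit_id, cc.genotype, days[1:], np.diff(daily_cc), daily=True
    )


def select_negative(delta: DeltaCCSeries) -> DeltaCCSeries:
    """Keep only intervals with declining CC (the damage signal)."""
    keep = delta.delta_cc < 0
    return DeltaCCSeries(
        delta.unit_id,
        delta.genotype,
        delta.interval_ends[keep],
        delta.delta_cc[keep],
        daily=delta.daily,
    )


def predict_delta_cc(
    fdi: FDISeries,
    sensitivity: SensitivityLike,
    genotype: str | None = None,
    unit_id: str = "predicted",
) -> DeltaCCSeries:
    """Predicted CC change per interval, ``dCC = s * FDI`` (all <= 0)."""
    if isinstance(sensitivity, Mapping):
        if genotype not in sensitivity:
            raise KeyError(f"genotype {genotype!r} not present in sensitivity map")
        s = float(sensitivity[genotype])
    else:
        s = float(sensitivity)
    if s < 0:
        raise ValueError("sensitivity must be >= 0")
    return DeltaCCSeries(
        unit_id, genotype or "", fdi.interval_ends, s * fdi.fdi, daily=False
    )
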