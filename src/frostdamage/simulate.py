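"""Synthetic winter seasons: temperature courses and canopy-cover panels.

The generator emulates the study conditions of a winter-wheat field
season: an hourly air-temperature trajectory over the first 150 days
after sowing (seasonal trend + diurnal cycle + AR(1) noise, with injected
cold spells), and per-sowing-row canopy-cover trajectories for a panel of
genotypes whose declines obey the linear damage model
``dCC(d) = s_g * FDI_daily(d)`` at known (lag, smoothing, base
temperature).  Damage is applied on the daily grid so that the
analysis-side daily interpolation is exact when measurements are daily,
which keeps exact-recovery tests well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (
    DAY,
    HOUR,
    CanopyCoverSeries,
    CoverageError,
    FDIParams,
    TemperatureSeries,
)
from .estimation import _DailyFDI

__all__ = [
    "ColdSpell",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_temperature",
    "simulate_cc",
    "make_recovery_dataset",
    "PRESETS",
]


@dataclass(frozen=True)
class ColdSpell:
    """A cold spell depressing the seasonal trend to a given floor.

    The depression is trapezoidal: it deepens linearly over
    ``ramp_days``, sits on a plateau at ``min_temp_c``, and decays over
    ``ramp_days`` again -- the multi-day plateau of a winter blocking
    high.  ``min_temp_c`` is the floor of the *trend*; the diurnal cycle
    and the AR(1) noise ride on top, so realized air minima are lower.
    """

    start_day: float
    length_days: float
    min_temp_c: float
    ramp_days: float = 2.0

    def __post_init__(self):
        if self.length_days <= 0:
            raise ValueError("cold spell length must be positive")
        if not 0 < self.ramp_days <= self.length_days / 2:
            raise ValueError("ramp_days must lie in (0, length_days/2]")

    @property
    def end_day(self) -> float:
        return self.start_day + self.length_days

    def shape(self, t_rel: np.ndarray) -> np.ndarray:
        """Depression profile in [0, 1] as a function of days since onset."""
        return np.clip(
            np.minimum(t_rel / self.ramp_days, (self.length_days - t_rel) / self.ramp_days),
            0.0,
            1.0,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and sampling design of one synthetic season."""

    seed: int
    n_days: int = 150
    sowing_date: str = "2017-10-17"
    temp_lead_days: int = 14
    seasonal_mean: float = 4.0
    seasonal_amplitude: float = 5.0
    das_coldest: float = 90.0
    diurnal_amplitude: float = 4.0
    ar1_coeff: float = 0.8
    ar1_sd: float = 1.5
    cold_spells: tuple = ()
    true_params: FDIParams = field(
        default_factory=lambda: FDIParams(t_base=-9.0, lag_days=3, smooth_hours=18)
    )
    genotypes: Mapping[str, float] = field(default_factory=lambda: {"G01": 2e-3})
    rows_per_genotype: int = 7
    schedule_days: tuple = ()
    cc_initial: float = 0.3
    growth_rate: float = 0.0
    growth_plateau: float = 0.95
    growth_base_temp: float = 0.0
    cc_noise_sd: float = 0.0
    meas_noise_sd: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        spells = tuple(sorted(self.cold_spells, key=lambda s: s.start_day))
        for a, b in zip(spells, spells[1:]):
            if b.start_day < a.end_day:
                raise ValueError(
                    f"cold spells overlap: [{a.start_day}, {a.end_day}] and "
                    f"[{b.start_day}, {b.end_day}]"
                )
        object.__setattr__(self, "cold_spells", spells)
        sched = tuple(self.schedule_days) or tuple(range(0, self.n_days + 1, 7))
        if min(sched) < 0 or max(sched) > self.n_days:
            raise ValueError("schedule_days outside the simulated span")
        object.__setattr__(self, "schedule_days", tuple(sorted(sched)))
        intervals = np.diff(self.schedule_days)
        if self.n_days < self.true_params.lag_days + 2 * intervals.max(initial=0):
            raise ValueError("n_days too short for the lag and schedule")

    @property
    def sowing(self) -> pd.Timestamp:
        return pd.Timestamp(self.sowing_date)


@dataclass(frozen=True)
class SimulatedDataset:
    """One synthetic season: temperature, CC panel, and the ground truth."""

    temperature: TemperatureSeries
    cc: tuple
    truth: FDIParams
    config: SimulationConfig
    configs: tuple = ()


def _rngs(config: SimulationConfig) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(ss) for ss in children)


def _trend(config: SimulationConfig, das: np.ndarray) -> np.ndarray:
    trend = config.seasonal_mean - config.seasonal_amplitude * np.cos(
        2 * np.pi * (das - config.das_coldest) / 365.0
    )
    for spell in config.cold_spells:
        inside = (das >= spell.start_day) & (das <= spell.end_day)
        if not inside.any():
            continue
        center = spell.start_day + spell.length_days / 2.0
        base = config.seasonal_mean - config.seasonal_amplitude * np.cos(
            2 * np.pi * (center - config.das_coldest) / 365.0
        )
        depth = base - spell.min_temp_c
        if depth > 0:
            trend[inside] -= depth * spell.shape(das[inside] - spell.start_day)
    return trend


def simulate_temperature(config: SimulationConfig) -> TemperatureSeries:
    """Hourly temperatures: trend + diurnal sinus + AR(1) noise.

    The series starts ``temp_lead_days`` before sowing so that lagged
    trajectories (lags up to 10 d) still cover the first measured days.
    """
    rng = _rngs(config)[0]
    sow = config.sowing
    idx = pd.date_range(
        sow - config.temp_lead_days * DAY + HOUR, sow + config.n_days * DAY, freq="h"
    )
    das = (idx - sow) / DAY
    trend = _trend(config, np.asarray(das, dtype=float))
    diurnal = -config.diurnal_amplitude * np.cos(2 * np.pi * (idx.hour - 14) / 24.0)
    if config.ar1_sd > 0:
        innov_sd = config.ar1_sd * np.sqrt(1.0 - config.ar1_coeff**2)
        eps = rng.normal(0.0, innov_sd, idx.size)
        eps[0] = rng.normal(0.0, config.ar1_sd)
        noise = lfilter([1.0], [1.0, -config.ar1_coeff], eps)
    else:
        noise = 0.0
    return TemperatureSeries(idx, trend + diurnal + noise)


def _daily_cc_matrix(
    config: SimulationConfig, temperature: TemperatureSeries
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Simulate daily CC for every unit; returns (n_units, n_days+1) matrix."""
    sow = config.sowing
    day_ends = (sow + pd.to_timedelta(np.arange(1, config.n_days + 1), "D")).asi8
    p = config.true_params
    try:
        fdi_daily = _DailyFDI(temperature, p.lag_days, p.smooth_hours, day_ends)(p.t_base)
    except CoverageError as exc:
        raise CoverageError(f"temperature does not cover the schedule plus lag: {exc}")

    units = [
        (f"{g}_r{r}", g)
        for g in config.genotypes
        for r in range(1, config.rows_per_genotype + 1)
    ]
    s_vec = np.array([config.genotypes[g] for _, g in units])
    rng = _rngs(config)[1]
    n_units = len(units)
    eps = (
        rng.normal(0.0, config.cc_noise_sd, (n_units, config.n_days))
        if config.cc_noise_sd > 0
        else np.zeros((n_units, config.n_days))
    )
    # thermal-time-driven logistic growth: near zero in deep winter, the
    # spring rise follows accumulating degree days above growth_base_temp
    ts_pos = temperature.timestamps.searchsorted(
        pd.DatetimeIndex(day_ends - DAY.value + HOUR.value)
    )
    day_mean = np.array(
        [temperature.values[p : p + 24].mean() for p in ts_pos]
    )
    gdd = np.maximum(day_mean - config.growth_base_temp, 0.0)
    cc = np.empty((n_units, config.n_days + 1))
    cc[:, 0] = config.cc_initial
    for d in range(1, config.n_days + 1):
        prev = cc[:, d - 1]
        growth = (
            config.growth_rate * gdd[d - 1] * prev * (1.0 - prev / config.growth_plateau)
        )
        cc[:, d] = np.clip(
            prev + growth + s_vec * fdi_daily[d - 1] + eps[:, d - 1], 0.0, 1.0
        )
    return cc, units


def simulate_cc(
    config: SimulationConfig, temperature: TemperatureSeries
) -> tuple[tuple[CanopyCoverSeries, ...], FDIParams]:
    """Simulate the CC panel and sample it at the measurement schedule.

    Returns the per-unit series and the ground-truth parameters (with the
    genotype sensitivity map attached).
    """
    cc, units = _daily_cc_matrix(config, temperature)
    sched = np.asarray(config.schedule_days)
    dates = config.sowing + pd.to_timedelta(sched, "D")
    sampled = cc[:, sched]
    if config.meas_noise_sd > 0:
        rng = _rngs(config)[2]
        sampled = np.clip(
            sampled + rng.normal(0.0, config.meas_noise_sd, sampled.shape), 0.0, 1.0
        )
    series = tuple(
        CanopyCoverSeries(uid, g, dates, sampled[i])
        for i, (uid, g) in enumerate(units)
    )
    truth = config.true_params.replace(sensitivity=dict(config.genotypes))
    return series, truth


# ---------------------------------------------------------------------------
# presets


def _panel(seed: int, n: int = 36) -> dict[str, float]:
    """Genotype panel with sensitivities drawn uniformly in [5e-4, 5e-3]."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    s = rng.uniform(5e-4, 5e-3, n)
    return {f"G{i + 1:02d}": float(s[i]) for i in range(n)}


def _irregular_schedule(seed: int, n_days: int) -> tuple[int, ...]:
    """Roughly weekly measurements with irregular intervals of 5-9 days."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    days = [0]
    while days[-1] < n_days:
        days.append(days[-1] + int(rng.integers(5, 10)))
    if days[-1] > n_days:
        days[-1] = n_days
    return tuple(dict.fromkeys(days))


PRESETS = ("noiseless", "field_like", "sparse_stress")

# season archetypes: one winter with its multi-day severe plateau late
# (~DAS 130) and one with it early (~DAS 120), each with four frost
# events: two short deep snaps, a weak spell and the plateau
_SPELLS_LATE = (
    ColdSpell(start_day=98, length_days=3, min_temp_c=-10.2, ramp_days=1.0),
    ColdSpell(start_day=115, length_days=5, min_temp_c=-7.8, ramp_days=1.5),
    ColdSpell(start_day=131, length_days=6, min_temp_c=-8.7, ramp_days=2.0),
    ColdSpell(start_day=145, length_days=3, min_temp_c=-10.2, ramp_days=1.0),
)
_SPELLS_EARLY = (
    ColdSpell(start_day=97, length_days=3, min_temp_c=-10.2, ramp_days=1.0),
    ColdSpell(start_day=110, length_days=5, min_temp_c=-7.8, ramp_days=1.5),
    ColdSpell(start_day=120, length_days=6, min_temp_c=-8.7, ramp_days=2.0),
    ColdSpell(start_day=143, length_days=3, min_temp_c=-10.2, ramp_days=1.0),
)
_MILD_SPELL = ColdSpell(start_day=120, length_days=3, min_temp_c=-5.0, ramp_days=1.0)


def _field_noise_sd(config: SimulationConfig) -> float:
    """Observation noise at 10% of the mean absolute measured dCC."""
    quiet = replace(config, cc_noise_sd=0.0, meas_noise_sd=0.0)
    temp = simulate_temperature(quiet)
    cc, _ = _daily_cc_matrix(quiet, temp)
    sampled = cc[:, np.asarray(quiet.schedule_days)]
    return 0.1 * float(np.abs(np.diff(sampled, axis=1)).mean())


def _season_config(seed, sowing, spells, panel, truth):
    config = SimulationConfig(
        seed=seed,
        sowing_date=sowing,
        cold_spells=spells,
        true_params=truth,
        genotypes=panel,
        rows_per_genotype=7,
        schedule_days=_irregular_schedule(seed, 150),
        cc_initial=0.6,
        growth_rate=0.004,
    )
    return replace(config, meas_noise_sd=_field_noise_sd(config))


def make_recovery_dataset(preset: str, seed: int) -> SimulatedDataset:
    """A ready-made recovery study with the global crop truth
    (lag 3 d, smoothing 18 h, base temperature -9 degC).

    ``noiseless``
        One season, zero noise, zero growth, daily measurements: the
        step-wise fit must recover the truth exactly.
    ``field_like``
        The two-season fitting panel the estimation procedure is meant
        for: 36 genotypes x 7 rows in each of two winters (one with the
        severe spell late, one early), irregular roughly weekly
        measurements, thermal-time growth, and observation noise at 10%
        of the mean absolute measured dCC.
    ``sparse_stress``
        One season with a single mild spell whose damage stays below the
        daily growth, so declines rarely surface in dCC and most
        genotype sensitivities come out not estimable or near zero.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    truth = FDIParams(t_base=-9.0, lag_days=3, smooth_hours=18)
    panel = _panel(seed)
    if preset == "noiseless":
        return _build(
            SimulationConfig(
                seed=seed,
                cold_spells=_SPELLS_LATE,
                true_params=truth,
                genotypes=panel,
                rows_per_genotype=2,
                schedule_days=tuple(range(0, 151)),
                cc_initial=0.6,
                growth_rate=0.0,
            )
        )
    if preset == "field_like":
        cfg1 = _season_config(seed * 2 + 1, "2017-10-17", _SPELLS_LATE, panel, truth)
        cfg2 = _season_config(seed * 2 + 2, "2018-10-17", _SPELLS_EARLY, panel, truth)
        seasons = []
        for year, cfg in enumerate((cfg1, cfg2), start=1):
            temp = simulate_temperature(cfg)
            cc, _ = simulate_cc(cfg, temp)
            cc = tuple(
                CanopyCoverSeries(f"y{year}_{c.unit_id}", c.genotype, c.dates, c.cc)
                for c in cc
            )
            seasons.append((temp, cc))
        temp = TemperatureSeries(
            seasons[0][0].timestamps.append(seasons[1][0].timestamps),
            np.concatenate([seasons[0][0].values, seasons[1][0].values]),
        )
        return SimulatedDataset(
            temperature=temp,
            cc=seasons[0][1] + seasons[1][1],
            truth=truth.replace(sensitivity=dict(panel)),
            config=cfg1,
            configs=(cfg1, cfg2),
        )
    config = SimulationConfig(
        seed=seed,
        cold_spells=(_MILD_SPELL,),
        true_params=truth,
        genotypes=panel,
        rows_per_genotype=7,
        schedule_days=_irregular_schedule(seed, 150),
        cc_initial=0.3,
        growth_rate=0.004,
    )
    return _build(replace(config, meas_noise_sd=_field_noise_sd(config)))


def _build(config: SimulationConfig) -> SimulatedDataset:
    temp = simulate_temperature(config)
    cc, truth = simulate_cc(config, temp)
    return SimulatedDataset(
        temperature=temp, cc=cc, truth=truth, config=config, configs=(config,)
    )
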