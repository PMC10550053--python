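"""Step-wise estimation of the frost-damage model parameters.

The crop-level parameters (lag, smoothing span, base temperature) and the
genotype-level sensitivity are estimated in three steps on pooled,
row-based data:

1. the lag is chosen on a 0-10 day grid, with base temperature and
   sensitivity fitted as nuisance parameters per candidate and discarded;
2. with the lag fixed, the smoothing span is chosen on a 0-56 h grid
   (6 h increments) the same way;
3. with both fixed, the base temperature is re-estimated globally by
   maximising the pooled Pearson correlation between daily negative dCC
   and the FDI, and the sensitivity is re-estimated globally and, if
   requested, per genotype by RMSE minimisation.

Base temperature is fitted by correlation rather than error because an
error criterion is minimised by predicting zero everywhere; sensitivity is
then the RMSE-minimising slope of the no-intercept regression of dCC on
FDI, which has the closed form ``s = sum(F*d) / sum(F^2)`` clipped at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .core import (
    DAY,
    HOUR,
    CanopyCoverSeries,
    DeltaCCSeries,
    FDIParams,
    FDISeries,
    InsufficientDataError,
    TemperatureSeries,
    _interval_values,
    fdi_series,
    lag_temperature,
    predict_delta_cc,
    smooth_temperature,
)

__all__ = [
    "EstimationInfeasibleError",
    "UndefinedSensitivityError",
    "GridProfile",
    "Diagnostics",
    "FitResult",
    "ScoringTable",
    "FrostDamageIndexModel",
    "pair_observations",
    "estimate_sensitivity",
    "estimate_tbase",
    "grid_search_lag",
    "grid_search_smoothing",
    "select_lag",
    "select_smoothing",
    "stepwise_fit",
    "diagnostics",
    "validate_against_scoring",
    "DEFAULT_LAG_GRID",
    "DEFAULT_SMOOTH_GRID",
]

DEFAULT_LAG_GRID: tuple[int, ...] = tuple(range(11))
#: 0..54 in 6 h increments with the 56 h endpoint appended.
DEFAULT_SMOOTH_GRID: tuple[int, ...] = tuple(range(0, 55, 6)) + (56,)


class EstimationInfeasibleError(RuntimeError):
    """No parameter candidate admits a defined fitting objective."""


class UndefinedSensitivityError(RuntimeError):
    """Sensitivity cannot be identified (all FDI values are zero)."""


@dataclass(frozen=True)
class GridProfile:
    """Objective profile of a one-dimensional parameter grid search."""

    grid_values: np.ndarray
    pearson_r: np.ndarray
    rmse: np.ndarray
    n_points: np.ndarray
    t_base: np.ndarray = None
    sensitivity: np.ndarray = None

    def __post_init__(self):
        g = np.asarray(self.grid_values)
        r = np.asarray(self.pearson_r, dtype=float)
        e = np.asarray(self.rmse, dtype=float)
        n = np.asarray(self.n_points, dtype=int)
        if not (g.size == r.size == e.size == n.size):
            raise ValueError("profile columns differ in length")
        ok = ~np.isnan(r)
        if ((r[ok] < -1 - 1e-9) | (r[ok] > 1 + 1e-9)).any():
            raise ValueError("pearson_r outside [-1, 1]")
        if (e[~np.isnan(e)] < 0).any():
            raise ValueError("rmse must be >= 0")
        for name, val in (("grid_values", g), ("pearson_r", r), ("rmse", e), ("n_points", n)):
            object.__setattr__(self, name, val)
        if self.t_base is not None:
            object.__setattr__(self, "t_base", np.asarray(self.t_base, dtype=float))
        if self.sensitivity is not None:
            object.__setattr__(self, "sensitivity", np.asarray(self.sensitivity, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "grid_value": self.grid_values,
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "n_points": self.n_points,
        }
        if self.t_base is not None:
            cols["t_base"] = self.t_base
        if self.sensitivity is not None:
            cols["sensitivity"] = self.sensitivity
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class Diagnostics:
    """Goodness-of-fit summary of predictions against observations."""

    pearson_r: float | None
    rmse: float
    mae: float
    n: int

    @property
    def r_defined(self) -> bool:
        return self.pearson_r is not None


@dataclass(frozen=True)
class ScoringTable:
    """Visual frost-damage scorings, one integer grade 1-9 per genotype.

    Grade 1 means no visible damage, 9 a completely dead plant.
    """

    genotypes: tuple
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=int)
        if len(self.genotypes) != scores.size:
            raise ValueError("genotypes and scores differ in length")
        if scores.size and ((scores < 1) | (scores > 9)).any():
            raise ValueError("scores must lie in [1, 9]")
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "scores", scores)

    def as_mapping(self) -> dict:
        return dict(zip(self.genotypes, self.scores.tolist()))


@dataclass(frozen=True)
class FitResult:
    """Outcome of the step-wise fit: parameters, profiles, diagnostics."""

    params: FDIParams
    lag_profile: GridProfile
    smooth_profile: GridProfile
    tbase_search: dict
    diagnostics: Diagnostics
    per_genotype_s: dict | None
    observed: np.ndarray
    predicted: np.ndarray

    def to_dict(self) -> dict:
        """JSON-serialisable summary (profiles exported separately as CSV)."""
        sens = self.params.sensitivity
        return {
            "lag_days": int(self.params.lag_days),
            "smooth_hours": int(self.params.smooth_hours),
            "t_base": float(self.params.t_base),
            "sensitivity_global": float(sens) if not isinstance(sens, Mapping) else None,
            "per_genotype_s": {
                g: {"s": (None if s is None else float(s)), "n_obs": int(n)}
                for g, (s, n) in (self.per_genotype_s or {}).items()
            },
            "diagnostics": {
                "pearson_r": self.diagnostics.pearson_r,
                "rmse": self.diagnostics.rmse,
                "mae": self.diagnostics.mae,
                "n": self.diagnostics.n,
            },
            "tbase_search": {
                "grid": [float(v) for v in self.tbase_search["grid"]],
                "pearson_r": [
                    None if np.isnan(v) else float(v)
                    for v in self.tbase_search["pearson_r"]
                ],
                "selected": float(self.tbase_search["selected"]),
            },
        }


# ---------------------------------------------------------------------------
# pooled observations and fast daily FDI evaluation


@dataclass(frozen=True)
class PairedObservations:
    """Pooled (observed dCC, FDI) regression pairs on the daily grid."""

    observed: np.ndarray
    fdi: np.ndarray
    genotype: np.ndarray
    unit: np.ndarray
    days: pd.DatetimeIndex

    def __len__(self) -> int:
        return len(self.observed)


class _ObservationPool:
    """Negative daily dCC observations pooled across units.

    Each retained measurement interval with declining CC contributes one
    observation per calendar day: the interval's dCC spread evenly over
    its days (the daily interpolation).  The matching FDI of a day is the
    interval's FDI spread the same way -- the FDI is defined between
    measurement time points, and dividing both sides of the damage model
    by the interval length keeps the regression slope while removing the
    bias of unequal measurement intervals.
    """

    def __init__(self, deltas):
        obs, geno, unit, day, iid = [], [], [], [], []
        n_intervals = 0
        for item in deltas:
            ends, values, daily = self._intervals(item)
            start = None
            for t_prev, t_now, dcc in zip(ends[:-1], ends[1:], values):
                if dcc >= 0:
                    continue
                days = pd.date_range(t_prev + DAY, t_now, freq="D")
                length = days.size
                obs.append(np.full(length, dcc / length))
                day.append(days.asi8)
                iid.append(np.full(length, n_intervals))
                geno.extend([item.genotype] * length)
                unit.extend([item.unit_id] * length)
                n_intervals += 1
        self.observed = np.concatenate(obs) if obs else np.empty(0)
        self.genotype = np.asarray(geno, dtype=object)
        self.unit = np.asarray(unit, dtype=object)
        day_i8 = np.concatenate(day) if day else np.empty(0, dtype=np.int64)
        self.interval_id = (
            np.concatenate(iid) if iid else np.empty(0, dtype=np.int64)
        ).astype(np.int64)
        self.n_intervals = n_intervals
        self.interval_len = np.bincount(self.interval_id, minlength=n_intervals)
        self.unique_days, self.day_pos = np.unique(day_i8, return_inverse=True)
        self.days = pd.DatetimeIndex(day_i8)

    @staticmethod
    def _intervals(item):
        """Interval ends (incl. the leading start) and per-interval dCC."""
        if isinstance(item, CanopyCoverSeries):
            if len(item) < 2:
                raise InsufficientDataError(
                    f"unit {item.unit_id!r}: need at least 2 CC measurements"
                )
            ends = item.dates.normalize()
            return ends, np.diff(item.cc), False
        if not item.daily:
            raise ValueError(
                f"unit {item.unit_id!r}: raw interval dCC lacks the first "
                "interval start; pass the CC series or daily dCC instead"
            )
        ends = item.interval_ends
        lead = pd.DatetimeIndex([ends[0] - DAY]).append(ends) if len(item) else ends
        return lead, item.delta_cc, True

    def fdi_per_obs(self, fdi_days: np.ndarray) -> np.ndarray:
        """Daily FDI share of each observation's measurement interval."""
        if len(self) == 0:
            return np.empty(0)
        totals = np.bincount(
            self.interval_id,
            weights=fdi_days[self.day_pos],
            minlength=self.n_intervals,
        )
        return (totals / self.interval_len)[self.interval_id]

    def __len__(self) -> int:
        return len(self.observed)


class _DailyFDI:
    """FDI per calendar day for a fixed (lag, smoothing) preprocessing.

    Precomputes the 24 processed hourly temperatures of each requested day
    so that evaluating a base-temperature candidate is a single vectorised
    reduction -- the inner loop of every grid search.
    """

    def __init__(
        self,
        temp: TemperatureSeries,
        lag_days: int,
        smooth_hours: int,
        day_ends_i8: np.ndarray,
    ):
        proc = lag_temperature(smooth_temperature(temp, smooth_hours), lag_days)
        offsets = HOUR.value * np.arange(1, 25)
        expected = (day_ends_i8[:, None] - DAY.value) + offsets[None, :]
        ts = proc.timestamps.asi8
        pos = np.searchsorted(ts, expected.ravel())
        pos_ok = (pos < ts.size) & (ts[np.minimum(pos, ts.size - 1)] == expected.ravel())
        if pos_ok.all():
            self.matrix = proc.values[pos].reshape(expected.shape)
        else:
            # gappy series: per-day fallback with explicit coverage errors
            rows = []
            ends = pd.DatetimeIndex(day_ends_i8)
            for end in ends:
                rows.append(
                    _interval_values(proc, end - DAY, end, allow_gaps=False, max_gap_hours=0)
                )
            self.matrix = np.asarray(rows)

    def __call__(self, t_base: float) -> np.ndarray:
        return np.minimum(self.matrix - t_base, 0.0).sum(axis=1)


def _as_pool(deltas) -> _ObservationPool:
    if isinstance(deltas, _ObservationPool):
        return deltas
    return _ObservationPool(deltas)


def pair_observations(
    deltas, temp: TemperatureSeries, params: FDIParams
) -> PairedObservations:
    """Assemble the pooled (observed dCC, FDI) regression pairs.

    One pair per retained negative daily interval per unit.  Both sides
    of a pair are the interval quantities spread over the interval's
    days: the daily-interpolated dCC and the measurement-interval FDI
    (computed from the lagged, smoothed temperature at
    ``params.t_base``) divided by the interval length.
    """
    pool = _as_pool(deltas)
    if len(pool) == 0:
        return PairedObservations(
            pool.observed, np.empty(0), pool.genotype, pool.unit, pool.days
        )
    dfdi = _DailyFDI(temp, params.lag_days, params.smooth_hours, pool.unique_days)
    f = pool.fdi_per_obs(dfdi(params.t_base))
    return PairedObservations(pool.observed, f, pool.genotype, pool.unit, pool.days)


# ---------------------------------------------------------------------------
# estimators for the individual parameters


def estimate_sensitivity(observed, fdi=None) -> float:
    """RMSE-minimising sensitivity of the no-intercept damage regression.

    Equals ``sum(F*d) / sum(F^2)`` clipped at zero: a negative slope would
    predict canopy growth from frost.
    """
    if fdi is None:  # PairedObservations
        observed, fdi = observed.observed, observed.fdi
    d = np.asarray(observed, dtype=float)
    f = np.asarray(fdi, dtype=float)
    if d.size != f.size:
        raise ValueError("observed and fdi differ in length")
    if d.size < 2:
        raise InsufficientDataError("need at least 2 (dCC, FDI) pairs")
    if not np.any(f != 0):
        raise UndefinedSensitivityError("all FDI values are zero")
    return max(0.0, float(np.dot(f, d) / np.dot(f, f)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _tbase_objective(pool: _ObservationPool, dfdi: _DailyFDI):
    d = pool.observed

    def objective(t_base: float) -> float:
        f = pool.fdi_per_obs(dfdi(t_base))
        if np.count_nonzero(f) < 2:
            return -np.inf
        r = _pearson(d, f)
        return -np.inf if np.isnan(r) else r

    return objective


def _estimate_tbase_record(
    deltas,
    temp: TemperatureSeries,
    lag_days: int,
    smooth_hours: int,
    bounds: tuple[float, float] = (-25.0, 0.0),
    coarse_step: float = 0.5,
) -> tuple[float, dict]:
    pool = _as_pool(deltas)
    if len(pool) < 2:
        raise EstimationInfeasibleError("fewer than 2 negative daily observations")
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("bounds must be a finite interval")
    dfdi = _DailyFDI(temp, lag_days, smooth_hours, pool.unique_days)
    objective = _tbase_objective(pool, dfdi)
    grid = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    r_grid = np.array([objective(tb) for tb in grid])
    if not np.isfinite(r_grid).any():
        raise EstimationInfeasibleError(
            "no base-temperature candidate yields >= 2 nonzero-FDI pairs"
        )
    finite = np.where(np.isfinite(r_grid), r_grid, -np.inf)
    best_r = finite.max()
    # tie-break a flat plateau (no new frost hours between candidates)
    # toward the warmest maximiser: the most parsimonious threshold
    best = int(np.flatnonzero(finite >= best_r - 1e-12)[-1])
    lo_b = grid[max(best - 1, 0)]
    hi_b = min(grid[min(best + 1, grid.size - 1)], hi)
    selected = float(grid[best])
    refined = None
    if hi_b > lo_b:
        res = optimize.minimize_scalar(
            lambda tb: -objective(tb) if np.isfinite(objective(tb)) else 1e300,
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-3},
        )
        if np.isfinite(res.fun) and -res.fun >= finite[best]:
            refined = float(res.x)
            selected = refined
    record = {
        "grid": grid,
        "pearson_r": np.where(np.isfinite(r_grid), r_grid, np.nan),
        "selected": selected,
        "refined": refined,
    }
    return selected, record


def estimate_tbase(
    deltas,
    temp: TemperatureSeries,
    lag_days: int = 0,
    smooth_hours: int = 0,
    bounds: tuple[float, float] = (-25.0, 0.0),
    coarse_step: float = 0.5,
) -> float:
    """Correlation-maximising base temperature (coarse grid + refinement)."""
    tb, _ = _estimate_tbase_record(deltas, temp, lag_days, smooth_hours, bounds, coarse_step)
    return tb


def diagnostics(observed, predicted) -> Diagnostics:
    """Pearson r, RMSE and MAE of predictions against observations.

    Pearson's r is ``None`` (flagged, not NaN) when either vector has zero
    variance.
    """
    d = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if d.size != p.size:
        raise ValueError("observed and predicted differ in length")
    if d.size < 2:
        raise InsufficientDataError("need at least 2 observations")
    resid = d - p
    r = _pearson(d, p)
    return Diagnostics(
        pearson_r=None if np.isnan(r) else r,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        n=int(d.size),
    )


def _fit_candidate(
    pool: _ObservationPool,
    temp: TemperatureSeries,
    lag_days: int,
    smooth_hours: int,
    bounds,
    coarse_step,
) -> tuple[float, float, float, float]:
    """Nuisance (t_base, s) fit for one grid candidate; returns r, rmse too."""
    tb, _ = _estimate_tbase_record(pool, temp, lag_days, smooth_hours, bounds, coarse_step)
    dfdi = _DailyFDI(temp, lag_days, smooth_hours, pool.unique_days)
    f = pool.fdi_per_obs(dfdi(tb))
    s = estimate_sensitivity(pool.observed, f)
    diag = diagnostics(pool.observed, s * f)
    r = diag.pearson_r if diag.pearson_r is not None else np.nan
    return tb, s, r, diag.rmse


def _profile_over(
    grid, pool, temp, bounds, coarse_step, *, lag_of, window_of
) -> GridProfile:
    r_list, e_list, tb_list, s_list = [], [], [], []
    for g in grid:
        try:
            tb, s, r, rmse = _fit_candidate(
                pool, temp, lag_of(g), window_of(g), bounds, coarse_step
            )
        except (EstimationInfeasibleError, UndefinedSensitivityError):
            tb, s, r, rmse = np.nan, np.nan, np.nan, np.nan
        tb_list.append(tb)
        s_list.append(s)
        r_list.append(r)
        e_list.append(rmse)
    if not np.isfinite(np.asarray(r_list, dtype=float)).any():
        raise EstimationInfeasibleError("no grid candidate admits a fit")
    return GridProfile(
        grid_values=np.asarray(list(grid)),
        pearson_r=r_list,
        rmse=e_list,
        n_points=np.full(len(list(grid)), len(pool)),
        t_base=tb_list,
        sensitivity=s_list,
    )


def grid_search_lag(
    deltas,
    temp: TemperatureSeries,
    lag_grid: Sequence[int] = DEFAULT_LAG_GRID,
    smooth_hours: int = 0,
    tbase_bounds=(-25.0, 0.0),
    tbase_step: float = 0.5,
) -> GridProfile:
    """Step 1: profile of pooled fit quality over candidate lags.

    For each lag the base temperature and sensitivity are fitted on pooled
    (genotype-unspecific) data and discarded; the profile records the
    resulting Pearson r and RMSE.
    """
    pool = _as_pool(deltas)
    grid = list(lag_grid)
    return _profile_over(
        grid, pool, temp, tbase_bounds, tbase_step,
        lag_of=lambda g: int(g), window_of=lambda g: smooth_hours,
    )


def grid_search_smoothing(
    deltas,
    temp: TemperatureSeries,
    lag_days: int,
    smooth_grid: Sequence[int] = DEFAULT_SMOOTH_GRID,
    tbase_bounds=(-25.0, 0.0),
    tbase_step: float = 0.5,
) -> GridProfile:
    """Step 2: profile over smoothing spans with the lag fixed."""
    pool = _as_pool(deltas)
    grid = list(smooth_grid)
    return _profile_over(
        grid, pool, temp, tbase_bounds, tbase_step,
        lag_of=lambda g: lag_days, window_of=lambda g: int(g),
    )


def _argopt(values, grid, maximize: bool):
    v = np.asarray(values, dtype=float)
    v = np.where(np.isnan(v), -np.inf if maximize else np.inf, v)
    opt = v.max() if maximize else v.min()
    cands = np.flatnonzero(v == opt)
    return grid[cands[np.argmin(np.asarray(grid)[cands])]] if len(cands) else grid[0]


def select_lag(profile: GridProfile) -> int:
    """Lag with the highest pooled Pearson r (ties to the smaller lag)."""
    order = np.argsort(profile.grid_values)
    g = profile.grid_values[order]
    return int(_argopt(profile.pearson_r[order], g, maximize=True))


def select_smoothing(profile: GridProfile, rule: str = "compromise") -> int:
    """Pick the smoothing span from a step-2 profile.

    ``max_r`` takes the correlation optimum, ``min_rmse`` the error
    optimum, and ``compromise`` (default) the grid value nearest the
    midpoint of the two, ties going to the smaller span.
    """
    order = np.argsort(profile.grid_values)
    g = profile.grid_values[order]
    if rule == "max_r":
        return int(_argopt(profile.pearson_r[order], g, maximize=True))
    if rule == "min_rmse":
        return int(_argopt(profile.rmse[order], g, maximize=False))
    if rule != "compromise":
        raise ValueError(f"unknown smoothing-selection rule {rule!r}")
    g_r = _argopt(profile.pearson_r[order], g, maximize=True)
    g_e = _argopt(profile.rmse[order], g, maximize=False)
    mid = 0.5 * (g_r + g_e)
    dist = np.abs(np.asarray(g, dtype=float) - mid)
    cands = np.flatnonzero(dist == dist.min())
    return int(g[cands[np.argmin(np.asarray(g)[cands])]])


def validate_against_scoring(per_genotype_s: Mapping, scoring) -> float:
    """Spearman rank correlation between sensitivities and visual scores.

    Accepts ``{genotype: s}`` or the ``{genotype: (s, n_obs)}`` form of
    :class:`FitResult`; genotypes with no estimate are skipped.  Ties are
    handled by average ranks.
    """
    score_map = scoring.as_mapping() if isinstance(scoring, ScoringTable) else dict(scoring)
    s_vals, scores = [], []
    for g, s in per_genotype_s.items():
        if isinstance(s, tuple):
            s = s[0]
        if s is None or g not in score_map:
            continue
        s_vals.append(float(s))
        scores.append(score_map[g])
    if len(s_vals) < 3:
        raise InsufficientDataError(
            f"only {len(s_vals)} genotypes in common; need >= 3"
        )
    rho = stats.spearmanr(s_vals, scores).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# the estimator


class FrostDamageIndexModel(BaseEstimator):
    """Frost-damage model fitted by the three-step grid procedure.

    Fit on a collection of per-row canopy-cover series together with the
    hourly temperature trajectory of the same season.  Fitted crop
    parameters (lag, smoothing span, base temperature) are global;
    sensitivity is estimated globally and optionally per genotype.

    Parameters
    ----------
    lag_grid : sequence of int, default 0..10 days
    smooth_grid : sequence of int, default 0,6,...,54,56 hours
    tbase_bounds : (float, float), default (-25, 0) degC
    tbase_step : float, default 0.5 degC coarse-grid step
    smoothing_rule : {"compromise", "max_r", "min_rmse"}
    per_genotype : bool, estimate a sensitivity per genotype
    min_genotype_obs : int, minimum negative daily observations for a
        genotype-specific sensitivity; below it the genotype is reported
        as not estimable (``None``) rather than near-zero.

    Attributes
    ----------
    lag_days_, smooth_hours_, t_base_, sensitivity_ : fitted parameters
    per_genotype_s_ : dict genotype -> (s or None, n_obs)
    result_ : :class:`FitResult` with grid profiles and diagnostics
    """

    def __init__(
        self,
        lag_grid=DEFAULT_LAG_GRID,
        smooth_grid=DEFAULT_SMOOTH_GRID,
        tbase_bounds=(-25.0, 0.0),
        tbase_step=0.5,
        smoothing_rule="compromise",
        per_genotype=True,
        min_genotype_obs=5,
    ):
        self.lag_grid = lag_grid
        self.smooth_grid = smooth_grid
        self.tbase_bounds = tbase_bounds
        self.tbase_step = tbase_step
        self.smoothing_rule = smoothing_rule
        self.per_genotype = per_genotype
        self.min_genotype_obs = min_genotype_obs

    def fit(self, X, y=None, *, temperature: TemperatureSeries):
        """Run the step-wise fit.

        ``X`` is a sequence of :class:`CanopyCoverSeries` (interpolated to
        the daily grid and filtered to declines internally) or of daily
        :class:`DeltaCCSeries`.
        """
        pool = _as_pool(X)
        if len(pool) < 2:
            raise InsufficientDataError(
                "fewer than 2 negative daily dCC observations in the input"
            )
        try:
            lag_profile = grid_search_lag(
                pool, temperature, self.lag_grid, 0, self.tbase_bounds, self.tbase_step
            )
        except EstimationInfeasibleError as exc:
            raise EstimationInfeasibleError(f"lag grid search: {exc}") from exc
        lag = select_lag(lag_profile)
        try:
            smooth_profile = grid_search_smoothing(
                pool, temperature, lag, self.smooth_grid, self.tbase_bounds, self.tbase_step
            )
        except EstimationInfeasibleError as exc:
            raise EstimationInfeasibleError(f"smoothing grid search: {exc}") from exc
        window = select_smoothing(smooth_profile, self.smoothing_rule)
        try:
            t_base, record = _estimate_tbase_record(
                pool, temperature, lag, window, self.tbase_bounds, self.tbase_step
            )
        except EstimationInfeasibleError as exc:
            raise EstimationInfeasibleError(f"base-temperature estimation: {exc}") from exc
        dfdi = _DailyFDI(temperature, lag, window, pool.unique_days)
        f = pool.fdi_per_obs(dfdi(t_base))
        try:
            s_global = estimate_sensitivity(pool.observed, f)
        except UndefinedSensitivityError as exc:
            raise EstimationInfeasibleError(f"sensitivity estimation: {exc}") from exc
        predicted = s_global * f
        diag = diagnostics(pool.observed, predicted)

        per_g = None
        if self.per_genotype:
            per_g = {}
            for g in sorted(set(pool.genotype.tolist())):
                mask = pool.genotype == g
                n = int(mask.sum())
                fg, dg = f[mask], pool.observed[mask]
                if n < self.min_genotype_obs or not np.any(fg != 0):
                    per_g[g] = (None, n)
                else:
                    per_g[g] = (estimate_sensitivity(dg, fg), n)

        self.lag_days_ = lag
        self.smooth_hours_ = window
        self.t_base_ = t_base
        self.sensitivity_ = s_global
        self.per_genotype_s_ = per_g
        self.result_ = FitResult(
            params=FDIParams(
                t_base=t_base, lag_days=lag, smooth_hours=window, sensitivity=s_global
            ),
            lag_profile=lag_profile,
            smooth_profile=smooth_profile,
            tbase_search=record,
            diagnostics=diag,
            per_genotype_s=per_g,
            observed=pool.observed,
            predicted=predicted,
        )
        return self

    def _sensitivity_for(self, genotype: str | None) -> float:
        if genotype is not None and self.per_genotype_s_:
            if genotype not in self.per_genotype_s_:
                raise KeyError(f"genotype {genotype!r} was not in the fitting data")
            s, _ = self.per_genotype_s_[genotype]
            if s is not None:
                return s
        return self.sensitivity_

    def predict(
        self, schedule, *, temperature: TemperatureSeries, genotype: str | None = None
    ) -> DeltaCCSeries:
        """Predicted dCC per interval of a measurement schedule."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "t_base_")
        proc = lag_temperature(
            smooth_temperature(temperature, self.smooth_hours_), self.lag_days_
        )
        f = fdi_series(proc, self.t_base_, schedule)
        return predict_delta_cc(f, self._sensitivity_for(genotype), genotype or None)

    def fdi(self, schedule, *, temperature: TemperatureSeries) -> FDISeries:
        """FDI per interval under the fitted preprocessing and threshold."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "t_base_")
        proc = lag_temperature(
            smooth_temperature(temperature, self.smooth_hours_), self.lag_days_
        )
        return fdi_series(proc, self.t_base_, schedule)


def stepwise_fit(cc_or_deltas, temp: TemperatureSeries, config=None, **overrides) -> FitResult:
    """Functional wrapper around :class:`FrostDamageIndexModel`.

    ``config`` may be a mapping of estimator parameters; keyword overrides
    take precedence.
    """
    params = dict(config or {})
    params.update(overrides)
    model = FrostDamageIndexModel(**params)
    model.fit(cc_or_deltas, temperature=temp)
    return model.result_
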