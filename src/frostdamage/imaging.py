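"""Sowing-row detection and per-row canopy cover from binary plant masks.

A wheat plot holds 9 parallel sowing rows.  Given an aligned binary
plant/soil mask, the plot is first de-rotated by brute force: the image is
rotated over a small angle grid, the per-column plant-pixel sums are
filtered with a mean sliding window, and the angle maximising the max-min
contrast of the filtered profile wins.  A 9-fold sinus is then fitted to
the column sums of the de-rotated mask; its maxima are the row centres.
Canopy cover is the plant-pixel ratio within each row's vertical band,
and only the inner 7 of the 9 rows are used (the outer two border the
neighbouring plots).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NoRowSignalError",
    "RowDetectionError",
    "GeometryError",
    "PlotMask",
    "RowLayout",
    "column_profile",
    "sliding_mean",
    "rotate_mask",
    "optimal_rotation",
    "fit_row_sinus",
    "extract_row_cc",
    "render_synthetic_mask",
    "SowingRowExtractor",
    "DEFAULT_ANGLE_GRID",
]

#: 0.2-degree steps spanning -1.5..1.5 degrees; centred on zero so an
#: already-straight plot maps to a 0.0 correction.
DEFAULT_ANGLE_GRID: tuple[float, ...] = tuple(np.round(0.2 * np.arange(-7, 8), 1))


class NoRowSignalError(ValueError):
    """The mask carries no plant signal to detect rows from."""


class RowDetectionError(RuntimeError):
    """The 9-row sinus pattern could not be fitted."""


class GeometryError(ValueError):
    """A row band falls outside the mask."""


@dataclass(frozen=True)
class PlotMask:
    """Binary plant/soil mask of one plot (1 = plant, 0 = soil)."""

    pixels: np.ndarray
    pixel_scale: float | None = None
    plot_id: str = ""
    date: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a nonempty 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask must be strictly binary (0/1)")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RowLayout:
    """Fitted plot rotation and 9-row geometry (columns in pixels)."""

    rotation_deg: float
    row_centers: np.ndarray
    period_px: float
    band_halfwidth_px: float
    inner_rows: tuple = tuple(range(1, 8))

    def __post_init__(self):
        centers = np.asarray(self.row_centers, dtype=float)
        if centers.size != 9:
            raise ValueError("exactly 9 row centers required")
        if not (np.diff(centers) > 0).all():
            raise ValueError("row centers must be strictly increasing")
        if len(self.inner_rows) != 7:
            raise ValueError("inner_rows must hold 7 indices")
        object.__setattr__(self, "row_centers", centers)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": float(self.rotation_deg),
            "row_centers": [float(c) for c in self.row_centers],
            "period_px": float(self.period_px),
            "band_halfwidth_px": float(self.band_halfwidth_px),
            "inner_rows": list(self.inner_rows),
        }


def column_profile(mask: PlotMask) -> np.ndarray:
    """Plant-pixel sum per image column."""
    return mask.pixels.sum(axis=0).astype(np.int64)


def sliding_mean(profile: np.ndarray, window: int = 100) -> np.ndarray:
    """Centred mean filter with edge-shrinking windows; length preserved."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return (
        pd.Series(np.asarray(profile, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def rotate_mask(mask: PlotMask, angle_deg: float) -> PlotMask:
    """Rotate counter-clockwise with nearest-neighbour resampling.

    Nearest-neighbour keeps the mask strictly binary, which the column
    sums rely on.
    """
    if angle_deg == 0:
        return mask
    rot = ndimage.rotate(
        mask.pixels, angle_deg, reshape=False, order=0, prefilter=False
    )
    return PlotMask(rot, mask.pixel_scale, mask.plot_id, mask.date)


def optimal_rotation(
    mask: PlotMask,
    angle_grid: Sequence[float] = DEFAULT_ANGLE_GRID,
    window: int = 100,
) -> float:
    """Brute-force de-rotation angle of the plot.

    For every candidate the mask is rotated, the filtered column profile
    computed, and its max-min contrast recorded; the contrast-maximising
    angle is returned.  Positive angles are counter-clockwise corrections,
    so a clockwise-skewed plot yields a positive optimum.  Ties go to the
    angle of smallest magnitude, then to the negative one.
    """
    if mask.pixels.sum() == 0:
        raise NoRowSignalError("all-zero mask: no plant signal")
    # column sums of the rotated mask computed by rotating the plant-pixel
    # coordinates directly (same nearest-pixel binning, no full-image warp)
    ys, xs = np.nonzero(mask.pixels)
    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dx, dy = xs - cx, ys - cy
    scores = []
    for a in angle_grid:
        th = np.deg2rad(a)
        cols = np.round(np.cos(th) * dx + np.sin(th) * dy + cx).astype(np.int64)
        cols = cols[(cols >= 0) & (cols < w)]
        prof = sliding_mean(np.bincount(cols, minlength=w), window)
        scores.append(prof.max() - prof.min())
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores[i], abs(angle_grid[i]), angle_grid[i]),
    )
    return float(angle_grid[order[0]])


def _sinus(x, offset, amp, period, phase):
    return offset + amp * np.sin(2 * np.pi * x / period + phase)


def fit_row_sinus(profile: np.ndarray, n_rows: int = 9) -> RowLayout:
    """Least-squares fit of the 9-fold sinus row pattern to column sums.

    The plot extent is co-estimated from the smoothed profile so the soil
    margins around the plot do not bias the fit; the period is
    initialised from the extent and bounded to +-10% of it, while offset,
    amplitude and phase are free.  Row centres are the sinus maxima
    inside the plot extent.
    """
    y_full = np.asarray(profile, dtype=float)
    y = y_full
    width = y.size
    if width < 2 * n_rows:
        raise RowDetectionError("profile too short for a row fit")
    if np.ptp(y) == 0:
        raise RowDetectionError("flat profile: row pattern unidentifiable")
    # co-estimate the plot extent: the mask carries soil margins around the
    # plot, and fitting the sinus across them biases the period.  The
    # extent is where the smoothed profile rises above the soil floor;
    # its span covers the outer strip edges, i.e. n_rows - 1 periods plus
    # the two outer half-strips.
    sm = sliding_mean(y, min(100, max(1, width // 4)))
    thr = sm.min() + 0.1 * (sm.max() - sm.min())
    above = np.flatnonzero(sm > thr)
    lo, hi = int(above[0]), int(above[-1]) + 1
    x = np.arange(lo, hi, dtype=float)
    y = y[lo:hi]
    # the inter-row period from the autocorrelation of the mean-subtracted
    # profile: its first peak is insensitive to plot margins and to the
    # cover of individual rows
    yc = y - y.mean()
    k_lo = max(2, int((hi - lo) / (n_rows + 3)))
    k_hi = min(y.size - 2, int(np.ceil((hi - lo) / (n_rows - 2))))
    lags = np.arange(k_lo, k_hi + 1)
    ac = np.array([np.dot(yc[:-k], yc[k:]) / (y.size - k) for k in lags])
    p0_period = float(lags[int(np.argmax(ac))])
    # initialise by linear least squares (offset + sin + cos) on a small
    # period grid, then polish the four parameters jointly
    best0 = None
    for p_try in np.linspace(0.92, 1.08, 9) * p0_period:
        arg = 2 * np.pi * x / p_try
        design = np.column_stack([np.ones_like(x), np.sin(arg), np.cos(arg)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        cost = float(np.sum((y - design @ coef) ** 2))
        if best0 is None or cost < best0[0]:
            best0 = (cost, p_try, coef)
    _, p_init, (off0, a_s, a_c) = best0
    amp0 = float(np.hypot(a_s, a_c))
    phase0 = float(np.arctan2(a_c, a_s))
    try:
        popt, _ = optimize.curve_fit(
            _sinus,
            x,
            y,
            p0=[off0, max(amp0, 1e-6), np.clip(p_init, 0.9 * p0_period, 1.1 * p0_period), phase0],
            bounds=(
                [-np.inf, 0.0, 0.9 * p0_period, -2 * np.pi],
                [np.inf, np.inf, 1.1 * p0_period, 4 * np.pi],
            ),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RowDetectionError("sinus fit did not converge") from exc
    offset, amp, period, phase = popt
    if amp <= 1e-8 * max(1.0, np.abs(y).max()):
        raise RowDetectionError("fitted amplitude is zero: no row pattern")
    # maxima: 2*pi*x/period + phase = pi/2 + 2*pi*k, kept within the
    # detected plot extent (slightly expanded for boundary rows)
    span_lo, span_hi = lo - period / 4.0, hi + period / 4.0
    k0 = np.ceil((span_lo - (np.pi / 2 - phase) / (2 * np.pi) * period) / period)
    centers = []
    k = k0
    while True:
        c = ((np.pi / 2 - phase) / (2 * np.pi) + k) * period
        if c >= span_hi or c >= width:
            break
        if c >= max(span_lo, 0):
            centers.append(c)
        k += 1
    if len(centers) < n_rows:
        raise RowDetectionError(
            f"only {len(centers)} row maxima inside the profile; need {n_rows}"
        )
    centers = np.asarray(centers)
    if len(centers) > n_rows:
        # keep the run of 9 consecutive maxima best supported by the profile
        support = [
            y_full[
                np.clip(np.round(centers[i : i + n_rows]).astype(int), 0, width - 1)
            ].sum()
            for i in range(len(centers) - n_rows + 1)
        ]
        i0 = int(np.argmax(support))
        centers = centers[i0 : i0 + n_rows]
    return RowLayout(
        rotation_deg=0.0,
        row_centers=centers,
        period_px=float(period),
        band_halfwidth_px=float(period) / 2.0,
    )


def extract_row_cc(mask: PlotMask, layout: RowLayout) -> np.ndarray:
    """Plant-pixel ratio per inner sowing row.

    Each row's band spans its centre +- the band halfwidth (period/2 by
    default, so the 9 bands tile the plot without overlap).
    """
    width = mask.shape[1]
    cc = []
    for i in layout.inner_rows:
        c = layout.row_centers[i]
        lo = int(round(c - layout.band_halfwidth_px))
        hi = int(round(c + layout.band_halfwidth_px))
        if hi <= 0 or lo >= width:
            raise GeometryError(
                f"row band [{lo}, {hi}) lies outside the mask of width {width}"
            )
        lo, hi = max(lo, 0), min(hi, width)
        cc.append(float(mask.pixels[:, lo:hi].mean()))
    return np.asarray(cc)


def render_synthetic_mask(
    n_rows: int = 9,
    period_px: int = 150,
    row_cover: Sequence[float] = (0.4,) * 9,
    rotation_deg: float = 0.0,
    noise_fraction: float = 0.0,
    seed: int = 0,
    height_px: int = 800,
) -> tuple[PlotMask, RowLayout]:
    """Render a synthetic 9-row plot mask with known geometry.

    Each row is a solid vertical strip of width ``cover * period`` centred
    on its row, so the cover within the row band equals ``cover`` exactly.
    ``rotation_deg`` is the skew applied to the rendered mask; the
    returned ground-truth layout carries the *correction* angle (its
    negative).  Salt-and-pepper noise resets ``noise_fraction`` of the
    pixels to a fair coin.
    """
    covers = np.asarray(row_cover, dtype=float)
    if covers.size != n_rows:
        raise ValueError(f"need {n_rows} row covers")
    if ((covers < 0) | (covers > 1)).any():
        raise ValueError("covers must lie in [0, 1]")
    margin = period_px // 2
    width = n_rows * period_px + 2 * margin
    px = np.zeros((height_px, width), dtype=np.uint8)
    centers = margin + (np.arange(n_rows) + 0.5) * period_px
    for c, cov in zip(centers, covers):
        hw = cov * period_px / 2.0
        px[:, int(round(c - hw)) : int(round(c + hw))] = 1
    mask = PlotMask(px)
    if rotation_deg != 0:
        mask = rotate_mask(mask, rotation_deg)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(mask.pixels.shape) < noise_fraction
        noise = rng.integers(0, 2, mask.pixels.shape, dtype=np.uint8)
        px = mask.pixels.copy()
        px[flip] = noise[flip]
        mask = PlotMask(px)
    truth = RowLayout(
        rotation_deg=-rotation_deg,
        row_centers=centers,
        period_px=float(period_px),
        band_halfwidth_px=period_px / 2.0,
    )
    return mask, truth


class SowingRowExtractor(BaseEstimator, TransformerMixin):
    """De-rotate a plot mask, fit the 9-row pattern, extract per-row CC.

    ``fit`` detects the rotation and row geometry of a mask; ``transform``
    returns the canopy cover of the 7 inner rows.  Each mask is processed
    independently (``fit_transform`` per image).

    Attributes
    ----------
    rotation_ : float, fitted de-rotation angle in degrees
    layout_ : :class:`RowLayout` with the fitted geometry
    """

    def __init__(
        self,
        angle_grid: Sequence[float] = DEFAULT_ANGLE_GRID,
        window: int = 100,
        n_rows: int = 9,
    ):
        self.angle_grid = angle_grid
        self.window = window
        self.n_rows = n_rows

    def fit(self, X: PlotMask, y=None):
        angle = optimal_rotation(X, self.angle_grid, self.window)
        rotated = rotate_mask(X, angle)
        layout = fit_row_sinus(column_profile(rotated), self.n_rows)
        self.rotation_ = angle
        self.layout_ = RowLayout(
            rotation_deg=angle,
            row_centers=layout.row_centers,
            period_px=layout.period_px,
            band_halfwidth_px=layout.band_halfwidth_px,
            inner_rows=layout.inner_rows,
        )
        return self

    def transform(self, X: PlotMask) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "layout_")
        return extract_row_cc(rotate_mask(X, self.rotation_), self.layout_)
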