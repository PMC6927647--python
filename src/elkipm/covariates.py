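"""Environmental index construction from per-pixel daily or composite series.

Builds the four covariate families the recruitment analysis uses:

* smoothed NDVI phenology (running mean + iterative upper-envelope correction,
  on the assumption that errant NDVI values are biased low),
* growing-season detection by the 50%-of-annual-maximum threshold, restricted
  to a March-October window,
* season-split time-integrated NDVI (cumulative sum of differences from the
  value at season start, split at the June 30 / July 1 boundary),
* windowed cumulative precipitation (May 1 - Jun 30 neonatal window and
  Jul 1 - Sep 30 juvenile-independence window) and cumulative winter
  snow-water-equivalent (Dec 1 - Apr 30, reported in m*days),

each computed per pixel then averaged over a district's seasonal range.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PixelSeries",
    "GrowingSeason",
    "smooth_series",
    "detect_growing_season",
    "time_integrated_ndvi",
    "windowed_cumulative",
    "cumulative_swe",
    "district_mean",
    "read_pixel_series",
    "read_pixel_district_map",
    "SEASON_WINDOW",
    "SPRING_SUMMER_SPLIT",
]

# March 1 .. Oct 31 in a non-leap year; the threshold method is evaluated
# only inside this window.
SEASON_WINDOW = (60, 304)
# June 30 / July 1 boundary (day-of-year of Jun 30, non-leap).
SPRING_SUMMER_SPLIT = 181


@dataclass
class PixelSeries:
    """Ordered (day, value) observations for one pixel and one span.

    ``days`` are strictly increasing integers (day-of-year for within-year
    series; any consecutive labelling for the winter SWE window).  NDVI
    series must stay within [-1, 1].
    """

    pixel: str
    days: np.ndarray
    values: np.ndarray
    kind: str = "ndvi"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape or self.days.ndim != 1:
            raise ValueError("days and values must be matching 1-d arrays")
        if len(self.days) and np.any(np.diff(self.days) <= 0):
            raise ValueError(f"pixel {self.pixel}: days must be strictly increasing")
        if self.kind == "ndvi" and len(self.values):
            if np.any(self.values < -1.0) or np.any(self.values > 1.0):
                raise ValueError(f"pixel {self.pixel}: NDVI outside [-1, 1]")


@dataclass(frozen=True)
class GrowingSeason:
    """Start/end day-of-year of the growing season and the annual maximum
    (both determined inside the March-October window)."""

    start_day: int
    end_day: int
    annual_max: float


def smooth_series(series: PixelSeries, window: int = 3) -> PixelSeries:
    """Centered running mean followed by iterative upper-envelope correction.

    The envelope step replaces any interior point lying below the straight
    line joining its neighbours with the interpolated (chord) value and
    iterates to convergence, so dips are lifted but values are never lowered.
    ``window = 1`` skips the running mean.
    """
    if window % 2 == 0:
        raise ValueError("running-mean window must be odd")
    n = len(series.values)
    if window > n:
        raise ValueError("running-mean window larger than the series")
    vals = series.values.astype(float).copy()
    if window > 1:
        half = window // 2
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half, n - 1)
        vals = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    vals = _upper_envelope(series.days, vals)
    return PixelSeries(series.pixel, series.days, vals, kind=series.kind)


def _upper_envelope(days: np.ndarray, values: np.ndarray,
                    tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    vals = values.copy()
    if len(vals) < 3:
        return vals
    d = days.astype(float)
    for _ in range(max_iter):
        left, mid, right = vals[:-2], vals[1:-1], vals[2:]
        w = (d[1:-1] - d[:-2]) / (d[2:] - d[:-2])
        chord = left + w * (right - left)
        # lift only genuine dips (below the chord AND both neighbours):
        # lifting every sub-chord point would converge to the concave
        # majorant and distort clean convex segments of the curve
        dip = (mid < chord) & (mid < left) & (mid < right)
        lifted = np.where(dip, chord, mid)
        change = np.max(np.abs(lifted - mid))
        vals[1:-1] = lifted
        if change < tol:
            break
    return vals


def detect_growing_season(series: PixelSeries,
                          window: tuple[int, int] = SEASON_WINDOW) -> GrowingSeason:
    """Threshold phenology: the season starts at the first observation (inside
    the window) reaching 50% of the annual maximum and ends when the series
    next falls back to 50%, clamped to the window edge if it never does."""
    lo, hi = window
    mask = (series.days >= lo) & (series.days <= hi)
    if not mask.any():
        raise ValueError("series does not cover the season window")
    days = series.days[mask]
    vals = series.values[mask]
    peak = float(vals.max())
    if peak <= 0:
        raise ValueError("no growing season: all values <= 0 in the window")
    thresh = 0.5 * peak
    above = vals >= thresh
    start_idx = int(np.argmax(above))
    start_day = int(days[start_idx])
    end_day = int(days[-1])
    after = np.nonzero((days > start_day) & (vals <= thresh))[0]
    if after.size:
        end_day = int(days[after[0]])
    return GrowingSeason(start_day=start_day, end_day=end_day, annual_max=peak)


def time_integrated_ndvi(
    series: PixelSeries,
    season: GrowingSeason,
    split_day: int = SPRING_SUMMER_SPLIT,
) -> tuple[float, float]:
    """Season-split time-integrated NDVI: the cumulative sum of differences
    between observed values and the value at season start, summed over
    [start, split] (spring) and (split, end] (summer).  A split outside the
    season simply zeroes one component."""
    days, vals = series.days, series.values
    in_season = (days >= season.start_day) & (days <= season.end_day)
    if not in_season.any():
        return 0.0, 0.0
    v0 = float(vals[in_season][0])
    spring = (days >= season.start_day) & (days <= min(split_day, season.end_day))
    summer = (days > max(split_day, season.start_day - 1)) & (days <= season.end_day)
    spring_ti = float(np.sum(vals[spring] - v0))
    summer_ti = float(np.sum(vals[summer & ~spring] - v0))
    return spring_ti, summer_ti


def windowed_cumulative(series: PixelSeries, start_day: int, end_day: int) -> float:
    """Sum of values with day in [start_day, end_day] inclusive (e.g. the
    May 1 - Jun 30 and Jul 1 - Sep 30 precipitation windows)."""
    if end_day < start_day:
        raise ValueError("empty window")
    mask = (series.days >= start_day) & (series.days <= end_day)
    if not mask.any():
        raise ValueError(
            f"window [{start_day}, {end_day}] has no observations in the series"
        )
    return float(np.sum(series.values[mask]))


def _winter_length(year: int | None) -> int | None:
    # Dec 1 (year-1) .. Apr 30 (year): 31 + 31 + {28,29} + 31 + 30 days.
    if year is None:
        return None
    feb = 29 if calendar.isleap(year) else 28
    return 31 + 31 + feb + 31 + 30


def cumulative_swe(series: PixelSeries, year: int | None = None) -> float:
    """Cumulative daily snow-water-equivalent over the winter window
    (Dec 1 of year-1 through Apr 30 of ``year``), in m*days.

    ``series.values`` are daily SWE in mm on consecutive days; any gap (or a
    wrong total length when ``year`` is given) is an error listing the missing
    days.
    """
    days = series.days
    if len(days) == 0:
        raise ValueError("empty SWE series")
    expected = np.arange(days[0], days[-1] + 1)
    missing = sorted(int(x) for x in set(expected.tolist()) - set(days.tolist()))
    if missing:
        raise ValueError(f"winter window not fully covered; missing days {missing[:10]}")
    n_expected = _winter_length(year)
    if n_expected is not None and len(days) != n_expected:
        raise ValueError(
            f"winter window for {year} needs {n_expected} daily values, got {len(days)}"
        )
    return float(np.sum(series.values)) / 1000.0


def district_mean(values) -> float:
    """Arithmetic mean of per-pixel results over a district's range."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("district mean of an empty pixel set")
    return float(arr.mean())


def read_pixel_district_map(path) -> dict[str, str]:
    """Read a (pixel, district) membership CSV mapping each pixel to the
    hunting-district range it belongs to."""
    df = pd.read_csv(path, dtype=str)
    if {"pixel", "district"} - set(df.columns):
        raise ValueError("pixel-district map needs columns pixel, district")
    return dict(zip(df["pixel"], df["district"]))


def read_pixel_series(path, kind: str = "ndvi") -> dict[str, PixelSeries]:
    """Read a long-format (pixel, day, value) CSV into per-pixel series."""
    df = pd.read_csv(path, dtype={"pixel": str})
    required = {"pixel", "day", "value"}
    if required - set(df.columns):
        raise ValueError("pixel series CSV needs columns pixel, day, value")
    out = {}
    for pixel, grp in df.groupby("pixel", sort=True):
        grp = grp.sort_values("day")
        out[pixel] = PixelSeries(
            pixel=str(pixel),
            days=grp["day"].to_numpy(dtype=int),
            values=grp["value"].to_numpy(dtype=float),
            kind=kind,
        )
    return out
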