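"""Heatwave indices from daily maximum temperature.

A heatwave is at least ``min_duration`` (default 3) consecutive days with
daily Tmax above the local calendar-day 90th-percentile threshold. The
threshold for calendar day ``d`` is the chosen percentile of all reference
values falling in a centred window (default 31 days, wrapping across the year
boundary) pooled over the reference years.

The annual Heat Wave Magnitude Index daily (HWMId) sums, over the days of the
year's strongest heatwave, the daily anomaly scaled by the interquartile range
of the reference-period annual maxima:

    Md(T) = (T - T25p) / (T75p - T25p)   if T > T25p, else 0
    HWMId = max over heatwaves of sum(Md over the event's days)

and is 0 in years without a heatwave. TX5x, the annual maximum of the 5-day
running mean of Tmax, serves as a simpler validation index.

All percentile computations use linear interpolation between order statistics
so that oracle tests can reproduce them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ThresholdClimatology:
    """Per-cell calendar-day exceedance thresholds (degC).

    ``thresholds`` has shape (365, ...) — one value per calendar day for each
    cell of the trailing grid dimensions.
    """

    thresholds: np.ndarray
    percentile: float
    window: int

    def __post_init__(self) -> None:
        if self.thresholds.shape[0] != DAYS_PER_YEAR:
            raise ValueError("thresholds must have a leading axis of 365 days")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class ReferenceQuartiles:
    """25th/75th percentiles of reference-period annual maximum Tmax."""

    t25: np.ndarray
    t75: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.t75 < self.t25):
            raise ValueError("t75 must be >= t25")

    @property
    def iqr(self) -> np.ndarray:
        return self.t75 - self.t25


@dataclass(frozen=True)
class HeatwaveEvent:
    """One heatwave: inclusive day-of-year span and its daily temperatures."""

    start: int
    end: int
    temperatures: np.ndarray

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def compute_thresholds(
    daily: np.ndarray, percentile: float = 90.0, window: int = 31
) -> ThresholdClimatology:
    """Calendar-day percentile thresholds from a reference ensemble.

    Parameters
    ----------
    daily
        Reference-period series, shape (years, 365, ...). At least 10 years.
    percentile
        Percentile level (default the heatwave-definition 90th).
    window
        Centred pooling window in days (odd; wraps across the year boundary).
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim < 2 or daily.shape[1] != DAYS_PER_YEAR:
        raise ValueError("daily must have shape (years, 365, ...)")
    if daily.shape[0] < 10:
        raise ValueError("reference period must contain at least 10 years")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of days")
    half = window // 2
    offsets = np.arange(-half, half + 1)
    out = np.empty((DAYS_PER_YEAR,) + daily.shape[2:])
    for d in range(DAYS_PER_YEAR):
        idx = (d + offsets) % DAYS_PER_YEAR
        pool = daily[:, idx].reshape((-1,) + daily.shape[2:])
        out[d] = np.percentile(pool, percentile, axis=0)
    return ThresholdClimatology(thresholds=out, percentile=percentile, window=window)


def reference_quartiles(daily: np.ndarray) -> ReferenceQuartiles:
    """IQR anchors of HWMId from reference annual maxima of daily Tmax."""
    daily = np.asarray(daily, dtype=float)
    annual_max = daily.max(axis=1)
    t25, t75 = np.percentile(annual_max, [25.0, 75.0], axis=0)
    return ReferenceQuartiles(t25=t25, t75=t75)


def detect_heatwaves(
    series: np.ndarray,
    thresholds: np.ndarray,
    min_duration: int = 3,
) -> list[HeatwaveEvent]:
    """Maximal runs of consecutive threshold exceedances, length >= min_duration."""
    series = np.asarray(series, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if series.shape != (DAYS_PER_YEAR,) or thresholds.shape != (DAYS_PER_YEAR,):
        raise ValueError("series and thresholds must both have shape (365,)")
    exceed = series > thresholds
    padded = np.concatenate(([False], exceed, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    events = []
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_duration:
            events.append(HeatwaveEvent(start=int(s), end=int(e), temperatures=series[s : e + 1].copy()))
    return events


def hwmid_annual(
    series: np.ndarray,
    thresholds: ThresholdClimatology | np.ndarray,
    quartiles: ReferenceQuartiles,
    min_duration: int = 3,
) -> float:
    """HWMId for one cell-year (0 when no heatwave occurs).

    Cells with a degenerate reference IQR (t75 == t25) get magnitude 0 for
    every day, hence HWMId 0.
    """
    thr = thresholds.thresholds if isinstance(thresholds, ThresholdClimatology) else thresholds
    events = detect_heatwaves(series, np.asarray(thr), min_duration=min_duration)
    t25 = float(np.asarray(quartiles.t25))
    iqr = float(np.asarray(quartiles.iqr))
    if not events:
        return 0.0
    if iqr <= 0:
        return 0.0
    best = 0.0
    for ev in events:
        md = np.clip((ev.temperatures - t25) / iqr, 0.0, None)
        best = max(best, float(md.sum()))
    return best


def hwmid_series(
    daily: np.ndarray,
    thresholds: ThresholdClimatology,
    quartiles: ReferenceQuartiles,
    min_duration: int = 3,
) -> np.ndarray:
    """Vectorised annual HWMId over a (years, 365, ...) ensemble.

    Implemented as a single flattened run-length pass: all (year, cell)
    day series are concatenated with separator gaps so event segmentation,
    magnitude summation and the per-year maximum are pure array operations.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim < 2 or daily.shape[1] != DAYS_PER_YEAR:
        raise ValueError("daily must have shape (years, 365, ...)")
    thr = thresholds.thresholds
    if thr.shape != daily.shape[1:]:
        raise ValueError(
            f"threshold shape {thr.shape} does not match daily series {daily.shape[1:]}"
        )
    years = daily.shape[0]
    grid_shape = daily.shape[2:]
    ncell = int(np.prod(grid_shape, dtype=int)) if grid_shape else 1

    # rows = (year, cell) series of length 365, padded with one non-exceeding day
    t = np.moveaxis(daily.reshape(years, DAYS_PER_YEAR, ncell), 1, 2)  # (years, ncell, 365)
    t = t.reshape(years * ncell, DAYS_PER_YEAR)
    thr_rows = np.broadcast_to(
        np.moveaxis(thr.reshape(DAYS_PER_YEAR, ncell), 0, 1)[None], (years, ncell, DAYS_PER_YEAR)
    ).reshape(years * ncell, DAYS_PER_YEAR)

    exceed = np.concatenate(
        [t > thr_rows, np.zeros((t.shape[0], 1), dtype=bool)], axis=1
    ).ravel()
    t25 = np.asarray(quartiles.t25).reshape(1, ncell, 1)
    iqr = np.asarray(quartiles.iqr).reshape(ncell)
    safe_iqr = np.where(iqr > 0, iqr, np.inf)  # degenerate cells -> magnitude 0
    md = np.clip((t.reshape(years, ncell, DAYS_PER_YEAR) - t25)
                 / np.broadcast_to(safe_iqr[None, :, None], (years, ncell, DAYS_PER_YEAR)),
                 0.0, None)
    md = np.concatenate([md.reshape(t.shape), np.zeros((t.shape[0], 1))], axis=1).ravel()

    edges = np.flatnonzero(np.diff(np.concatenate(([False], exceed)).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # runs are exceed[s:e]
    lengths = ends - starts
    keep = lengths >= min_duration
    starts, ends = starts[keep], ends[keep]
    csum = np.concatenate(([0.0], np.cumsum(md)))
    magnitudes = csum[ends] - csum[starts]
    rows = starts // (DAYS_PER_YEAR + 1)

    out = np.zeros(years * ncell)
    np.maximum.at(out, rows, magnitudes)
    return out.reshape((years,) + grid_shape)


def tx5x_annual(series: np.ndarray, window: int = 5) -> float:
    """Annual maximum of the ``window``-day running mean for one cell-year."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < window:
        raise ValueError(f"series must be 1-D with at least {window} days")
    means = np.convolve(series, np.ones(window) / window, mode="valid")
    return float(means.max())


def tx5x_series(daily: np.ndarray, window: int = 5) -> np.ndarray:
    """Vectorised annual TX5x over a (years, 365, ...) ensemble."""
    daily = np.asarray(daily, dtype=float)
    if daily.shape[1] < window:
        raise ValueError(f"need at least {window} days per year")
    sw = np.lib.stride_tricks.sliding_window_view(daily, window, axis=1)
    return sw.mean(axis=-1).max(axis=1)
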