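"""Phenology metrics of a migration season from smoothed daily CPUE.

For each species-year the daily CPUE series is smoothed with a centred
7-day moving average (MA).  The peak date of passage is the day with the
highest MA (earliest day on ties).  The main migration period is the
contiguous window around the peak delimited by the nearest days, on each
side, whose MA falls below 10% of the peak MA; its width is end − start
in days.  When the field season starts after migration onset (the MA on
the first season day is still at or above the threshold) the start is
undefined and flagged truncated — a fabricated date would bias trend
estimates; symmetrically for the end.  Species-years with fewer than 5
captures in total are excluded outright.

All thresholds are relative to the peak, so the metrics are invariant to
the CPUE scale constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DailyCpueSeries

__all__ = [
    "SmoothedSeries",
    "PhenologyMetrics",
    "moving_average",
    "find_peak",
    "find_window_bounds",
    "extract_phenology",
    "PhenologyExtractor",
]

#: study defaults: 7-day moving average, 10%-of-peak threshold, <5 captures excluded
DEFAULT_MA_WINDOW = 7
DEFAULT_THRESHOLD_FRAC = 0.1
DEFAULT_MIN_CAPTURES = 5


@dataclass
class SmoothedSeries:
    """Moving-average smoothed CPUE aligned with the season days."""

    species: str
    year: int
    days: np.ndarray
    ma: np.ndarray


@dataclass
class PhenologyMetrics:
    """Per species-year passage-timing metrics (Julian days, 1 = Jan 1)."""

    species: str
    year: int
    total_captures: int
    excluded: bool
    peak_day: int | None = None
    peak_ma: float | None = None
    start_day: int | None = None
    end_day: int | None = None
    window_days: int | None = None
    start_truncated: bool = False
    end_truncated: bool = False


def moving_average(series: DailyCpueSeries, window: int = DEFAULT_MA_WINDOW) -> SmoothedSeries:
    """Centred moving average over calendar days, skipping missing days.

    For each day ``d`` of the season span, ``MA(d)`` is the mean of the
    defined CPUE values on calendar days ``[d - w//2, d + w//2]`` clipped
    to the span.  Missing (closure) days are dropped from the mean, not
    zero-filled, and the window shrinks at the season edges so the MA is
    defined on the first and last season day.  ``MA(d)`` is NaN only when
    every day of the window is missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if len(series.days) == 0 or series.n_operated == 0:
        raise ValueError("series has no defined days")
    ma = (
        pd.Series(series.cpue)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return SmoothedSeries(series.species, series.year, series.days.copy(), ma)


def find_peak(smoothed: SmoothedSeries) -> tuple[int, float]:
    """Day with the highest MA; ties broken by the earliest day."""
    if len(smoothed.ma) == 0 or np.all(np.isnan(smoothed.ma)):
        raise ValueError("cannot locate a peak in an all-missing series")
    idx = int(np.nanargmax(smoothed.ma))  # nanargmax returns the first maximum
    return int(smoothed.days[idx]), float(smoothed.ma[idx])


def find_window_bounds(
    smoothed: SmoothedSeries,
    peak_day: int,
    peak_ma: float,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> tuple[int | None, int | None, bool, bool]:
    """Nearest sub-threshold days flanking the peak, or truncation flags.

    Scanning outward from the peak on each side, the bound is the first
    day whose MA is strictly below ``threshold_frac * peak_ma``.  Days
    with undefined MA are skipped (a closure day says nothing about
    passage intensity).  If the scan exhausts the season with the MA still
    at or above the threshold, that bound is undefined and the
    corresponding truncation flag is set.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    thr = threshold_frac * peak_ma
    days, ma = smoothed.days, smoothed.ma
    peak_idx = int(np.flatnonzero(days == peak_day)[0])

    start_day = end_day = None
    for i in range(peak_idx - 1, -1, -1):
        if not np.isnan(ma[i]) and ma[i] < thr:
            start_day = int(days[i])
            break
    for i in range(peak_idx + 1, len(days)):
        if not np.isnan(ma[i]) and ma[i] < thr:
            end_day = int(days[i])
            break
    return start_day, end_day, start_day is None, end_day is None


def extract_phenology(
    series: DailyCpueSeries,
    window: int = DEFAULT_MA_WINDOW,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_captures: int = DEFAULT_MIN_CAPTURES,
) -> PhenologyMetrics:
    """Smooth, find the peak and the threshold window for one species-year.

    Species-years with ``total_captures < min_captures`` are excluded and
    report no metrics.  ``window_days`` is computed only when both bounds
    are defined.
    """
    if series.total_captures < 0:
        raise ValueError(
            "total_captures is unknown for this series; the exclusion rule "
            "needs raw counts (use a CPUE table that carries a 'count' column)"
        )
    if series.total_captures < min_captures:
        return PhenologyMetrics(
            species=series.species,
            year=series.year,
            total_captures=series.total_captures,
            excluded=True,
        )
    smoothed = moving_average(series, window=window)
    peak_day, peak_ma = find_peak(smoothed)
    start, end, start_tr, end_tr = find_window_bounds(
        smoothed, peak_day, peak_ma, threshold_frac=threshold_frac
    )
    return PhenologyMetrics(
        species=series.species,
        year=series.year,
        total_captures=series.total_captures,
        excluded=False,
        peak_day=peak_day,
        peak_ma=peak_ma,
        start_day=start,
        end_day=end,
        window_days=(end - start) if (start is not None and end is not None) else None,
        start_truncated=start_tr,
        end_truncated=end_tr,
    )


def metrics_to_frame(metrics: list[PhenologyMetrics]) -> pd.DataFrame:
    """Tidy per-species-year metrics table (one row each)."""
    return pd.DataFrame(
        {
            "species": [m.species for m in metrics],
            "year": [m.year for m in metrics],
            "total_captures": [m.total_captures for m in metrics],
            "excluded": [m.excluded for m in metrics],
            "peak_day": [m.peak_day for m in metrics],
            "start_day": [m.start_day for m in metrics],
            "end_day": [m.end_day for m in metrics],
            "window_days": [m.window_days for m in metrics],
            "start_truncated": [m.start_truncated for m in metrics],
            "end_truncated": [m.end_truncated for m in metrics],
        }
    )


class PhenologyExtractor(TransformerMixin, BaseEstimator):
    """Transformer from a tidy daily-CPUE table to per-species-year metrics.

    Parameters
    ----------
    ma_window : int, default 7
        Width (days) of the centred moving average; must be odd.
    threshold_frac : float, default 0.1
        Window bounds are the nearest days with MA below this fraction of
        the peak MA.
    min_captures : int, default 5
        Species-years with fewer raw captures are excluded.

    The transformer is stateless; ``fit`` only validates parameters.
    ``transform`` expects the output of :func:`phenopass.io.daily_cpue_table`
    (columns species, year, julian_day, cpue, count) and returns the tidy
    metrics table.
    """

    def __init__(
        self,
        ma_window: int = DEFAULT_MA_WINDOW,
        threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
        min_captures: int = DEFAULT_MIN_CAPTURES,
    ):
        self.ma_window = ma_window
        self.threshold_frac = threshold_frac
        self.min_captures = min_captures

    def fit(self, X: pd.DataFrame, y=None):
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be odd and >= 1")
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must lie in (0, 1)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        required = {"species", "year", "julian_day", "cpue"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"daily CPUE table lacks column(s) {sorted(missing)}")
        out = []
        for (sp, yr), sub in X.groupby(["species", "year"], sort=True):
            sub = sub.sort_values("julian_day")
            total = int(sub["count"].sum()) if "count" in sub.columns else -1
            series = DailyCpueSeries(
                species=sp,
                year=int(yr),
                days=sub["julian_day"].to_numpy(),
                cpue=sub["cpue"].to_numpy(dtype=float),
                total_captures=total,
            )
            out.append(
                extract_phenology(
                    series,
                    window=self.ma_window,
                    threshold_frac=self.threshold_frac,
                    min_captures=self.min_captures,
                )
            )
        return metrics_to_frame(out)
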