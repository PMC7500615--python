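"""Per-species linear trends of annual passage-timing metrics.

Each metric (start, peak, end of the main migration period, and window
width) is regressed on calendar year by ordinary least squares, species by
species.  The slope is the average yearly change in days per year:
negative = advancing passage, positive = delay (for the window, positive =
broadening).  The p-value is the two-sided t-test on the slope.  A species
needs at least three usable years for an estimate; with fewer the trend is
flagged undefined rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["TrendEstimate", "fit_annual_trend", "fit_species_trends",
           "SpeciesTrendEstimator", "METRIC_COLUMNS"]

#: metric name -> column of the tidy phenology table
METRIC_COLUMNS = {
    "start": "start_day",
    "peak": "peak_day",
    "end": "end_day",
    "window": "window_days",
}

DEFAULT_MIN_YEARS = 3


@dataclass
class TrendEstimate:
    """OLS trend of one metric for one species across years."""

    species: str
    metric: str
    slope: float | None
    se: float | None
    p_value: float | None
    n_years: int
    defined: bool


def fit_annual_trend(
    years: np.ndarray,
    values: np.ndarray,
    species: str = "",
    metric: str = "",
    min_years: int = DEFAULT_MIN_YEARS,
) -> TrendEstimate:
    """OLS of annual metric values on calendar year.

    NaN values are dropped first.  With fewer than ``min_years`` usable
    years no estimate is produced (``defined=False``).  Degenerate exact
    fits are handled explicitly: zero residual variance gives p = 1 for a
    zero slope and p = 0 otherwise.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values) & ~np.isnan(years)
    years, values = years[ok], values[ok]
    n = len(years)
    if n < min_years:
        return TrendEstimate(species, metric, None, None, None, n, False)
    if np.ptp(years) == 0:
        raise ValueError("years have zero variance; cannot fit a trend")
    res = stats.linregress(years, values)
    slope, se, p = float(res.slope), float(res.stderr), float(res.pvalue)
    if not np.isfinite(se) or se == 0.0:
        # exact linear fit: the t statistic degenerates
        se = 0.0
        p = 1.0 if slope == 0.0 else 0.0
    return TrendEstimate(species, metric, slope, se, p, n, True)


def fit_species_trends(
    metrics: pd.DataFrame,
    metric_names: tuple[str, ...] = ("start", "peak", "end", "window"),
    min_years: int = DEFAULT_MIN_YEARS,
) -> pd.DataFrame:
    """Tidy trend table over all species and requested metrics.

    ``metrics`` is the per-species-year phenology table; excluded
    species-years and undefined metric values are dropped per metric
    before fitting.  Returns columns species, metric, slope, se, p_value,
    n_years, defined.
    """
    usable = metrics.loc[~metrics["excluded"]]
    rows = []
    for sp, sub in usable.groupby("species", sort=True):
        for name in metric_names:
            col = METRIC_COLUMNS[name]
            vals = pd.to_numeric(sub[col], errors="coerce").to_numpy(dtype=float)
            est = fit_annual_trend(
                sub["year"].to_numpy(), vals, species=sp, metric=name,
                min_years=min_years,
            )
            rows.append(est)
    return pd.DataFrame([vars(e) for e in rows])


class SpeciesTrendEstimator(BaseEstimator):
    """Per-species OLS trends of annual phenology metrics.

    Parameters
    ----------
    metric_names : tuple of str
        Which metrics to fit, out of start/peak/end/window.
    min_years : int, default 3
        Minimum usable years for a defined trend.

    Attributes
    ----------
    trends_ : DataFrame
        Tidy trend table (species, metric, slope, se, p_value, n_years,
        defined).
    """

    def __init__(
        self,
        metric_names: tuple[str, ...] = ("start", "peak", "end", "window"),
        min_years: int = DEFAULT_MIN_YEARS,
    ):
        self.metric_names = metric_names
        self.min_years = min_years

    def fit(self, X: pd.DataFrame, y=None):
        self.trends_ = fit_species_trends(
            X, metric_names=tuple(self.metric_names), min_years=self.min_years
        )
        return self

    def summary_table(self, species_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """Wide per-species table: one row per species, slope/se/p per metric.

        Undefined cells (too few years, or a metric never observed because
        of truncation) are NA.  With ``species_meta`` the wintering group
        is joined in and rows are ordered by group then species.
        """
        if not hasattr(self, "trends_"):
            raise AttributeError("estimator is not fitted")
        t = self.trends_.copy()
        for col in ("slope", "se", "p_value"):
            t.loc[~t["defined"], col] = np.nan
        wide = t.pivot(index="species", columns="metric",
                       values=["slope", "se", "p_value"])
        wide.columns = [f"{m}_{v}" for v, m in wide.columns]
        order = [f"{m}_{v}" for m in self.metric_names for v in ("slope", "se", "p_value")]
        wide = wide[[c for c in order if c in wide.columns]].reset_index()
        if species_meta is not None:
            wide = wide.merge(
                species_meta[["species", "wintering_group"]], on="species", how="left"
            )
            cols = ["species", "wintering_group"] + [c for c in wide.columns
                                                     if c not in ("species", "wintering_group")]
            wide = wide[cols].sort_values(["wintering_group", "species"]).reset_index(drop=True)
        return wide
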