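"""Reading, validation and effort standardization of ringing-station tables.

A constant-effort ringing station produces two daily tables: captures (one
row per ringed bird or per species count) and effort (metres of mist-net
deployed and hours the nets were open).  Daily capture counts are
standardized to catch per unit of effort (CPUE), here captures per
``scale`` net-metre-hours, which is the unit of daily migration intensity
used by all downstream phenology metrics.  The CPUE scale constant cancels
out of every downstream quantity (peaks and thresholds are ratios within a
series), so only the ratio structure matters.

Non-operated days (rain or wind closures) are represented as *missing*,
never as zero: a zero would drag the moving average down and bias peak and
window estimates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaConfig",
    "SchemaError",
    "RowValidationError",
    "DailyCpueSeries",
    "read_captures",
    "read_effort",
    "read_species_metadata",
    "load_species_metadata",
    "compute_daily_cpue",
    "daily_cpue_table",
    "series_from_table",
    "WINTERING_GROUPS",
    "SEX_LEVELS",
]

WINTERING_GROUPS = ("North Africa", "Sahel", "Tropical")
SEX_LEVELS = ("male", "female", "unknown")

_SEX_ALIASES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
    "u": "unknown", "unknown": "unknown", "": "unknown",
}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class RowValidationError(ValueError):
    """One or more rows failed validation; ``rows`` holds (line, message)."""

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in rows[:10])
        more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
        super().__init__(f"{len(rows)} invalid row(s): {lines}{more}")


@dataclass
class SchemaConfig:
    """Column-name mapping and validation settings for delimited inputs.

    ``delimiter=None`` auto-detects comma vs tab from the header line.
    ``study_period`` is an inclusive (start, end) date pair; rows outside
    it are rejected with their line numbers.
    """

    date: str = "date"
    species: str = "species"
    sex: str = "sex"
    age: str = "age"
    count: str = "count"
    net_length: str = "net_length_m"
    hours_open: str = "hours_open"
    delimiter: str | None = None
    study_period: tuple[dt.date, dt.date] | None = None


def _read_delimited(path, delimiter):
    path = Path(path)
    if delimiter is None:
        header = path.open().readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _parse_dates(raw: pd.Series, errors: list[tuple[int, str]]) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    for idx in np.flatnonzero(parsed.isna().to_numpy()):
        # +2: header line plus 1-based numbering
        errors.append((int(idx) + 2, f"unparseable date {raw.iloc[idx]!r}"))
    return parsed


def read_captures(path, schema: SchemaConfig | None = None) -> pd.DataFrame:
    """Read and validate a captures table.

    Returns a DataFrame with columns ``date`` (datetime), ``species``,
    ``sex`` (male/female/unknown), ``age`` (string, may be empty) and
    ``count`` (positive int, defaulting to 1 per row when the column is
    absent).  Raises :class:`SchemaError` for a missing required column and
    :class:`RowValidationError` listing offending line numbers for bad
    dates, bad counts, empty species, or dates outside the study period.
    """
    schema = schema or SchemaConfig()
    df = _read_delimited(path, schema.delimiter)
    for col in (schema.date, schema.species):
        if col not in df.columns:
            raise SchemaError(f"captures file {path} is missing required column {col!r}")

    errors: list[tuple[int, str]] = []
    dates = _parse_dates(df[schema.date], errors)

    species = df[schema.species].str.strip()
    for idx in np.flatnonzero((species == "").to_numpy()):
        errors.append((int(idx) + 2, "empty species"))

    if schema.sex in df.columns:
        sex = df[schema.sex].str.strip().str.lower().map(_SEX_ALIASES).fillna("unknown")
    else:
        sex = pd.Series("unknown", index=df.index)
    age = df[schema.age].str.strip() if schema.age in df.columns else pd.Series("", index=df.index)

    if schema.count in df.columns:
        counts = pd.to_numeric(df[schema.count], errors="coerce")
        bad = counts.isna() | (counts < 0) | (counts != counts.round())
        for idx in np.flatnonzero(bad.to_numpy()):
            errors.append((int(idx) + 2, f"invalid count {df[schema.count].iloc[idx]!r}"))
        counts = counts.where(~bad, 0).astype(int)
    else:
        counts = pd.Series(1, index=df.index)

    if schema.study_period is not None:
        lo, hi = (pd.Timestamp(d) for d in schema.study_period)
        outside = dates.notna() & ((dates < lo) | (dates > hi))
        for idx in np.flatnonzero(outside.to_numpy()):
            errors.append((int(idx) + 2, f"date {dates.iloc[idx].date()} outside study period"))

    if errors:
        raise RowValidationError(sorted(errors))

    return pd.DataFrame(
        {"date": dates, "species": species, "sex": sex, "age": age, "count": counts}
    )


def read_effort(path, schema: SchemaConfig | None = None) -> pd.DataFrame:
    """Read and validate a daily effort table.

    One row per operated day: ``date``, ``net_length`` (m, > 0) and
    ``hours_open`` (h, > 0).  Non-operated days must be absent, not zero.
    Duplicate dates and non-positive effort are validation errors.
    """
    schema = schema or SchemaConfig()
    df = _read_delimited(path, schema.delimiter)
    for col in (schema.date, schema.net_length, schema.hours_open):
        if col not in df.columns:
            raise SchemaError(f"effort file {path} is missing required column {col!r}")

    errors: list[tuple[int, str]] = []
    dates = _parse_dates(df[schema.date], errors)
    net = pd.to_numeric(df[schema.net_length], errors="coerce")
    hours = pd.to_numeric(df[schema.hours_open], errors="coerce")
    for name, vals in (("net_length", net), ("hours_open", hours)):
        bad = vals.isna() | (vals <= 0)
        for idx in np.flatnonzero(bad.to_numpy()):
            errors.append((int(idx) + 2, f"non-positive or invalid {name}"))
    dup = dates.duplicated(keep=False) & dates.notna()
    for idx in np.flatnonzero(dup.to_numpy()):
        errors.append((int(idx) + 2, f"duplicate effort record for {dates.iloc[idx].date()}"))
    if errors:
        raise RowValidationError(sorted(set(errors)))

    return pd.DataFrame({"date": dates, "net_length": net, "hours_open": hours})


def read_species_metadata(path) -> pd.DataFrame:
    """Read a species metadata table (species, wintering_group, dimorphic)."""
    df = pd.read_csv(path)
    if "species" not in df.columns or "wintering_group" not in df.columns:
        raise SchemaError("species metadata needs 'species' and 'wintering_group' columns")
    unknown = set(df["wintering_group"]) - set(WINTERING_GROUPS)
    if unknown:
        raise RowValidationError(
            [(0, f"unknown wintering group(s) {sorted(unknown)}; "
                 f"expected one of {WINTERING_GROUPS}")]
        )
    if "dimorphic" in df.columns:
        df["dimorphic"] = df["dimorphic"].astype(bool)
    else:
        df["dimorphic"] = False
    return df


def load_species_metadata() -> pd.DataFrame:
    """Packaged metadata for the 30 most abundant spring migrants at a
    Tyrrhenian-island stopover station: wintering group (North Africa /
    Sahel / Tropical), whether the sexes are separable in the hand, and
    typical passage statistics used as simulation defaults."""
    with resources.as_file(
        resources.files("phenopass").joinpath("data/species_metadata.csv")
    ) as p:
        return read_species_metadata(p)


@dataclass
class DailyCpueSeries:
    """Daily CPUE of one species in one year over the operated season span.

    ``days`` covers every Julian day (1 = Jan 1) from the first to the last
    operated day; ``cpue`` is NaN on non-operated days inside the span and
    ``>= 0`` elsewhere.
    """

    species: str
    year: int
    days: np.ndarray
    cpue: np.ndarray
    total_captures: int

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.cpue = np.asarray(self.cpue, dtype=float)
        if len(self.days) != len(self.cpue):
            raise ValueError("days and cpue must be aligned")
        if len(self.days) and np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        defined = self.cpue[~np.isnan(self.cpue)]
        if np.any(defined < 0):
            raise ValueError("cpue must be non-negative where defined")

    @property
    def n_operated(self) -> int:
        return int(np.sum(~np.isnan(self.cpue)))


def _julian(dates: pd.Series) -> pd.Series:
    return dates.dt.dayofyear


def compute_daily_cpue(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    species: str,
    year: int,
    scale: float = 100.0,
) -> DailyCpueSeries:
    """Standardize one species-year of daily counts by effort.

    ``cpue[d] = scale * counts[d] / (net_length[d] * hours_open[d])`` on
    operated days; operated days with no captures get 0; days inside the
    season span with no effort record are NaN (missing).  A capture dated
    on a day without an effort record is a data inconsistency and raises.
    """
    eff = effort.loc[effort["date"].dt.year == year]
    if eff.empty:
        raise ValueError(f"no effort records in year {year}")
    if (eff["net_length"] <= 0).any() or (eff["hours_open"] <= 0).any():
        raise ValueError("effort must be strictly positive on operated days")

    eff_days = _julian(eff["date"]).to_numpy()
    order = np.argsort(eff_days)
    eff_days = eff_days[order]
    denom = (eff["net_length"].to_numpy() * eff["hours_open"].to_numpy())[order]

    cap = captures.loc[
        (captures["species"] == species) & (captures["date"].dt.year == year)
    ]
    cap_days = _julian(cap["date"]).to_numpy()
    missing_effort = np.setdiff1d(cap_days, eff_days)
    if missing_effort.size:
        raise ValueError(
            f"captures of {species} in {year} on day(s) {missing_effort.tolist()} "
            "have no effort record"
        )

    counts = (
        cap.groupby(cap_days)["count"].sum() if len(cap) else pd.Series(dtype=int)
    )
    span = np.arange(eff_days[0], eff_days[-1] + 1)
    cpue = np.full(span.shape, np.nan)
    pos = eff_days - eff_days[0]
    day_counts = counts.reindex(eff_days, fill_value=0).to_numpy(dtype=float)
    cpue[pos] = scale * day_counts / denom
    return DailyCpueSeries(
        species=species,
        year=year,
        days=span,
        cpue=cpue,
        total_captures=int(cap["count"].sum()),
    )


def daily_cpue_table(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    species: list[str] | None = None,
    scale: float = 100.0,
) -> pd.DataFrame:
    """Tidy per-species-year daily CPUE over all years with effort.

    Columns: species, year, julian_day, cpue, missing_flag, count.  Every
    species in ``species`` (default: all captured species) gets a row for
    every day of each year's operated span, including zero-capture and
    missing days; ``count`` carries the raw daily total so the <5-captures
    exclusion rule can be applied downstream.
    """
    if species is None:
        species = sorted(captures["species"].unique())
    years = sorted(effort["date"].dt.year.unique())
    cap_days = _julian(captures["date"])
    cap_years = captures["date"].dt.year
    frames = []
    for sp in species:
        mask = captures["species"] == sp
        for yr in years:
            s = compute_daily_cpue(captures, effort, sp, yr, scale=scale)
            day_counts = (
                captures.loc[mask & (cap_years == yr)]
                .groupby(cap_days[mask & (cap_years == yr)])["count"]
                .sum()
                .reindex(s.days, fill_value=0)
                .to_numpy()
            )
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "year": yr,
                        "julian_day": s.days,
                        "cpue": s.cpue,
                        "missing_flag": np.isnan(s.cpue),
                        "count": day_counts,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def series_from_table(table: pd.DataFrame, species: str, year: int) -> DailyCpueSeries:
    """Rebuild a :class:`DailyCpueSeries` from one species-year of the tidy table."""
    sub = table.loc[(table["species"] == species) & (table["year"] == year)]
    if sub.empty:
        raise KeyError(f"no rows for {species} in {year}")
    sub = sub.sort_values("julian_day")
    total = int(sub["count"].sum()) if "count" in sub.columns else -1
    return DailyCpueSeries(
        species=species,
        year=year,
        days=sub["julian_day"].to_numpy(),
        cpue=sub["cpue"].to_numpy(dtype=float),
        total_captures=total,
    )
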