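"""Reading, validation and alignment of phenology and climate tables.

All tabular inputs are delimited text.  Phenology files carry one row
per park x year x event kind with the observed date (day-of-year
integer or ISO date); climate files carry per-station daily mean air
temperature (°C) and snow depth (cm); coordinate files map identifiers
to decimal-degree latitude/longitude.

The whole package works on a 365-day year: Feb 29 is folded onto
Feb 28 (both map to day 59) and later dates of a leap year are shifted
back one day, so day-of-year always runs 1..365.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_YEAR

__all__ = [
    "SchemaError",
    "ValidationReport",
    "LagWindowSet",
    "read_phenology",
    "write_phenology",
    "read_climate",
    "write_climate",
    "read_coordinates",
    "haversine_km",
    "assign_nearest_station",
    "fill_gaps",
    "align_event_windows",
]

EVENT_KINDS = ("last_entry", "first_exit")
# plausible day-of-year intervals per event kind; violations are flagged
EVENT_INTERVALS = {"last_entry": (211, 365), "first_exit": (1, 150)}

EARTH_RADIUS_KM = 6371.0


class SchemaError(ValueError):
    """Input file violates the expected schema."""


@dataclass
class ValidationReport:
    flagged_out_of_interval: list = field(default_factory=list)
    long_gaps: list = field(default_factory=list)
    excluded_windows: list = field(default_factory=list)

    def __str__(self) -> str:
        return (
            f"ValidationReport(out_of_interval={len(self.flagged_out_of_interval)}, "
            f"long_gaps={len(self.long_gaps)}, excluded_windows={len(self.excluded_windows)})"
        )


def day_of_year_365(date: _dt.date) -> int:
    """Day-of-year on the 365-day calendar (Feb 29 folds onto Feb 28)."""
    doy = date.timetuple().tm_yday
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    if leap and doy >= 60:  # Mar 1 of a leap year is raw doy 61 -> 60
        doy -= 1
    return doy


def _parse_event_day(value, year: int, line: int) -> int:
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        date = _dt.date.fromisoformat(s)
    except ValueError as exc:
        raise SchemaError(f"line {line}: unparseable event_date {value!r}") from exc
    if date.year != int(year):
        raise SchemaError(f"line {line}: event_date {s} disagrees with year {year}")
    return day_of_year_365(date)


def read_phenology(path, delimiter: str = ",") -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a phenology table.

    Returns ``(records, report)``: records with columns ``park_id, year,
    event_kind, day_of_year, outside_interval`` and a report listing
    flagged rows.  Duplicate (park, year, kind) rows and unparseable
    dates raise :class:`SchemaError` with line numbers.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    required = {"park_id", "year", "event_kind"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"phenology file missing required columns: {sorted(missing)}")
    date_col = "event_date" if "event_date" in df.columns else "day_of_year"
    if date_col not in df.columns:
        raise SchemaError("phenology file needs an event_date or day_of_year column")

    df = df.copy()
    df["_line"] = df.index + 2  # header is line 1
    bad_kind = df[~df["event_kind"].isin(EVENT_KINDS)]
    if not bad_kind.empty:
        raise SchemaError(
            f"unknown event_kind values {sorted(bad_kind['event_kind'].unique())} "
            f"at lines {bad_kind['_line'].tolist()}"
        )
    try:
        df["year"] = df["year"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"non-integer year values: {exc}") from exc

    dup = df.duplicated(["park_id", "year", "event_kind"], keep=False)
    if dup.any():
        lines = df.loc[dup, "_line"].tolist()
        raise SchemaError(f"duplicate (park_id, year, event_kind) rows at lines {lines}")

    df["day_of_year"] = [
        _parse_event_day(v, y, ln)
        for v, y, ln in zip(df[date_col], df["year"], df["_line"])
    ]
    bad_day = ~df["day_of_year"].between(1, DAYS_PER_YEAR)
    if bad_day.any():
        raise SchemaError(
            f"day_of_year outside 1..{DAYS_PER_YEAR} at lines {df.loc[bad_day, '_line'].tolist()}"
        )

    report = ValidationReport()
    lo_hi = df["event_kind"].map(EVENT_INTERVALS)
    df["outside_interval"] = [
        not (lo <= d <= hi) for d, (lo, hi) in zip(df["day_of_year"], lo_hi)
    ]
    for _, row in df[df["outside_interval"]].iterrows():
        report.flagged_out_of_interval.append(
            (row["park_id"], int(row["year"]), row["event_kind"],
             int(row["day_of_year"]), int(row["_line"]))
        )
    out = df[["park_id", "year", "event_kind", "day_of_year", "outside_interval"]]
    return out.reset_index(drop=True), report


def write_phenology(records: pd.DataFrame, path, delimiter: str = ",") -> None:
    cols = ["park_id", "year", "event_kind", "day_of_year"]
    records[cols].to_csv(path, sep=delimiter, index=False)


def read_climate(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a station climate table (station_id, date, temperature_c, snow_cm).

    ISO dates are folded onto the 365-day calendar; rows for Feb 29 are
    dropped.  Missing values stay as NaN.  Returns columns
    ``station_id, year, doy, temperature_c, snow_cm``.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    required = {"station_id", "date", "temperature_c", "snow_cm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"climate file missing required columns: {sorted(missing)}")
    dates = pd.to_datetime(df["date"], format="ISO8601")
    feb29 = (dates.dt.month == 2) & (dates.dt.day == 29)
    df = df[~feb29].copy()
    dates = dates[~feb29]
    df["year"] = dates.dt.year.to_numpy()
    df["doy"] = [day_of_year_365(d.date()) for d in dates]
    df["temperature_c"] = pd.to_numeric(df["temperature_c"], errors="coerce")
    df["snow_cm"] = pd.to_numeric(df["snow_cm"], errors="coerce")
    neg = df["snow_cm"] < 0
    if neg.any():
        raise SchemaError(f"negative snow depths in {int(neg.sum())} rows")
    return df[["station_id", "year", "doy", "temperature_c", "snow_cm"]].reset_index(drop=True)


def write_climate(climate: pd.DataFrame, path, delimiter: str = ",",
                  id_col: str = "park_id") -> None:
    """Write a daily series back to the station CSV dialect.

    Day-of-year is expanded to an ISO date on the 365-day calendar
    (days >= 60 of leap years shift forward past Feb 29).
    """
    df = climate.copy()

    def iso(year: int, doy: int) -> str:
        leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
        shift = 1 if (leap and doy >= 60) else 0
        return (_dt.date(int(year), 1, 1) + _dt.timedelta(days=int(doy) - 1 + shift)).isoformat()

    df["date"] = [iso(y, d) for y, d in zip(df["year"], df["doy"])]
    df["station_id"] = df[id_col]
    df[["station_id", "date", "temperature_c", "snow_cm"]].to_csv(
        path, sep=delimiter, index=False
    )


def read_coordinates(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, delimiter=delimiter)
    missing = {"id", "lat", "lon"} - set(df.columns)
    if missing:
        raise SchemaError(f"coordinates file missing required columns: {sorted(missing)}")
    return df[["id", "lat", "lon"]].copy()


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def assign_nearest_station(park_coords: pd.DataFrame,
                           station_coords: pd.DataFrame) -> pd.DataFrame:
    """Map each park to its nearest station by great-circle distance.

    Ties are broken by lexicographic station id.  Returns columns
    ``park_id, station_id, distance_km``.
    """
    if len(station_coords) == 0:
        raise ValueError("no stations provided for nearest-neighbor assignment")
    stations = station_coords.sort_values("id", kind="stable").reset_index(drop=True)
    rows = []
    for _, park in park_coords.iterrows():
        d = haversine_km(park["lat"], park["lon"], stations["lat"], stations["lon"])
        j = int(np.argmin(d))  # first minimum = lexicographically smallest id
        rows.append({"park_id": park["id"], "station_id": stations.loc[j, "id"],
                     "distance_km": float(d[j])})
    return pd.DataFrame(rows)


def fill_gaps(series: pd.DataFrame, max_gap_days: int = 3,
              id_col: str = "station_id") -> tuple[pd.DataFrame, ValidationReport]:
    """Fill short gaps in a daily series; report longer ones.

    Temperature gaps of at most ``max_gap_days`` are linearly
    interpolated; snow gaps are forward-filled (keeping non-negativity).
    Longer gaps are left missing and listed in the report.
    """
    report = ValidationReport()
    out = []
    for sid, g in series.groupby(id_col, sort=False):
        g = g.sort_values(["year", "doy"], kind="stable").reset_index(drop=True)
        for col, method in (("temperature_c", "linear"), ("snow_cm", "ffill")):
            x = g[col]
            isna = x.isna().to_numpy()
            if not isna.any():
                continue
            grp = (~isna).cumsum()
            runs = pd.Series(np.arange(len(x))[isna]).groupby(grp[isna])
            fillable = np.zeros(len(x), dtype=bool)
            for _, idx in runs:
                run = idx.to_numpy()
                if len(run) <= max_gap_days and run[0] > 0 and (
                    method == "ffill" or run[-1] < len(x) - 1
                ):
                    fillable[run] = True
                else:
                    report.long_gaps.append(
                        (sid, col, int(g.loc[run[0], "year"]), int(g.loc[run[0], "doy"]),
                         len(run))
                    )
            if method == "linear":
                filled = x.interpolate(method="linear", limit_area="inside")
            else:
                filled = x.ffill()
            g[col] = np.where(fillable, filled, x)
        out.append(g)
    return pd.concat(out, ignore_index=True), report


@dataclass
class LagWindowSet:
    """Event-aligned climate matrices over lags -30..+30 days.

    ``values`` is (n_windows, n_lags) with NaN at masked entries;
    ``mask`` is True where a value is available; lag 0 aligns with the
    recorded event day.
    """

    event_kind: str
    variable: str
    lags: np.ndarray               # e.g. -30..30
    park_ids: np.ndarray           # (n_windows,)
    years: np.ndarray              # (n_windows,)
    values: np.ndarray             # (n_windows, n_lags), NaN where masked
    mask: np.ndarray               # (n_windows, n_lags) bool, True = observed

    @property
    def parks(self) -> list:
        return sorted(pd.unique(self.park_ids).tolist())

    def complete(self) -> bool:
        return bool(self.mask.all())


def align_event_windows(
    events: pd.DataFrame,
    climate: pd.DataFrame,
    variable: str = "temperature_c",
    lag_range: tuple[int, int] = (-30, 30),
    max_missing_frac: float = 0.20,
    id_col: str = "park_id",
) -> tuple[LagWindowSet, ValidationReport]:
    """Build one lag window per event record.

    Windows are built on the 365-day calendar axis, so a late-autumn
    window may spill into January of the following year.  Park-years
    with more than ``max_missing_frac`` of their lags unavailable are
    excluded and reported.
    """
    lo, hi = lag_range
    if lo > hi:
        raise ValueError(f"invalid lag range {lag_range}")
    lags = np.arange(lo, hi + 1)
    kinds = events["event_kind"].unique()
    if len(kinds) != 1:
        raise ValueError(f"align_event_windows expects a single event kind, got {kinds}")
    report = ValidationReport()

    # absolute day index per park for O(1) lag lookups across year ends
    lookup: dict[str, dict[int, float]] = {}
    for pid, g in climate.groupby(id_col, sort=False):
        absday = (g["year"].to_numpy() * DAYS_PER_YEAR + g["doy"].to_numpy() - 1)
        lookup[pid] = dict(zip(absday.tolist(), g[variable].to_numpy().tolist()))

    keep_rows, vals = [], []
    for _, ev in events.iterrows():
        pid = ev["park_id"]
        table = lookup.get(pid, {})
        center = int(ev["year"]) * DAYS_PER_YEAR + int(ev["day_of_year"]) - 1
        w = np.array([table.get(center + int(k), np.nan) for k in lags])
        n_missing = int(np.isnan(w).sum())
        if n_missing > max_missing_frac * len(lags):
            report.excluded_windows.append(
                (pid, int(ev["year"]), n_missing, len(lags))
            )
            continue
        keep_rows.append((pid, int(ev["year"])))
        vals.append(w)

    values = np.array(vals) if vals else np.empty((0, len(lags)))
    windows = LagWindowSet(
        event_kind=str(kinds[0]),
        variable=variable,
        lags=lags,
        park_ids=np.array([r[0] for r in keep_rows]),
        years=np.array([r[1] for r in keep_rows], dtype=int),
        values=values,
        mask=~np.isnan(values) if len(vals) else np.empty((0, len(lags)), bool),
    )
    return windows, report
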