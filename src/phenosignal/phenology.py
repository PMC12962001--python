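"""Flowering-phenology trait extraction from census and temperature series.

Converts raw field observations into the eleven per-species flowering
traits used throughout the package:

calendar-based (days)
    ``FF_DOY``  day of year of first flowering;
    ``FF``      days from snowmelt to first flowering;
    ``PFP``     days from snowmelt to the census with the maximum number
    of plants in flower; ``PFA`` same for the maximum number of open
    flowers; ``FSL`` days between the first and last flowering census.

thermal-sum-based (degree-days)
    ``GDD{0,5}{FF,PFP,PFA}`` — growing degree days accumulated from the
    snowmelt biofix through each calendar milestone, at base temperatures
    0 and 5 degrees C, using the double-sine method with a horizontal
    lower cutoff and no upper threshold.

The double-sine method (Allen 1976) models each day's temperature course
as two half-sines: one rising from the day's minimum to its maximum over
half the day, one falling from the maximum to the NEXT day's minimum over
the other half.  Degree days are the area of that curve above the base
temperature.  The final day of a season pairs with its own minimum for
the falling half.

Also provides the Augspurger flowering-synchrony index: for species i,
X_i = (1/(n-1)) * sum_{j != i} e_ij / f_i, where e_ij counts censuses on
which both i and j were in flower and f_i counts censuses on which i was
in flower.  The site index is the mean of X_i over species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CensusSeries",
    "TemperatureSeries",
    "SiteCalendar",
    "TRAIT_COLUMNS",
    "daily_extremes",
    "gdd_double_sine",
    "calendar_traits",
    "gdd_traits",
    "augspurger_synchrony",
    "build_trait_table",
    "read_census_csv",
    "read_temperature_csv",
    "read_site_calendars",
]

#: canonical trait column order for trait tables
TRAIT_COLUMNS = [
    "FF_DOY", "FF", "PFP", "PFA", "FSL",
    "GDD0FF", "GDD5FF", "GDD0PFP", "GDD5PFP", "GDD0PFA", "GDD5PFA",
]

CALENDAR_TRAITS = ["FF_DOY", "FF", "PFP", "PFA", "FSL"]


@dataclass
class SiteCalendar:
    """Per-site season anchors: snowmelt biofix and end of observations."""

    site_id: str
    snowmelt_date: date
    season_end: date

    def __post_init__(self) -> None:
        if self.snowmelt_date >= self.season_end:
            raise ValueError(
                f"{self.site_id}: snowmelt {self.snowmelt_date} must precede "
                f"season end {self.season_end}"
            )


@dataclass
class CensusSeries:
    """Flowering observations for one species at one site.

    ``records`` columns: ``date`` (datetime.date), ``n_plants`` (plants in
    flower), ``n_flowers`` (open flowers); rows sorted by date.
    """

    site_id: str
    species_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"date", "n_plants", "n_flowers"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"census records need columns {sorted(req)}")
        d = pd.to_datetime(self.records["date"]).dt.date
        if not d.is_monotonic_increasing or d.duplicated().any():
            raise ValueError(
                f"{self.site_id}/{self.species_id}: census dates must be "
                "strictly increasing"
            )
        if (self.records[["n_plants", "n_flowers"]] < 0).any().any():
            raise ValueError("census counts must be nonnegative")
        self.records = self.records.assign(date=d).reset_index(drop=True)

    @property
    def ever_flowers(self) -> bool:
        return bool((self.records["n_plants"] > 0).any())


@dataclass
class TemperatureSeries:
    """Hourly (or denser) air-temperature samples for one site."""

    site_id: str
    samples: pd.DataFrame  # columns: timestamp (datetime), temp_c

    def __post_init__(self) -> None:
        req = {"timestamp", "temp_c"}
        if not req.issubset(self.samples.columns):
            raise ValueError(f"temperature samples need columns {sorted(req)}")
        ts = pd.to_datetime(self.samples["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(
                f"{self.site_id}: timestamps must be strictly increasing"
            )
        self.samples = self.samples.assign(timestamp=ts).reset_index(drop=True)


# ---------------------------------------------------------------------------
# temperature -> degree days
# ---------------------------------------------------------------------------

def daily_extremes(series: TemperatureSeries, min_samples: int = 12) -> pd.DataFrame:
    """Per-calendar-day minimum and maximum temperature.

    Days with fewer than ``min_samples`` readings are kept but flagged;
    the caller decides whether flagged days invalidate a season.
    """
    if series.samples.empty:
        raise ValueError(f"{series.site_id}: empty temperature series")
    df = series.samples
    grp = df.groupby(df["timestamp"].dt.date)["temp_c"]
    out = grp.agg(tmin="min", tmax="max", n_samples="size").reset_index(
        names="date"
    )
    out["flagged"] = out["n_samples"] < min_samples
    return out


def _half_sine_dd(t_low: float, t_high: float, t_base: float) -> float:
    """Degree days above ``t_base`` for one half-day half-sine segment.

    The segment sweeps from ``t_low`` to ``t_high`` (in either direction:
    the sine is symmetric); no upper threshold, horizontal cutoff below
    the base.
    """
    if t_low > t_high:
        t_low, t_high = t_high, t_low
    m = 0.5 * (t_high + t_low)
    a = 0.5 * (t_high - t_low)
    if t_base <= t_low:
        return 0.5 * (m - t_base)
    if t_base >= t_high:
        return 0.0
    theta = np.arcsin((t_base - m) / a)
    return float(((m - t_base) * (np.pi / 2 - theta) + a * np.cos(theta)) / (2 * np.pi))


def double_sine_day(tmin: float, tmax: float, next_tmin: float, t_base: float) -> float:
    """One day's degree-day contribution under the double-sine method."""
    if tmin > tmax:
        raise ValueError(f"tmin {tmin} exceeds tmax {tmax}")
    if next_tmin > tmax:
        # falling half cannot rise; clamp to an isothermal half-day
        next_tmin = tmax
    return _half_sine_dd(tmin, tmax, t_base) + _half_sine_dd(next_tmin, tmax, t_base)


def gdd_double_sine(
    extremes: pd.DataFrame,
    t_base: float,
    start: date,
    end: date,
) -> pd.Series:
    """Cumulative growing degree days per day over [start, end], inclusive.

    ``extremes`` is the output of :func:`daily_extremes` (columns ``date``,
    ``tmin``, ``tmax``).  The last day in range pairs with its own minimum
    for the falling half-sine.  The returned series is nondecreasing and
    indexed by date.
    """
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    ext = extremes.set_index("date")
    days = [start + timedelta(days=i) for i in range((end - start).days + 1)]
    missing = [d for d in days if d not in ext.index]
    if missing:
        raise ValueError(f"temperature extremes missing for days: {missing}")
    bad = ext.loc[days][ext.loc[days, "tmin"] > ext.loc[days, "tmax"]]
    if len(bad):
        raise ValueError(f"tmin > tmax on {list(bad.index)}")
    daily = np.empty(len(days))
    for k, d in enumerate(days):
        nxt = d + timedelta(days=1)
        next_tmin = ext.at[nxt, "tmin"] if nxt in ext.index else ext.at[d, "tmin"]
        daily[k] = double_sine_day(
            ext.at[d, "tmin"], ext.at[d, "tmax"], next_tmin, t_base
        )
    return pd.Series(np.cumsum(daily), index=pd.Index(days, name="date"))


# ---------------------------------------------------------------------------
# censuses -> calendar traits
# ---------------------------------------------------------------------------

def calendar_traits(series: CensusSeries, cal: SiteCalendar) -> dict | None:
    """The five calendar-based traits for one species, or None if the
    species never flowered.

    Peak ties break to the earliest census.  FSL is last-minus-first
    flowering census in days (0 when the species flowered on one census
    only).
    """
    rec = series.records
    flowering = rec[rec["n_plants"] > 0]
    if flowering.empty:
        return None
    first = flowering["date"].iloc[0]
    last = flowering["date"].iloc[-1]
    snow = cal.snowmelt_date
    # idxmax returns the first occurrence: the earliest-census tie rule
    pfp_date = rec.loc[rec["n_plants"].idxmax(), "date"]
    pfa_date = rec.loc[rec["n_flowers"].idxmax(), "date"]
    return {
        "FF_DOY": float(first.timetuple().tm_yday),
        "FF": float((first - snow).days),
        "PFP": float((pfp_date - snow).days),
        "PFA": float((pfa_date - snow).days),
        "FSL": float((last - first).days),
    }


def gdd_traits(
    calendar: dict,
    cal: SiteCalendar,
    cumulative_gdd0: pd.Series,
    cumulative_gdd5: pd.Series,
) -> dict:
    """Thermal-sum traits: cumulative GDD through each calendar milestone.

    ``calendar`` holds FF/PFP/PFA as days from snowmelt; the milestone
    day itself accrues (biofix and milestone inclusive).
    """
    out = {}
    for milestone in ("FF", "PFP", "PFA"):
        offset = calendar[milestone]
        if offset < 0:
            raise ValueError(
                f"milestone {milestone} precedes the snowmelt biofix"
            )
        day = cal.snowmelt_date + timedelta(days=int(offset))
        for base, cum in (("0", cumulative_gdd0), ("5", cumulative_gdd5)):
            if day not in cum.index:
                raise ValueError(
                    f"cumulative GDD series does not cover {day} "
                    f"(milestone {milestone})"
                )
            out[f"GDD{base}{milestone}"] = float(cum.loc[day])
    return out


# ---------------------------------------------------------------------------
# synchrony
# ---------------------------------------------------------------------------

def augspurger_synchrony(presence: pd.DataFrame) -> tuple[pd.Series, float]:
    """Flowering-synchrony index per species and its site mean.

    ``presence`` is a species x census boolean matrix (True = at least
    one plant in flower on that census).  Species that never flower are
    excluded with a warning.  All values lie in [0, 1].
    """
    P = presence.astype(bool)
    f = P.sum(axis=1)
    silent = f[f == 0].index.tolist()
    if silent:
        warnings.warn(f"species never flowering excluded from synchrony: {silent}")
        P = P.drop(index=silent)
        f = f.drop(index=silent)
    n = len(P)
    if n < 2:
        raise ValueError("synchrony needs >= 2 flowering species")
    M = P.to_numpy(dtype=float)
    overlap = M @ M.T  # e_ij
    np.fill_diagonal(overlap, 0.0)
    x = overlap.sum(axis=1) / (f.to_numpy() * (n - 1))
    per_species = pd.Series(x, index=P.index, name="synchrony")
    return per_species, float(per_species.mean())


# ---------------------------------------------------------------------------
# assembly into a trait table
# ---------------------------------------------------------------------------

def build_trait_table(
    censuses: list[CensusSeries],
    calendars: dict[str, SiteCalendar],
    temperatures: dict[str, TemperatureSeries],
    t_bases: tuple[float, float] = (0.0, 5.0),
) -> pd.DataFrame:
    """All eleven traits for every (site, species) census series.

    Species that never flowered are omitted (with a warning naming them).
    Returns a DataFrame indexed by (site, species) with
    :data:`TRAIT_COLUMNS` columns.
    """
    cum: dict[str, dict[float, pd.Series]] = {}
    for site, cal in calendars.items():
        ext = daily_extremes(temperatures[site])
        cum[site] = {
            b: gdd_double_sine(ext, b, cal.snowmelt_date, cal.season_end)
            for b in t_bases
        }
    rows = {}
    skipped = []
    for cs in censuses:
        cal = calendars[cs.site_id]
        cal_traits = calendar_traits(cs, cal)
        if cal_traits is None:
            skipped.append((cs.site_id, cs.species_id))
            continue
        gdd = gdd_traits(
            cal_traits, cal, cum[cs.site_id][t_bases[0]], cum[cs.site_id][t_bases[1]]
        )
        rows[(cs.site_id, cs.species_id)] = {**cal_traits, **gdd}
    if skipped:
        warnings.warn(f"species with no flowering records skipped: {skipped}")
    table = pd.DataFrame.from_dict(rows, orient="index")[TRAIT_COLUMNS]
    table.index = pd.MultiIndex.from_tuples(table.index, names=["site", "species"])
    return table.sort_index()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_census_csv(path) -> list[CensusSeries]:
    """Read a tidy census file (site, species, date, n_plants, n_flowers)."""
    df = pd.read_csv(path)
    req = {"site", "species", "date", "n_plants", "n_flowers"}
    if not req.issubset(df.columns):
        raise ValueError(f"census file needs columns {sorted(req)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    out = []
    for (site, species), grp in df.groupby(["site", "species"], sort=True):
        out.append(
            CensusSeries(
                str(site), str(species), grp.sort_values("date")[
                    ["date", "n_plants", "n_flowers"]
                ]
            )
        )
    return out


def read_temperature_csv(path, site_id: str) -> TemperatureSeries:
    df = pd.read_csv(path)
    if not {"timestamp", "temp_c"}.issubset(df.columns):
        raise ValueError("temperature file needs columns timestamp, temp_c")
    return TemperatureSeries(site_id, df)


def read_site_calendars(path) -> dict[str, SiteCalendar]:
    """Read site calendars from YAML: {site: {snowmelt: date, season_end: date}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for site, entry in raw.items():
        out[str(site)] = SiteCalendar(
            str(site),
            _as_date(entry["snowmelt"]),
            _as_date(entry["season_end"]),
        )
    return out


def _as_date(value) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    return datetime.strptime(str(value), "%Y-%m-%d").date()
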