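"""Daily driver tables: readers, writers, and derived drivers.

Driver tables are delimited text with one row per enclosure-day.  Each
focal year's :class:`~phenoproc.datatypes.DriverSeries` spans 1 Sep of the
previous calendar year (day-of-year index -121) through 31 Dec of the focal
year, so chilling accumulation can start in the preceding autumn.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SOIL_DEPTHS_CM, DriverSeries, EnclosureMetadata, TransitionObservation

__all__ = [
    "compute_daylength",
    "compute_vpd",
    "read_driver_table",
    "write_driver_table",
    "read_transition_table",
    "write_transition_table",
    "read_metadata_table",
    "write_metadata_table",
    "DEFAULT_SCHEMA",
]

#: Default column mapping for driver tables.
DEFAULT_SCHEMA: dict[str, str] = {
    "enclosure": "enclosure",
    "date": "date",
    "t_air": "tair_c",
    "water_table": "wtd_cm",
    "co2": "co2_ppm",
    "rh": "rh_pct",
    **{f"t_soil_{d}": f"tsoil_{d}cm" for d in SOIL_DEPTHS_CM},
}

#: Solar elevation (degrees) defining sunrise/sunset; -0.83 gives civil
#: daylength including refraction and the solar disc radius.
SUN_ELEVATION_DEG = -0.83

#: Longest run of missing days filled by linear interpolation.
MAX_INTERP_GAP = 3


class SchemaError(ValueError):
    """A mandatory column is missing from a driver table."""


class DataError(ValueError):
    """Duplicate or inconsistent rows in a driver table."""


class GapError(ValueError):
    """A gap in the daily axis too long to interpolate."""


def compute_daylength(latitude: float, doy, elevation_deg: float = SUN_ELEVATION_DEG):
    """Photoperiod in hours for a latitude and day(s) of year.

    Uses solar declination delta = -23.44 deg * cos(2*pi*(doy+10)/365) and the
    sunset hour angle at the configured solar elevation threshold
    (``elevation_deg``, default -0.83 deg: civil daylength).  Negative or
    >365 day-of-year values wrap around the calendar, so the previous-autumn
    window indexes directly.

    Parameters
    ----------
    latitude : float
        Degrees north, in [-90, 90].
    doy : int or array-like
        Day of year; values outside [1, 366] are wrapped modulo 365.

    Returns
    -------
    float or ndarray
        Daylength in hours, clipped to [0, 24].
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} out of [-90, 90]")
    doy_arr = np.atleast_1d(np.asarray(doy, dtype=float))
    doy_wrapped = np.mod(doy_arr - 1, 365) + 1
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (doy_wrapped + 10) / 365.0)
    phi = np.deg2rad(latitude)
    h0 = np.deg2rad(elevation_deg)
    cos_omega = (np.sin(h0) - np.sin(phi) * np.sin(decl)) / (np.cos(phi) * np.cos(decl))
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_omega)
    return float(hours[0]) if np.isscalar(doy) or np.ndim(doy) == 0 else hours


def saturation_vapour_pressure(t_air):
    """Saturation vapour pressure (kPa) over water, Tetens formula."""
    t = np.asarray(t_air, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def compute_vpd(t_air, relative_humidity):
    """Vapour pressure deficit (kPa) from air temperature and RH (%).

    VPD = e_sat(T) * (1 - RH/100) with e_sat from the Tetens formula; zero
    at saturation, e_sat itself at 0% humidity.
    """
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity outside [0, 100] %")
    vpd = saturation_vapour_pressure(t_air) * (1.0 - rh / 100.0)
    return float(vpd) if np.ndim(vpd) == 0 else vpd


def _window_index(date: _dt.date, focal_year: int) -> int:
    """Day-of-year index of a date relative to a focal year (may be <= 0)."""
    doy = date.timetuple().tm_yday
    if date.year == focal_year:
        return doy
    days_prev = 366 if _is_leap(date.year) else 365
    return doy - days_prev


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _interpolate_gaps(df: pd.DataFrame, enclosure: str) -> pd.DataFrame:
    """Reindex to a continuous daily axis; fill short gaps, error on long ones."""
    full = pd.date_range(df.index.min(), df.index.max(), freq="D")
    missing = full.difference(df.index)
    if len(missing):
        runs = _runs(missing)
        for start, end, length in runs:
            if length > MAX_INTERP_GAP:
                raise GapError(
                    f"enclosure {enclosure}: {length}-day gap "
                    f"{start.date()}..{end.date()} exceeds the "
                    f"{MAX_INTERP_GAP}-day interpolation limit"
                )
        df = df.reindex(full).interpolate(method="time", limit_area="inside")
    return df


def _runs(missing: pd.DatetimeIndex) -> list[tuple[pd.Timestamp, pd.Timestamp, int]]:
    runs = []
    start = prev = missing[0]
    for ts in missing[1:]:
        if (ts - prev).days > 1:
            runs.append((start, prev, (prev - start).days + 1))
            start = ts
        prev = ts
    runs.append((start, prev, (prev - start).days + 1))
    return runs


def read_driver_table(
    path,
    schema: Optional[Mapping[str, str]] = None,
    latitude: Optional[float] = None,
    sep: str = ",",
) -> list[DriverSeries]:
    """Read a delimited driver table into per-(enclosure, year) series.

    A focal year is emitted only when both the full calendar year and the
    preceding 1 Sep - 31 Dec window are covered.  Missing optional drivers
    (water table, CO2, humidity) are left absent rather than zero-filled;
    daylength is derived when ``latitude`` is given; VPD is derived when a
    humidity column is present.

    Raises
    ------
    SchemaError
        Mandatory column (enclosure, date, air temperature) absent.
    DataError
        Duplicated (enclosure, date) row.
    GapError
        A hole in the daily axis longer than 3 days.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, sep=sep)
    for key in ("enclosure", "date", "t_air"):
        if colmap[key] not in raw.columns:
            raise SchemaError(f"mandatory column {colmap[key]!r} missing from {path}")
    raw["_date"] = pd.to_datetime(raw[colmap["date"]])

    out: list[DriverSeries] = []
    for enc, grp in raw.groupby(colmap["enclosure"], sort=True):
        dup = grp["_date"].duplicated()
        if dup.any():
            first = grp.loc[dup, "_date"].iloc[0].date()
            raise DataError(f"duplicate date {first} for enclosure {enc}")
        grp = grp.set_index("_date").sort_index()
        grp = _interpolate_gaps(grp.drop(columns=[colmap["enclosure"], colmap["date"]]), str(enc))
        years = sorted(set(grp.index.year))
        for year in years:
            win_start = pd.Timestamp(year - 1, 9, 1)
            win_end = pd.Timestamp(year, 12, 31)
            if grp.index.min() > win_start or grp.index.max() < win_end:
                continue
            win = grp.loc[win_start:win_end]
            doy = np.array([_window_index(d.date(), year) for d in win.index])
            t_soil = {}
            for d in SOIL_DEPTHS_CM:
                col = colmap[f"t_soil_{d}"]
                if col in win.columns and not win[col].isna().all():
                    t_soil[d] = win[col].to_numpy(dtype=float)

            def _opt(key):
                col = colmap[key]
                if col in win.columns and not win[col].isna().all():
                    return win[col].to_numpy(dtype=float)
                return None

            daylength = None
            if latitude is not None:
                daylength = compute_daylength(latitude, doy)
            rh = _opt("rh")
            t_air = win[colmap["t_air"]].to_numpy(dtype=float)
            vpd = compute_vpd(t_air, rh) if rh is not None else None
            out.append(
                DriverSeries(
                    enclosure_id=str(enc),
                    focal_year=int(year),
                    doy=doy,
                    t_air=t_air,
                    t_soil=t_soil,
                    water_table=_opt("water_table"),
                    co2=_opt("co2"),
                    daylength=daylength,
                    vpd=vpd,
                )
            )
    return out


def _doy_to_date(doy: int, focal_year: int, skip_leap_day: bool = False) -> _dt.date:
    """Date of a window index.  With ``skip_leap_day`` a 365-day axis in a
    leap focal year maps to the real calendar minus 29 Feb, so consecutive
    focal-year windows written to one table stay mutually consistent."""
    doy = int(doy)
    if skip_leap_day and doy >= 60:  # on/after 1 Mar in the 365-day calendar
        doy += 1
    return _dt.date(focal_year, 1, 1) + _dt.timedelta(days=doy - 1)


def write_driver_table(
    series: Sequence[DriverSeries],
    path,
    schema: Optional[Mapping[str, str]] = None,
    sep: str = ",",
) -> None:
    """Write driver series back to the delimited format of
    :func:`read_driver_table`.  Overlapping windows of consecutive focal
    years are merged (previous-autumn rows deduplicated)."""
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    frames = []
    for s in series:
        skip = _is_leap(s.focal_year) and int(s.doy[-1]) == 365
        row = {
            colmap["enclosure"]: s.enclosure_id,
            colmap["date"]: [_doy_to_date(d, s.focal_year, skip).isoformat() for d in s.doy],
            colmap["t_air"]: s.t_air,
        }
        for d, arr in s.t_soil.items():
            row[colmap[f"t_soil_{d}"]] = arr
        if s.water_table is not None:
            row[colmap["water_table"]] = s.water_table
        if s.co2 is not None:
            row[colmap["co2"]] = s.co2
        frames.append(pd.DataFrame(row))
    df = pd.concat(frames, ignore_index=True)
    df = df.drop_duplicates(subset=[colmap["enclosure"], colmap["date"]])
    df = df.sort_values([colmap["enclosure"], colmap["date"]])
    df.to_csv(path, sep=sep, index=False)


def read_transition_table(path, sep: str = ",") -> list[TransitionObservation]:
    """Read transition observations from CSV
    (enclosure, year, pft, season, doy, ci_lower, ci_upper)."""
    df = pd.read_csv(path, sep=sep)
    obs = []
    for _, r in df.iterrows():
        obs.append(
            TransitionObservation(
                enclosure_id=str(r["enclosure"]),
                year=int(r["year"]),
                pft=str(r["pft"]),
                season=str(r["season"]),
                doy=float(r["doy"]),
                ci_lower=float(r.get("ci_lower", np.nan)),
                ci_upper=float(r.get("ci_upper", np.nan)),
            )
        )
    return obs


def write_transition_table(observations: Iterable[TransitionObservation], path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "enclosure": o.enclosure_id,
                "year": o.year,
                "pft": o.pft,
                "season": o.season,
                "doy": o.doy,
                "ci_lower": o.ci_lower,
                "ci_upper": o.ci_upper,
            }
            for o in observations
        ]
    )
    df.to_csv(path, sep=sep, index=False)


def read_metadata_table(path, sep: str = ",") -> list[EnclosureMetadata]:
    df = pd.read_csv(path, sep=sep)
    return [
        EnclosureMetadata(
            enclosure_id=str(r["enclosure"]),
            target_warming=float(r["target_warming"]),
            co2_treatment=str(r["co2_treatment"]),
            measured_warming=float(r["measured_warming"]),
            latitude=float(r.get("latitude", 47.5)),
            longitude=float(r.get("longitude", -93.45)),
        )
        for _, r in df.iterrows()
    ]


def write_metadata_table(metadata: Iterable[EnclosureMetadata], path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "enclosure": m.enclosure_id,
                "target_warming": m.target_warming,
                "co2_treatment": m.co2_treatment,
                "measured_warming": m.measured_warming,
                "latitude": m.latitude,
                "longitude": m.longitude,
            }
            for m in metadata
        ]
    )
    df.to_csv(path, sep=sep, index=False)
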