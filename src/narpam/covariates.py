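"""Environmental and response series for presence modelling.

Covers solar elevation (NOAA Solar Calculator algorithm with atmospheric
refraction), daily sea-ice concentration summaries over a radial mask,
effort-aware binary presence binning, detection-event statistics, transit
cessation fractions, and assembly of the per-bin model frame consumed by
the GEE module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ais import range_to_site

__all__ = [
    "solar_elevation",
    "IceSummary",
    "summarize_ice",
    "bin_presence",
    "detection_events",
    "cessation_stats",
    "assemble_model_frame",
]


# --------------------------------------------------------------------------
# solar geometry
# --------------------------------------------------------------------------

def solar_elevation(timestamps_utc, lat_deg: float, lon_deg: float):
    """Solar elevation above the horizon, degrees, refraction-corrected.

    Implements the NOAA Solar Calculator spreadsheet chain: Julian century,
    geometric mean solar longitude and anomaly, equation of centre, apparent
    longitude, corrected obliquity, declination, equation of time, hour
    angle, zenith, and the standard piecewise atmospheric-refraction
    correction.  Accurate to well under 0.1 deg for years 1900-2100, which
    is ample for a diel/seasonal covariate.

    Accepts a scalar or array-like of timezone-aware (UTC) timestamps.
    """
    scalar = np.ndim(timestamps_utc) == 0 and not isinstance(
        timestamps_utc, (list, tuple, np.ndarray, pd.Index, pd.Series)
    )
    arg = [timestamps_utc] if scalar else timestamps_utc
    ts = pd.DatetimeIndex(pd.to_datetime(arg, utc=True))
    # Julian day from unix epoch (1970-01-01 = JD 2440587.5)
    jd = ts.astype("int64").to_numpy() / 1e9 / 86400.0 + 2440587.5
    jc = (jd - 2451545.0) / 36525.0  # Julian century from J2000

    geom_mean_long = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    m = np.radians(geom_mean_anom)
    eq_center = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(125.04 - 1934.136 * jc))

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * np.cos(np.radians(125.04 - 1934.136 * jc))

    decl = np.degrees(
        np.arcsin(np.sin(np.radians(obliq_corr)) * np.sin(np.radians(app_long)))
    )

    var_y = np.tan(np.radians(obliq_corr / 2.0)) ** 2
    eq_time_min = 4.0 * np.degrees(
        var_y * np.sin(2 * np.radians(geom_mean_long))
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * var_y * np.sin(m) * np.cos(2 * np.radians(geom_mean_long))
        - 0.5 * var_y**2 * np.sin(4 * np.radians(geom_mean_long))
        - 1.25 * ecc**2 * np.sin(2 * m)
    )

    frac_day = (jd + 0.5) % 1.0  # fraction of UTC day
    true_solar_min = np.mod(frac_day * 1440.0 + eq_time_min + 4.0 * lon_deg, 1440.0)
    hour_angle = np.where(
        true_solar_min / 4.0 < 0, true_solar_min / 4.0 + 180.0, true_solar_min / 4.0 - 180.0
    )

    lat = np.radians(lat_deg)
    zen = np.degrees(
        np.arccos(
            np.clip(
                np.sin(lat) * np.sin(np.radians(decl))
                + np.cos(lat) * np.cos(np.radians(decl)) * np.cos(np.radians(hour_angle)),
                -1.0,
                1.0,
            )
        )
    )
    elev = 90.0 - zen

    # NOAA piecewise refraction correction (degrees), applied to apparent elevation
    e = elev
    te = np.tan(np.radians(np.where(np.abs(e) > 1e-9, e, 1e-9)))
    refr = np.where(
        e > 85.0,
        0.0,
        np.where(
            e > 5.0,
            58.1 / te - 0.07 / te**3 + 0.000086 / te**5,
            np.where(
                e > -0.575,
                1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711))),
                -20.772 / te,
            ),
        ),
    ) / 3600.0
    out = elev + refr
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# sea ice
# --------------------------------------------------------------------------

@dataclass
class IceSummary:
    date: object
    mean_pct: float
    median_pct: float
    variance: float
    n_cells: int
    sit_m: float | None = None


def summarize_ice(
    grid: pd.DataFrame,
    site_lat_deg: float,
    site_lon_deg: float,
    radius_km: float = 20.0,
    shore_mask=None,
    date=None,
) -> IceSummary:
    """Mean/median/variance of sea-ice concentration inside a radial mask.

    ``grid`` holds one day's cells with columns lat_deg, lon_deg, sic_pct.
    Cells whose centre lies within ``radius_km`` of the site and are not
    excluded by ``shore_mask`` (boolean, True = within 1 km of shore, drop)
    contribute.  The median is the headline statistic; with an even cell
    count the midpoint (mean of the two central values) convention is used.
    """
    cells = grid.reset_index(drop=True)
    r = np.atleast_1d(
        range_to_site(
            cells["lat_deg"].to_numpy(), cells["lon_deg"].to_numpy(),
            site_lat_deg, site_lon_deg,
        )
    )
    keep = r <= radius_km
    if shore_mask is not None:
        keep &= ~np.asarray(shore_mask, dtype=bool)
    vals = cells.loc[keep, "sic_pct"].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("ice mask is empty: no grid cells within radius")
    return IceSummary(
        date=date,
        mean_pct=float(np.mean(vals)),
        median_pct=float(np.median(vals)),
        variance=float(np.var(vals)),
        n_cells=int(vals.size),
    )


# --------------------------------------------------------------------------
# presence series
# --------------------------------------------------------------------------

def bin_presence(
    detection_times,
    effort: pd.DataFrame,
    bin_width: str = "1h",
) -> pd.DataFrame:
    """Effort-aware binary presence series.

    ``effort`` has columns t_start, t_end, fraction (1.0 for continuous
    recording, 0.75 for the 15-min-on/5-min-off duty cycle).  Bins with zero
    recorded fraction are *excluded* from the output rather than coded as
    absence.  ``present`` is 1 iff at least one finalized detection falls in
    the bin (binary, not a count).
    """
    effort = effort.copy()
    effort["t_start"] = pd.to_datetime(effort["t_start"], utc=True)
    effort["t_end"] = pd.to_datetime(effort["t_end"], utc=True)
    if effort.empty:
        return pd.DataFrame(columns=["bin_start", "present", "effort"])
    t0 = effort["t_start"].min().floor(bin_width)
    t1 = effort["t_end"].max().ceil(bin_width)
    bins = pd.date_range(t0, t1, freq=bin_width, inclusive="left")
    width = pd.Timedelta(bin_width)

    frac = np.zeros(len(bins))
    for _, row in effort.iterrows():
        overlap = (
            np.minimum(bins + width, row["t_end"]) - np.maximum(bins, row["t_start"])
        ) / width
        frac += np.clip(overlap, 0.0, 1.0) * row["fraction"]
    frac = np.clip(frac, 0.0, 1.0)

    present = np.zeros(len(bins), dtype=int)
    det = pd.DatetimeIndex(pd.to_datetime(detection_times, utc=True))
    if len(det):
        pos = np.searchsorted(bins, det.to_numpy(), side="right") - 1
        pos = pos[(pos >= 0) & (pos < len(bins))]
        present[np.unique(pos)] = 1

    out = pd.DataFrame({"bin_start": bins, "present": present, "effort": frac})
    return out[out["effort"] > 0].reset_index(drop=True)


def detection_events(presence_min: pd.DataFrame, gap_min: float = 15.0):
    """Merge minute-resolution presence into events and summarize durations.

    Runs of presence separated by gaps of at most ``gap_min`` minutes are a
    single event.  Returns ``(events, summary)`` where summary holds the
    mean, SD, median, and max event duration in minutes (NaN when no event).
    """
    pres = presence_min[presence_min["present"] == 1].sort_values("bin_start")
    if pres.empty:
        return (
            pd.DataFrame(columns=["t_start", "t_end", "duration_min"]),
            {"n_events": 0, "mean_min": np.nan, "sd_min": np.nan,
             "median_min": np.nan, "max_min": np.nan},
        )
    t = pres["bin_start"].reset_index(drop=True)
    gaps = t.diff().dt.total_seconds().to_numpy() / 60.0
    new_event = np.concatenate([[True], gaps[1:] > gap_min])
    eid = np.cumsum(new_event)
    ev = pd.DataFrame({"t": t, "eid": eid}).groupby("eid")["t"].agg(["min", "max"])
    events = pd.DataFrame(
        {
            "t_start": ev["min"],
            "t_end": ev["max"] + pd.Timedelta(minutes=1),
        }
    ).reset_index(drop=True)
    events["duration_min"] = (
        (events["t_end"] - events["t_start"]).dt.total_seconds() / 60.0
    )
    dur = events["duration_min"].to_numpy()
    summary = {
        "n_events": int(len(events)),
        "mean_min": float(np.mean(dur)),
        "sd_min": float(np.std(dur, ddof=1)) if len(dur) > 1 else 0.0,
        "median_min": float(np.median(dur)),
        "max_min": float(np.max(dur)),
    }
    return events, summary


def cessation_stats(
    presence_min: pd.DataFrame,
    windows,
    rnv_min: pd.DataFrame,
    bands_km=(30.0, 20.0, 15.0, 10.0, 5.0),
) -> pd.DataFrame:
    """Fraction of ship-transit cases in which detections ceased, per band.

    A *case* is a valid transit window during which narwhals were acoustically
    present at some time while the ship was inside the 40 km radius.  For a
    distance band ``b``, cases where the ship actually came within ``b`` form
    the denominator, and such a case counts as a cessation iff no presence
    minute occurs while the ship's range is <= ``b``.  Returns a frame
    (band_km, n_cases, n_cessation, fraction); empty counts when no window
    overlaps presence.
    """
    pres = presence_min.set_index("bin_start")["present"]
    rnv = rnv_min.set_index("bin_start")["rnv_km"]
    rows = []
    cases = []
    for w in windows:
        if not w.valid:
            continue
        idx = pres.index[(pres.index >= w.t_enter) & (pres.index <= w.t_exit)]
        if len(idx) == 0 or pres.loc[idx].sum() == 0:
            continue
        cases.append((w, idx))
    for band in bands_km:
        n_cess = n_in_band = 0
        for w, idx in cases:
            in_band = rnv.reindex(idx).to_numpy() <= band
            present = pres.loc[idx].to_numpy().astype(bool)
            if np.any(in_band):
                n_in_band += 1
                if not np.any(in_band & present):
                    n_cess += 1
        rows.append(
            {
                "band_km": band,
                "n_cases": n_in_band,
                "n_cessation": n_cess,
                "fraction": n_cess / n_in_band if n_in_band else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model frame
# --------------------------------------------------------------------------

def assemble_model_frame(
    presence: pd.DataFrame,
    lat_deg: float,
    lon_deg: float,
    ice_daily: pd.DataFrame | None = None,
    rnv: pd.DataFrame | None = None,
    rnv_sentinel_km: float = 40.0,
    period=None,
) -> pd.DataFrame:
    """Join response and covariates into the per-bin GEE input frame.

    Adds day_of_year, year (categorical label), solar_deg (computed at bin
    start), ice_pct (that calendar day's median SIC, broadcast), and when
    ``rnv`` is given, ship_present plus rnv_km with no-ship bins set to the
    sentinel reference (consumed via the ship_present x rnv interaction so
    the sentinel value cannot influence no-ship fits).
    """
    frame = presence.copy()
    if period is not None:
        t0, t1 = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        frame = frame[(frame["bin_start"] >= t0) & (frame["bin_start"] < t1)]
    frame = frame.reset_index(drop=True)
    frame["day_of_year"] = frame["bin_start"].dt.dayofyear
    frame["year"] = frame["bin_start"].dt.year.astype(str)
    frame["solar_deg"] = solar_elevation(frame["bin_start"], lat_deg, lon_deg)

    if ice_daily is not None:
        ice = ice_daily.copy()
        ice["date"] = pd.to_datetime(ice["date"], utc=True).dt.normalize()
        frame["date"] = frame["bin_start"].dt.normalize()
        frame = frame.merge(
            ice[["date", "median_pct"]].rename(columns={"median_pct": "ice_pct"}),
            on="date",
            how="left",
        ).drop(columns="date")
        if frame["ice_pct"].isna().any():
            missing = frame.loc[frame["ice_pct"].isna(), "bin_start"]
            raise ValueError(
                f"ice series does not cover {len(missing)} bins, first {missing.iloc[0]}"
            )

    if rnv is not None:
        frame = frame.merge(rnv, on="bin_start", how="left")
        frame["ship_present"] = frame["ship_present"].fillna(False).astype(int)
        frame["rnv_km"] = frame["rnv_km"].where(
            frame["ship_present"] == 1, rnv_sentinel_km
        )
        if frame["rnv_km"].isna().any():
            raise ValueError("rnv series has ship_present bins without a range")
    return frame
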