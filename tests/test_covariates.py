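"""Solar geometry, ice summaries, presence binning, events, cessation, frames."""

import numpy as np
import pandas as pd
import pytest

from narpam.ais import TransitWindow
from narpam.covariates import (
    assemble_model_frame,
    bin_presence,
    cessation_stats,
    detection_events,
    solar_elevation,
    summarize_ice,
)

SITE = (72.724, -76.231)


def almanac_solar_elevation(ts, lat_deg, lon_deg):
    """Independent low-precision ephemeris (Astronomical Almanac 1950-2050).

    Different formulation from the production algorithm: ecliptic longitude
    from a two-term equation of centre, declination/right ascension via the
    obliquity, hour angle from GMST.  Used purely as a cross-check oracle.
    """
    ts = pd.Timestamp(ts)
    jd = ts.value / 1e9 / 86400.0 + 2440587.5
    n = jd - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    hour_ut = ts.hour + ts.minute / 60 + ts.second / 3600
    gmst_h = (6.697375 + 0.0657098242 * n + hour_ut) % 24
    lst = np.radians((gmst_h * 15 + lon_deg) % 360.0)
    ha = lst - ra
    lat = np.radians(lat_deg)
    elev = np.degrees(
        np.arcsin(np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha))
    )
    return elev


class TestSolar:
    def test_equator_equinox_solar_noon_near_zenith(self):
        # 2019 March equinox; solar noon at lon 0 ~ 12:07 UTC
        e = solar_elevation(pd.Timestamp("2019-03-20 12:07", tz="UTC"), 0.0, 0.0)
        assert e == pytest.approx(90.0, abs=0.5)

    def test_polar_night_at_site_in_late_december(self):
        times = pd.date_range("2019-12-21", periods=24, freq="1h", tz="UTC")
        assert (solar_elevation(times, *SITE) < 0).all()

    def test_midnight_sun_at_site_in_june(self):
        times = pd.date_range("2019-06-21", periods=24, freq="1h", tz="UTC")
        assert (solar_elevation(times, *SITE) > 0).all()

    def test_agrees_with_independent_ephemeris(self):
        rng = np.random.default_rng(7)
        t0 = pd.Timestamp("2019-01-01", tz="UTC")
        for _ in range(100):
            ts = t0 + pd.Timedelta(seconds=float(rng.uniform(0, 365 * 86400)))
            mine = solar_elevation(ts, *SITE)
            ref = almanac_solar_elevation(ts, *SITE)
            if ref > 5.0:  # compare away from horizon where refraction differs
                assert mine == pytest.approx(ref, abs=0.2)
            else:
                assert mine == pytest.approx(ref, abs=0.6)

    def test_diel_periodicity_up_to_equation_of_time(self):
        t = pd.Timestamp("2019-07-01 06:00", tz="UTC")
        a = solar_elevation(t, *SITE)
        b = solar_elevation(t + pd.Timedelta(days=1), *SITE)
        assert abs(a - b) < 0.5


def grid_from(vals, lat0=72.724, lon0=-76.231):
    n = len(vals)
    return pd.DataFrame(
        {
            "lat_deg": lat0 + 0.01 * np.arange(n),
            "lon_deg": lon0,
            "sic_pct": vals,
        }
    )


class TestIce:
    def test_uniform_grid(self):
        s = summarize_ice(grid_from([80.0] * 9), *SITE)
        assert (s.mean_pct, s.median_pct, s.variance) == (80.0, 80.0, 0.0)

    def test_even_count_median_midpoint_convention(self):
        s = summarize_ice(grid_from([100.0, 100.0, 0.0, 0.0]), *SITE)
        assert s.median_pct == 50.0

    def test_shore_mask_excludes_cells(self):
        vals = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0]
        mask = [False] * 7 + [True, True]
        s = summarize_ice(grid_from(vals), *SITE, shore_mask=mask)
        assert s.n_cells == 7
        assert s.mean_pct == pytest.approx(np.mean(vals[:7]))
        assert s.median_pct == pytest.approx(np.median(vals[:7]))
        assert s.variance == pytest.approx(np.var(vals[:7]))

    def test_cell_order_invariance(self):
        vals = [10.0, 90.0, 40.0, 70.0, 20.0]
        a = summarize_ice(grid_from(vals), *SITE)
        g = grid_from(vals).sample(frac=1.0, random_state=1)
        b = summarize_ice(g, *SITE)
        assert (a.mean_pct, a.median_pct) == (b.mean_pct, b.median_pct)

    def test_empty_mask_errors(self):
        far = grid_from([50.0], lat0=60.0)
        with pytest.raises(ValueError):
            summarize_ice(far, *SITE)


def effort_day(fraction=1.0, start="2019-07-01"):
    t0 = pd.Timestamp(start, tz="UTC")
    return pd.DataFrame(
        {"t_start": [t0], "t_end": [t0 + pd.Timedelta(days=1)], "fraction": [fraction]}
    )


class TestPresence:
    def test_single_detection_marks_its_hour(self):
        p = bin_presence(
            [pd.Timestamp("2019-07-01 10:07", tz="UTC")], effort_day(), "1h"
        )
        row = p[p["bin_start"] == pd.Timestamp("2019-07-01 10:00", tz="UTC")]
        assert row["present"].item() == 1
        assert p["present"].sum() == 1

    def test_zero_effort_bins_absent_not_zero(self):
        p = bin_presence([], effort_day(), "1h")
        assert len(p) == 24  # only the covered day appears
        assert (p["effort"] > 0).all()

    def test_duty_cycle_effort_fraction(self):
        p = bin_presence([], effort_day(fraction=0.75), "1h")
        assert np.allclose(p["effort"], 0.75)

    def test_multiple_detections_still_binary(self):
        t0 = pd.Timestamp("2019-07-01 10:02", tz="UTC")
        p = bin_presence(
            [t0, t0 + pd.Timedelta(minutes=1), t0 + pd.Timedelta(minutes=2)],
            effort_day(),
            "5min",
        )
        assert p["present"].max() == 1
        assert p["present"].sum() == 1


def minute_presence(mins, start="2019-07-01"):
    t0 = pd.Timestamp(start, tz="UTC")
    idx = pd.date_range(t0, periods=24 * 60, freq="1min")
    s = pd.DataFrame({"bin_start": idx, "present": 0})
    s.loc[s.index.isin(mins), "present"] = 1
    return s


class TestEvents:
    def test_short_gap_merges_into_one_event(self):
        p = minute_presence(list(range(0, 11)) + list(range(20, 31)))
        events, summary = detection_events(p)
        assert summary["n_events"] == 1
        assert events["duration_min"].item() == 31.0

    def test_long_gap_splits_events(self):
        p = minute_presence(list(range(0, 11)) + list(range(40, 51)))
        events, summary = detection_events(p)
        assert summary["n_events"] == 2

    def test_empty_series(self):
        events, summary = detection_events(minute_presence([]))
        assert summary["n_events"] == 0
        assert np.isnan(summary["mean_min"])

    def test_mean_at_least_median_on_skewed_input(self):
        mins = list(range(0, 5)) + list(range(100, 104)) + list(range(300, 800))
        _, summary = detection_events(minute_presence(mins))
        assert summary["mean_min"] >= summary["median_min"]


def make_window(t0, t1, cpa, cpa_km=3.0, valid=True):
    return TransitWindow(
        mmsi=1, t_enter=t0, t_exit=t1, cpa_time=cpa, cpa_range_km=cpa_km,
        loitering=False, valid=valid,
    )


class TestCessation:
    def _fixture(self):
        """Three transits; presence stops exactly when the ship is < 10 km."""
        t0 = pd.Timestamp("2019-10-01", tz="UTC")
        idx = pd.date_range(t0, periods=3 * 240, freq="1min")
        rnv = np.full(len(idx), np.nan)
        present = np.zeros(len(idx), dtype=int)
        windows = []
        for k in range(3):
            a = k * 240
            mid = a + 120
            ramp = np.abs(np.arange(240) - 120) / 120 * 37.0 + 3.0  # 40 -> 3 -> 40 km
            rnv[a : a + 240] = ramp
            present[a : a + 240] = (ramp[:240] >= 10.0).astype(int)
            windows.append(
                make_window(idx[a], idx[a + 239], idx[mid])
            )
        presence = pd.DataFrame({"bin_start": idx, "present": present})
        rnv_min = pd.DataFrame({"bin_start": idx, "rnv_km": rnv})
        return presence, windows, rnv_min

    def test_constructed_truth_fractions(self):
        presence, windows, rnv_min = self._fixture()
        out = cessation_stats(presence, windows, rnv_min)
        frac = dict(zip(out["band_km"], out["fraction"]))
        assert frac == {30.0: 0.0, 20.0: 0.0, 15.0: 0.0, 10.0: 1.0, 5.0: 1.0}

    def test_no_overlapping_windows_gives_empty_cases(self):
        presence, windows, rnv_min = self._fixture()
        presence["present"] = 0
        out = cessation_stats(presence, windows, rnv_min)
        assert (out["n_cases"] == 0).all()

    def test_fractions_monotone_when_cessation_persists(self):
        presence, windows, rnv_min = self._fixture()
        out = cessation_stats(presence, windows, rnv_min)
        assert out.sort_values("band_km", ascending=False)["fraction"].is_monotonic_increasing


class TestModelFrame:
    def _presence(self):
        t0 = pd.Timestamp("2019-07-01", tz="UTC")
        bins = pd.date_range(t0, periods=24, freq="1h")
        return pd.DataFrame(
            {"bin_start": bins, "present": 0, "effort": 1.0}
        )

    def _ice(self):
        return pd.DataFrame(
            {"date": [pd.Timestamp("2019-07-01", tz="UTC")], "median_pct": [42.0]}
        )

    def test_full_day_gives_24_complete_rows(self):
        frame = assemble_model_frame(self._presence(), *SITE, ice_daily=self._ice())
        assert len(frame) == 24
        assert not frame.isna().any().any()

    def test_ice_join_uses_calendar_day_median(self):
        frame = assemble_model_frame(self._presence(), *SITE, ice_daily=self._ice())
        assert (frame["ice_pct"] == 42.0).all()

    def test_missing_ice_coverage_errors(self):
        p = self._presence()
        p.loc[0, "bin_start"] = pd.Timestamp("2019-06-30 23:00", tz="UTC")
        with pytest.raises(ValueError, match="cover"):
            assemble_model_frame(p.sort_values("bin_start"), *SITE, ice_daily=self._ice())

    def test_no_ship_bins_take_sentinel_range(self):
        rnv = pd.DataFrame(
            {
                "bin_start": self._presence()["bin_start"],
                "rnv_km": np.nan,
                "ship_present": False,
            }
        )
        frame = assemble_model_frame(
            self._presence(), *SITE, ice_daily=self._ice(), rnv=rnv
        )
        assert (frame["rnv_km"] == 40.0).all()
        assert (frame["ship_present"] == 0).all()
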