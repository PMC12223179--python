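"""Synthetic audio scenes, vessel tracks, ice series, and presence datasets.

Every downstream stage of the analysis is exercised against data generated
here with known ground truth: Gaussian-envelope echolocation clicks inside
the detector's acceptance envelope (peak frequency 15-90 kHz, duration
30-1200 us, train ICIs 2 ms-0.5 s), low-frequency ship-transit noise rising
and falling symmetrically about the closest point of approach, impostor
impulses (slow sperm-whale-like trains with ICI > 0.5 s, low-frequency
ice cracks), great-circle AIS transit tracks at up to 18 kn with reporting
gaps, a double-logistic seasonal sea-ice concentration curve, and binary
presence series drawn from a logistic model with AR(1)-correlated latent
noise and known coefficients.

All randomness flows from the single integer seed of each call; identical
seed and config give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ais as ais_mod
from . import covariates as cov_mod
from .geemodel import Term, build_design

__all__ = [
    "ClickParams",
    "NarwhalTrainSpec",
    "ImpostorSpec",
    "ShipPassageSpec",
    "SceneConfig",
    "PresenceSimConfig",
    "gen_click_waveform",
    "gen_scene",
    "gen_ais_track",
    "gen_ice_series",
    "gen_presence_dataset",
    "presence_terms",
    "default_beta",
]

SITE_LAT = 72.724
SITE_LON = -76.231

# -10 dB full width of a Gaussian envelope is 2*sqrt(2 ln 10^(0.5)) sigma
_GAUSS_M10DB_WIDTH = 2.0 * np.sqrt(2.0 * np.log(10.0 ** (10.0 / 20.0)))  # ~3.035


@dataclass(frozen=True)
class ClickParams:
    """A synthetic click train: Gaussian-windowed cosine pulses."""

    peak_freq_khz: float = 40.0
    duration_us: float = 200.0
    source_rl_db_pp: float = 130.0
    ici_ms: float = 100.0
    n_clicks: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.peak_freq_khz <= 100:
            raise ValueError("peak_freq_khz must be in (0, 100]")
        if self.duration_us <= 0:
            raise ValueError("duration_us must be positive")
        if self.n_clicks < 1:
            raise ValueError("n_clicks must be >= 1")


def gen_click_waveform(
    params: ClickParams, fs_hz: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render a click train; returns (pressure series in uPa, onset times s).

    Each pulse is cos(2 pi f t) under a Gaussian envelope whose -10 dB width
    equals ``duration_us``; the pulse is rescaled so its measured
    peak-to-peak amplitude matches ``source_rl_db_pp`` exactly.  Onset times
    mark the envelope centre of each pulse, spaced ``ici_ms`` apart (rounded
    to the sample grid).
    """
    if fs_hz < 2.0 * params.peak_freq_khz * 1000.0:
        raise ValueError("fs below Nyquist for the requested peak frequency")
    sigma_s = params.duration_us * 1e-6 / _GAUSS_M10DB_WIDTH
    half = int(np.ceil(4.0 * sigma_s * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    pulse = np.exp(-(t**2) / (2.0 * sigma_s**2)) * np.cos(
        2.0 * np.pi * params.peak_freq_khz * 1000.0 * t
    )
    target_pp = 10.0 ** (params.source_rl_db_pp / 20.0)
    pulse *= target_pp / (pulse.max() - pulse.min())

    ici_samp = int(round(params.ici_ms * 1e-3 * fs_hz))
    n_total = half + (params.n_clicks - 1) * ici_samp + half + 1
    x = np.zeros(n_total)
    onsets = np.empty(params.n_clicks)
    for k in range(params.n_clicks):
        c = half + k * ici_samp
        x[c - half : c + half + 1] += pulse
        onsets[k] = c / fs_hz
    return x, onsets


@dataclass(frozen=True)
class NarwhalTrainSpec:
    start_s: float
    params: ClickParams = ClickParams(n_clicks=12)


@dataclass(frozen=True)
class ImpostorSpec:
    """Non-narwhal impulse source: sperm-whale-like (slow ICI) or ice crack."""

    kind: str  # "sperm_whale_like" | "ice"
    start_s: float
    params: ClickParams = ClickParams(
        peak_freq_khz=18.0, duration_us=400.0, ici_ms=800.0, n_clicks=8,
        source_rl_db_pp=135.0,
    )


@dataclass(frozen=True)
class ShipPassageSpec:
    """Low-frequency transit noise with level symmetric about CPA."""

    cpa_time_s: float
    cpa_range_km: float = 1.0
    speed_kn: float = 14.0
    level_at_cpa_db: float = 110.0  # broadband RMS re 1 uPa
    band_hz: tuple[float, float] = (20.0, 1000.0)


@dataclass(frozen=True)
class SceneConfig:
    duration_s: float = 30.0
    fs_hz: int = 200_000
    noise_floor_db: float = 85.0  # broadband RMS re 1 uPa
    trains: tuple[NarwhalTrainSpec, ...] = ()
    impostors: tuple[ImpostorSpec, ...] = ()
    ship: ShipPassageSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("scene duration must be positive")


def _ship_noise(cfg: SceneConfig, spec: ShipPassageSpec, rng) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    n = int(cfg.duration_s * cfg.fs_hz)
    sos = butter(4, spec.band_hz, btype="bandpass", fs=cfg.fs_hz, output="sos")
    noise = sosfiltfilt(sos, rng.standard_normal(n))
    noise /= np.std(noise)
    t = np.arange(n) / cfg.fs_hz
    v_mps = spec.speed_kn * 0.514444
    r_km = np.sqrt(spec.cpa_range_km**2 + (v_mps * (t - spec.cpa_time_s) / 1000.0) ** 2)
    # received level falls with 20 log r relative to CPA (symmetric about CPA)
    level_db = spec.level_at_cpa_db - 20.0 * np.log10(r_km / spec.cpa_range_km)
    return noise * 10.0 ** (level_db / 20.0)


def gen_scene(cfg: SceneConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene; returns (pressure series uPa, truth table).

    Truth rows carry (time_s, label, train_id) for every impulse event;
    ship noise contributes no impulse rows (it is a continuous source whose
    CPA time, if any, is recoverable from the config).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.duration_s * cfg.fs_hz)
    x = rng.standard_normal(n) * 10.0 ** (cfg.noise_floor_db / 20.0)

    rows = []
    train_id = 0
    for spec in cfg.trains:
        wav, onsets = gen_click_waveform(spec.params, cfg.fs_hz, seed=cfg.seed)
        i0 = int(spec.start_s * cfg.fs_hz)
        seg = wav[: max(0, n - i0)]
        x[i0 : i0 + len(seg)] += seg
        for o in onsets:
            if spec.start_s + o < cfg.duration_s:
                rows.append(
                    {"time_s": spec.start_s + o, "label": "narwhal", "train_id": train_id}
                )
        train_id += 1
    for spec in cfg.impostors:
        wav, onsets = gen_click_waveform(spec.params, cfg.fs_hz, seed=cfg.seed)
        i0 = int(spec.start_s * cfg.fs_hz)
        seg = wav[: max(0, n - i0)]
        x[i0 : i0 + len(seg)] += seg
        for o in onsets:
            if spec.start_s + o < cfg.duration_s:
                rows.append(
                    {"time_s": spec.start_s + o, "label": spec.kind, "train_id": -1}
                )
    if cfg.ship is not None:
        x += _ship_noise(cfg, cfg.ship, rng)
    truth = pd.DataFrame(rows, columns=["time_s", "label", "train_id"]).sort_values(
        "time_s", ignore_index=True
    )
    return x, truth


# --------------------------------------------------------------------------
# AIS tracks
# --------------------------------------------------------------------------

def gen_ais_track(
    start: tuple[float, float],
    end: tuple[float, float],
    speed_kn: float,
    t_start,
    report_interval_s: float = 60.0,
    dropouts: tuple[tuple[float, float], ...] = (),
    mmsi: int = 200_000_001,
    sog_jitter_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Great-circle transit at constant speed with optional reporting gaps.

    ``dropouts`` are (t0_s, t1_s) intervals, relative to ``t_start``, whose
    reports are removed.  SOG is the configured speed with optional
    multiplicative jitter (kept within a few percent so SOG stays consistent
    with successive positions).
    """
    if speed_kn <= 0:
        raise ValueError("speed_kn must be positive")
    rng = np.random.default_rng(seed)
    lat1, lon1 = np.radians(start)
    lat2, lon2 = np.radians(end)
    # unit vectors for spherical linear interpolation
    def unit(lat, lon):
        return np.array(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        )

    u, v = unit(lat1, lon1), unit(lat2, lon2)
    omega = np.arccos(np.clip(u @ v, -1.0, 1.0))
    dist_km = omega * ais_mod.EARTH_RADIUS_KM
    duration_s = dist_km / (speed_kn * 1.852) * 3600.0
    t_rel = np.arange(0.0, duration_s + report_interval_s / 2, report_interval_s)
    t_rel[-1] = min(t_rel[-1], duration_s)
    frac = t_rel / duration_s
    if omega > 0:
        pts = (
            np.sin((1 - frac)[:, None] * omega) * u + np.sin(frac[:, None] * omega) * v
        ) / np.sin(omega)
    else:
        pts = np.tile(u, (len(frac), 1))
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    keep = np.ones(len(t_rel), dtype=bool)
    for a, b in dropouts:
        keep &= ~((t_rel >= a) & (t_rel <= b))
    sog = speed_kn * (1.0 + sog_jitter_frac * rng.uniform(-1, 1, size=len(t_rel)))
    # course over ground from successive positions (deg true, approximate)
    dlat = np.gradient(lat)
    dlon = np.gradient(lon) * np.cos(np.radians(lat))
    cog = np.degrees(np.arctan2(dlon, dlat)) % 360.0
    t0 = pd.Timestamp(t_start)
    t0 = t0.tz_localize("UTC") if t0.tzinfo is None else t0.tz_convert("UTC")
    ts = t0 + pd.to_timedelta(t_rel, unit="s")
    df = pd.DataFrame(
        {
            "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "mmsi": mmsi,
            "lat_deg": lat,
            "lon_deg": lon,
            "sog_kn": sog,
            "cog_deg": cog,
        }
    )[keep.tolist()].reset_index(drop=True)
    df["timestamp"] = pd.to_datetime(
        df["timestamp_iso8601"], format="%Y-%m-%dT%H:%M:%SZ", utc=True
    )
    return df


# --------------------------------------------------------------------------
# sea ice
# --------------------------------------------------------------------------

def gen_ice_series(
    year: int = 2019,
    breakup_doy: float = 195.0,
    freeze_doy: float = 290.0,
    k_breakup: float = 0.35,
    k_freeze: float = 0.30,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily sea-ice concentration: double-logistic seasonal curve, [0, 100].

    Near-complete cover in deep winter, open water between breakup and
    freeze-up, logistic transitions with midpoints at the configured days of
    year.  Gaussian noise (sd in percent) is added then clipped.
    """
    if not breakup_doy < freeze_doy:
        raise ValueError("breakup must precede freeze-up within the year")
    rng = np.random.default_rng(seed)
    doy = np.arange(1, 367 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 366)
    sic = 100.0 * (
        1.0 / (1.0 + np.exp(k_breakup * (doy - breakup_doy)))
        + 1.0 / (1.0 + np.exp(-k_freeze * (doy - freeze_doy)))
    )
    if noise_sd > 0:
        sic = sic + rng.normal(0.0, noise_sd, size=len(doy))
    sic = np.clip(sic, 0.0, 100.0)
    dates = pd.to_datetime(f"{year}-01-01", utc=True) + pd.to_timedelta(doy - 1, unit="D")
    return pd.DataFrame({"date": dates, "median_pct": sic})


# --------------------------------------------------------------------------
# presence datasets
# --------------------------------------------------------------------------

def presence_terms() -> list[Term]:
    """The design used by the presence simulator and its recovery fits."""
    return [
        Term("solar", "solar_deg", kind="bspline", df=3, bounds=(-45.0, 45.0)),
        Term("ice", "ice_pct", kind="bspline", df=3, bounds=(0.0, 100.0)),
        Term("ship_present", "ship_present", kind="linear"),
        Term("rnv", "rnv_km", kind="interaction", df=3, bounds=(0.0, 40.0),
             with_var="ship_present"),
    ]


def default_beta() -> dict[str, float]:
    """True coefficients of the generating logistic model (logit scale).

    Ship presence depresses presence strongly at close range; the proximity
    spline recovers the effect toward zero at the 40 km analysis radius
    (the spline columns vanish at 0 km and reach the ship-presence offset's
    negation at the far boundary).
    """
    return {
        "Intercept": -0.5,
        "bs(solar_deg)[0]": -1.0,
        "bs(solar_deg)[1]": 0.6,
        "bs(solar_deg)[2]": -0.8,
        "bs(ice_pct)[0]": 0.5,
        "bs(ice_pct)[1]": -0.5,
        "bs(ice_pct)[2]": -1.5,
        "ship_present": -2.5,
        "ship_present:bs(rnv_km)[0]": 1.0,
        "ship_present:bs(rnv_km)[1]": 2.0,
        "ship_present:bs(rnv_km)[2]": 2.5,
    }


def write_season_fixture(
    out_dir,
    seed: int = 0,
    n_files: int = 36,
    file_s: float = 8.0,
    start: str = "2019-06-01",
    span_days: int = 150,
    p_narwhal: float = 0.6,
    ship_transits: int = 6,
) -> dict:
    """Materialise a small synthetic season on disk for pipeline runs.

    Writes sparse timestamped WAV snapshots (a narwhal train in a random
    subset), a daily ice CSV, an AIS CSV with a few transits past the site,
    and a pipeline YAML config.  Returns the paths.  File coverage stands in
    for recording effort; the snapshots sample the season rather than
    covering it.
    """
    import yaml
    from scipy.io import wavfile

    from .clickdet import CalibrationSpec, pressure_to_counts

    out_dir = Path(out_dir)
    audio_dir = out_dir / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cal = CalibrationSpec()
    t0 = pd.Timestamp(start, tz="UTC")

    offsets = np.sort(rng.uniform(0, span_days * 86400.0, size=n_files))
    for k, off in enumerate(offsets):
        ts = (t0 + pd.Timedelta(seconds=float(off))).floor("s")
        has_narwhal = rng.uniform() < p_narwhal
        # a foraging-bout-length train: enough clicks to survive the
        # 50-detection minimum cluster size downstream
        train = NarwhalTrainSpec(
            start_s=float(rng.uniform(0.3, 1.0)),
            params=ClickParams(n_clicks=64, ici_ms=100.0),
        )
        cfg = SceneConfig(
            duration_s=file_s,
            trains=(train,) if has_narwhal else (),
            seed=int(rng.integers(2**31)),
        )
        audio, _ = gen_scene(cfg)
        counts = np.round(pressure_to_counts(audio, cal)).astype(np.int16)
        wavfile.write(audio_dir / (ts.strftime("%Y%m%dT%H%M%S") + ".wav"), cfg.fs_hz, counts)

    years = sorted({t0.year, (t0 + pd.Timedelta(days=span_days)).year})
    ice = pd.concat(
        [gen_ice_series(year=y, noise_sd=4.0, seed=seed + 31 + i) for i, y in enumerate(years)],
        ignore_index=True,
    )
    ice_csv = out_dir / "ice_daily.csv"
    ice.assign(date=ice["date"].dt.strftime("%Y-%m-%d")).to_csv(ice_csv, index=False)

    tracks = []
    for k in range(ship_transits):
        cpa_km = rng.uniform(1.0, 25.0)
        dlat = cpa_km / 111.19
        half_deg = 60.0 / (111.19 * np.cos(np.radians(SITE_LAT)))
        tracks.append(
            gen_ais_track(
                (SITE_LAT + dlat, SITE_LON - half_deg),
                (SITE_LAT + dlat, SITE_LON + half_deg),
                speed_kn=float(rng.uniform(8, 18)),
                t_start=t0 + pd.Timedelta(seconds=float(rng.uniform(0, span_days * 86400.0))),
                mmsi=300_000_001 + k,
                seed=int(rng.integers(2**31)),
            )
        )
    ais_csv = out_dir / "ais.csv"
    pd.concat(tracks, ignore_index=True).drop(columns="timestamp").to_csv(
        ais_csv, index=False
    )

    config = {
        "site": {"lat_deg": SITE_LAT, "lon_deg": SITE_LON},
        "paths": {
            "audio_dir": "audio",
            "ais_csv": "ais.csv",
            "ice_csv": "ice_daily.csv",
            "out_dir": "artifacts",
        },
        "period": {
            "start": str(t0.date()),
            "end": str((t0 + pd.Timedelta(days=span_days)).date()),
        },
        "seed": seed,
        "n_boot": 200,
    }
    cfg_path = out_dir / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return {
        "audio_dir": audio_dir,
        "ice_csv": ice_csv,
        "ais_csv": ais_csv,
        "config": cfg_path,
    }


@dataclass(frozen=True)
class PresenceSimConfig:
    n_bins: int = 10_000
    beta: dict = field(default_factory=default_beta)
    ar_rho: float = 0.5
    latent_sd: float = 0.5
    seed: int = 0
    start: str = "2019-09-15"
    bin_s: float = 300.0
    ships_per_day: float = 2.5
    ice_noise_sd: float = 6.0  # day-to-day SIC variability, percent
    cluster_len: int = 288  # one day of 5-min bins
    site_lat: float = SITE_LAT
    site_lon: float = SITE_LON

    def __post_init__(self) -> None:
        if not 0 <= self.ar_rho < 1:
            raise ValueError("ar_rho must be in [0, 1)")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")


def _sim_rnv(cfg: PresenceSimConfig, bins: pd.DatetimeIndex, rng) -> pd.DataFrame:
    """Episodic ship transits -> 5-min RNV series via the AIS machinery."""
    n_days = cfg.n_bins * cfg.bin_s / 86400.0
    n_ships = rng.poisson(cfg.ships_per_day * n_days)
    tracks: dict[int, pd.DataFrame] = {}
    t0 = bins[0]
    horizon_s = cfg.n_bins * cfg.bin_s
    for k in range(n_ships):
        start_s = rng.uniform(0.0, horizon_s)
        speed = rng.uniform(8.0, 18.0)
        # straight pass through a CPA offset east-west of the site
        cpa_km = rng.uniform(0.5, 20.0)
        dlat = cpa_km / 111.19
        half_deg = 60.0 / (111.19 * np.cos(np.radians(cfg.site_lat)))  # ~60 km legs
        raw = gen_ais_track(
            (cfg.site_lat + dlat, cfg.site_lon - half_deg),
            (cfg.site_lat + dlat, cfg.site_lon + half_deg),
            speed_kn=speed,
            t_start=t0 + pd.Timedelta(seconds=start_s),
            report_interval_s=60.0,
            mmsi=200_000_001 + k,
            seed=int(rng.integers(2**31)),
        )
        tracks[200_000_001 + k] = ais_mod.interpolate_track(raw)
    if not tracks:
        return pd.DataFrame(
            {"bin_start": bins, "rnv_km": np.nan, "ship_present": False}
        )
    _, five = ais_mod.rnv_series(
        tracks, cfg.site_lat, cfg.site_lon, bins[0], bins[-1] + pd.Timedelta(seconds=cfg.bin_s)
    )
    return five


def gen_presence_dataset(cfg: PresenceSimConfig):
    """Simulate a presence model frame with known coefficients.

    Returns ``(frame, beta, design_info)`` where frame holds bin_start,
    present, solar_deg, ice_pct, ship_present, rnv_km, day_of_year, year and
    cluster_id.  The response is Bernoulli(expit(X beta + z)) with z a
    stationary AR(1) latent noise of sd ``latent_sd`` and lag-1 correlation
    ``ar_rho``; the returned design info enables exact-model recovery fits.
    """
    rng = np.random.default_rng(cfg.seed)
    bins = pd.date_range(
        pd.Timestamp(cfg.start, tz="UTC"), periods=cfg.n_bins,
        freq=pd.Timedelta(seconds=cfg.bin_s),
    )
    frame = pd.DataFrame({"bin_start": bins})
    frame["day_of_year"] = bins.dayofyear
    frame["year"] = bins.year.astype(str)
    frame["solar_deg"] = cov_mod.solar_elevation(bins, cfg.site_lat, cfg.site_lon)

    year0 = int(bins[0].year)
    ice_parts = [
        gen_ice_series(year=y, noise_sd=cfg.ice_noise_sd, seed=cfg.seed + 17 + (y - year0))
        for y in range(year0, int(bins[-1].year) + 1)
    ]
    ice = pd.concat(ice_parts, ignore_index=True)
    frame["date"] = bins.normalize()
    frame = frame.merge(
        ice.rename(columns={"median_pct": "ice_pct"}), left_on="date", right_on="date",
        how="left",
    ).drop(columns="date")

    rnv = _sim_rnv(cfg, bins, rng)
    frame = frame.merge(rnv, on="bin_start", how="left")
    frame["ship_present"] = frame["ship_present"].fillna(False).astype(int)
    frame["rnv_km"] = frame["rnv_km"].where(frame["ship_present"] == 1, 40.0)
    frame["rnv_km"] = frame["rnv_km"].clip(0.0, 40.0)

    X, info = build_design(frame, presence_terms())
    beta_vec = np.array([cfg.beta.get(c, 0.0) for c in info.colnames])
    eta = X @ beta_vec

    z = np.empty(cfg.n_bins)
    eps = rng.standard_normal(cfg.n_bins)
    z[0] = eps[0] * cfg.latent_sd
    innov_sd = cfg.latent_sd * np.sqrt(1.0 - cfg.ar_rho**2)
    for i in range(1, cfg.n_bins):
        z[i] = cfg.ar_rho * z[i - 1] + innov_sd * eps[i]

    p = 1.0 / (1.0 + np.exp(-(eta + z)))
    frame["present"] = (rng.uniform(size=cfg.n_bins) < p).astype(int)
    frame["cluster_id"] = np.arange(cfg.n_bins) // cfg.cluster_len
    frame["latent"] = z
    frame["eta_true"] = eta
    return frame, dict(zip(info.colnames, beta_vec)), info
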