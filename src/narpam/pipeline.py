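"""End-to-end orchestration: audio -> detections -> covariates -> GEE models.

Two entry points mirror the two phases of the analysis: ``run_annual`` fits
the hourly-resolution temporal (day-of-year spline + year) and
environmental (ice + solar) presence models over May 1 - Nov 30, and
``run_ship_response`` fits the 5-min ship-proximity model (with the
ship_present x rnv spline interaction) for July or October, emitting
cessation fractions per distance band.

Audio arrives as a directory of 16-bit PCM WAV snapshots named by their
UTC start time (``YYYYmmddTHHMMSS.wav``); each file's coverage counts as
recording effort.  Detection output is cached keyed by the content hash of
the audio plus the detector configuration, so the expensive stage reruns
only when either changes.  Every artifact embeds the run's config hash and
seed in a comment header, and identical seed + config reproduce artifacts
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ais as ais_mod
from . import clickdet, covariates, trains
from .geemodel import (
    Term,
    acf_cluster_size,
    backward_select,
    bootstrap_curves,
    build_design,
    fit_gee,
    select_corstr,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_annual", "run_ship_response"]

_WAV_NAME = re.compile(r"^(\d{8}T\d{6})\.wav$")


class RunConfig:
    """Validated run configuration (see ``from_yaml``)."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        self.raw = raw
        base = Path(base_dir) if base_dir else Path(".")
        paths = raw.get("paths", {})
        self.audio_dir = base / paths["audio_dir"]
        self.ais_csv = base / paths["ais_csv"] if "ais_csv" in paths else None
        self.ice_csv = base / paths["ice_csv"]
        self.out_dir = base / paths.get("out_dir", "artifacts")
        self.site_lat = float(raw["site"]["lat_deg"])
        self.site_lon = float(raw["site"]["lon_deg"])
        self.period = (
            pd.Timestamp(raw["period"]["start"], tz="UTC"),
            pd.Timestamp(raw["period"]["end"], tz="UTC"),
        )
        self.seed = int(raw.get("seed", 0))
        self.cal = clickdet.CalibrationSpec(**raw.get("calibration", {}))
        self.det_cfg = clickdet.DetectorConfig(**raw.get("detector", {}))
        self.n_boot = int(raw.get("n_boot", 1000))
        for p, what in [(self.audio_dir, "audio_dir"), (self.ice_csv, "ice_csv")] + (
            [(self.ais_csv, "ais_csv")] if self.ais_csv else []
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {what} does not exist: {p}")
        if not self.period[0] < self.period[1]:
            raise ValueError("analysis period is empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw, base_dir=path.parent)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_artifact(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _detect_file(path: Path, cfg: RunConfig):
    """Run the full detection chain on one WAV; returns finalized times (s)."""
    fs, counts = clickdet.read_wav_counts(path)
    pressure = clickdet.counts_to_pressure(counts, cfg.cal)
    dets = clickdet.detect_impulses(
        pressure, fs, cfg.det_cfg, raw_counts=counts, cal=cfg.cal
    )
    kept, _ = clickdet.filter_impulses(dets, cfg.det_cfg)
    trs = trains.build_click_trains(kept)
    clusters = trains.cluster_detections(kept)
    final_idx, _ = trains.finalize_narwhal_detections(kept, clusters, trs)
    return [kept[i].time_s for i in final_idx]


def _detection_stage(cfg: RunConfig):
    """Detections + effort over the audio directory, with content-hash cache."""
    cache_dir = cfg.out_dir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    det_times, effort_rows = [], []
    det_key = json.dumps(
        [cfg.det_cfg.__dict__, cfg.cal.__dict__], sort_keys=True, default=str
    )
    for wav in sorted(Path(cfg.audio_dir).glob("*.wav")):
        m = _WAV_NAME.match(wav.name)
        if not m:
            log.warning("skipping unrecognized audio file name %s", wav.name)
            continue
        t0 = pd.Timestamp(m.group(1), tz="UTC")
        h = hashlib.sha256(wav.read_bytes() + det_key.encode()).hexdigest()[:16]
        cache_file = cache_dir / f"det_{h}.json"
        if cache_file.exists():
            payload = json.loads(cache_file.read_text())
        else:
            fs, counts = clickdet.read_wav_counts(wav)
            times = _detect_file(wav, cfg)
            payload = {"times_s": times, "duration_s": len(counts) / fs}
            cache_file.write_text(json.dumps(payload))
        det_times.extend(t0 + pd.to_timedelta(payload["times_s"], unit="s"))
        effort_rows.append(
            {
                "t_start": t0,
                "t_end": t0 + pd.Timedelta(seconds=payload["duration_s"]),
                "fraction": 1.0,
            }
        )
    if not effort_rows:
        raise RuntimeError("detection stage: no audio files found")
    return pd.DatetimeIndex(det_times), pd.DataFrame(effort_rows)


def _load_ice(cfg: RunConfig) -> pd.DataFrame:
    ice = pd.read_csv(cfg.ice_csv)
    if "median_pct" not in ice.columns or "date" not in ice.columns:
        raise ValueError("ice csv must carry columns date, median_pct")
    return ice


def _fit_and_dump(frame, terms, tag, cfg: RunConfig, curve_specs=()):
    """Select correlation structure, fit, and write coef/ANOVA/QIC/curves."""
    chosen, fit, qics = select_corstr(frame, terms)
    coefs = pd.DataFrame(
        {
            "coef": fit.coef,
            "se": np.sqrt(np.diag(fit.robust_cov.to_numpy())),
        }
    ).reset_index(names="name")
    _write_artifact(coefs, cfg.out_dir / f"model_{tag}_coefs.csv", cfg)
    _write_artifact(fit.wald, cfg.out_dir / f"model_{tag}_anova.csv", cfg)
    _write_artifact(
        pd.DataFrame(
            {"corstr": list(qics), "qic": [qics[k] for k in qics],
             "chosen": [k == chosen for k in qics],
             "marginal_r2": fit.marginal_r2}
        ),
        cfg.out_dir / f"model_{tag}_qic.csv",
        cfg,
    )
    for var, grid, reference in curve_specs:
        curves = bootstrap_curves(
            fit, var, grid, reference, n_boot=cfg.n_boot, seed=cfg.seed
        )
        _write_artifact(curves, cfg.out_dir / f"curves_{tag}_{var}.csv", cfg)
    return fit


def run_annual(cfg: RunConfig) -> dict:
    """Hourly-resolution annual analysis: temporal and environmental models."""
    det_times, effort = _detection_stage(cfg)
    presence = covariates.bin_presence(det_times, effort, "1h")
    frame = covariates.assemble_model_frame(
        presence, cfg.site_lat, cfg.site_lon, ice_daily=_load_ice(cfg),
        period=cfg.period,
    )
    if frame.empty:
        raise RuntimeError("annual stage: no effort bins inside the period")
    L, cluster_ids = acf_cluster_size(frame["present"].to_numpy())
    frame["cluster_id"] = cluster_ids
    _write_artifact(
        frame.drop(columns=[c for c in ("snippet",) if c in frame]),
        cfg.out_dir / "presence_hourly.csv",
        cfg,
    )
    sol_med = float(frame["solar_deg"].median())
    temporal = _fit_and_dump(
        frame,
        [
            Term("day_of_year", "day_of_year", kind="cyclic", df=4),
            Term("year", "year", kind="categorical"),
        ],
        "temporal",
        cfg,
        curve_specs=[("day_of_year", np.linspace(1, 366, 60), {})],
    )
    environmental = _fit_and_dump(
        frame,
        [
            Term("ice", "ice_pct", kind="bspline", df=3, bounds=(0.0, 100.0)),
            Term("solar", "solar_deg", kind="bspline", df=3, bounds=(-45.0, 45.0)),
        ],
        "environmental",
        cfg,
        curve_specs=[
            ("ice_pct", np.linspace(0, 100, 60), {"solar_deg": sol_med}),
            ("solar_deg", np.linspace(-45, 45, 60), {"ice_pct": 0.0}),
        ],
    )
    return {
        "frame": frame,
        "cluster_bins": L,
        "temporal": temporal,
        "environmental": environmental,
    }


MONTHS = {"July": 7, "October": 10}


def run_ship_response(cfg: RunConfig, month: str = "October") -> dict:
    """5-min-resolution ship-proximity analysis for July or October."""
    if month not in MONTHS:
        raise ValueError("month must be July or October")
    if cfg.ais_csv is None:
        raise FileNotFoundError("ship-response analysis requires paths.ais_csv")
    det_times, effort = _detection_stage(cfg)
    presence5 = covariates.bin_presence(det_times, effort, "5min")
    presence1 = covariates.bin_presence(det_times, effort, "1min")

    ais_df = ais_mod.read_ais_csv(cfg.ais_csv)
    tracks = {
        int(mmsi): ais_mod.interpolate_track(grp)
        for mmsi, grp in ais_df.groupby("mmsi")
    }
    windows = []
    for mmsi, track in tracks.items():
        windows.extend(
            ais_mod.build_transit_windows(track, cfg.site_lat, cfg.site_lon, mmsi)
        )
    rnv1, rnv5 = ais_mod.rnv_series(
        tracks, cfg.site_lat, cfg.site_lon, cfg.period[0], cfg.period[1]
    )
    _write_artifact(ais_mod.windows_to_frame(windows), cfg.out_dir / "transit_windows.csv", cfg)
    _write_artifact(rnv5, cfg.out_dir / "rnv_5min.csv", cfg)

    cess = covariates.cessation_stats(presence1, windows, rnv1)
    _write_artifact(cess, cfg.out_dir / f"cessation_{month}.csv", cfg)

    frame = covariates.assemble_model_frame(
        presence5, cfg.site_lat, cfg.site_lon, ice_daily=_load_ice(cfg),
        rnv=rnv5, period=cfg.period,
    )
    frame = frame[frame["bin_start"].dt.month == MONTHS[month]].reset_index(drop=True)
    if frame.empty:
        raise RuntimeError(f"ship-response stage: no effort bins in {month}")
    L, cluster_ids = acf_cluster_size(frame["present"].to_numpy())
    frame["cluster_id"] = cluster_ids
    _write_artifact(frame, cfg.out_dir / f"frame_5min_{month}.csv", cfg)

    terms = [
        Term("ice", "ice_pct", kind="bspline", df=3, bounds=(0.0, 100.0)),
        Term("solar", "solar_deg", kind="bspline", df=3, bounds=(-45.0, 45.0)),
    ]
    if frame["ship_present"].sum() > 0:
        terms += [
            Term("ship_present", "ship_present", kind="linear"),
            Term("rnv", "rnv_km", kind="interaction", df=3, bounds=(0.0, 40.0),
                 with_var="ship_present"),
        ]
    else:
        log.warning("%s has zero ship overlap; fitting without the interaction", month)
    fit = _fit_and_dump(
        frame,
        terms,
        f"ship_{month}",
        cfg,
        curve_specs=[
            (
                "rnv_km",
                np.linspace(0.0, 40.0, 41),
                {"ship_present": 1, "ice_pct": 0.0,
                 "solar_deg": float(frame["solar_deg"].median())},
            )
        ]
        if frame["ship_present"].sum() > 0
        else [],
    )
    return {"frame": frame, "fit": fit, "cessation": cess, "cluster_bins": L,
            "windows": windows}
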