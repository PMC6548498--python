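"""End-to-end pipeline: from trajectory tables to per-flock summaries.

``run_pipeline`` strings the stages together for a set of flock
recordings and emits a per-flock summary table in the layout of the
study's flock-parameter table: median (and 10th-90th percentile)
nearest-neighbor distance in metres and wingspans, the 10-NN power
exponent, ground speed, airspeed, wind speed and relative direction,
climb rate and turn rate — all extracted at one-wingbeat intervals —
plus modal neighbor position and the in-slice fraction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import neighbors, structure, wind
from .flock_io import FlockRecording, compute_kinematics, wingbeat_sample_frames

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "flock_summary_row"]


@dataclass
class PipelineConfig:
    """Analysis parameters.  Defaults follow the study conventions:
    0.25-wingspan KDE bandwidth, ±1-wingspan elevation slice,
    10-degree/500-point wind bins, 128-point FFT, 20-frame phase
    overlap, 0.7-1.5/2-wingspan aerodynamic-neighbor zone."""

    sampling: str = "wingbeat"  # or "every_frame"
    kde_bandwidth_ws: float = 0.25
    kde_grid_ws: float = 0.05
    elevation_slice_ws: float = 1.0
    wind_bin_deg: float = 10.0
    wind_min_bin_n: int = 500
    fft_len: int = 128
    fft_band_hz: tuple = (2.0, 15.0)
    min_phase_overlap: int = 20
    nn_power_k: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _pct_fmt(values, lo=10, hi=90):
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan, np.nan
    return float(np.median(v)), float(np.percentile(v, lo)), float(np.percentile(v, hi))


def flock_summary_row(flock: FlockRecording, config: PipelineConfig | None = None) -> dict:
    """Compute one summary row (plus intermediate products) for a flock.

    Returns a dict with the summary scalars and the keys ``kinematics``,
    ``offsets``, ``wind`` and ``sample_frames`` holding the intermediate
    products for downstream stages.
    """
    config = config or PipelineConfig()
    kin = compute_kinematics(flock)
    sample = wingbeat_sample_frames(flock) if config.sampling == "wingbeat" else None

    try:
        west = wind.estimate_wind(kin, sample, bin_width_deg=config.wind_bin_deg,
                                  min_bin_n=config.wind_min_bin_n)
        wind_vec = (west.wind_east, west.wind_north)
        wind_speed = west.speed
    except wind.WindEstimationError as exc:
        logger.warning("%s: %s", flock.flock_id, exc)
        west = None
        if flock.station_wind is not None:
            spd, met = flock.station_wind
            to_math = np.radians((270.0 - met) % 360.0)
            wind_vec = (spd * np.cos(to_math), spd * np.sin(to_math))
            wind_speed = spd
        else:
            wind_vec, wind_speed = (0.0, 0.0), np.nan

    kin = wind.airspeed(kin, wind_vec)
    offsets = neighbors.nearest_neighbor_offsets(flock, kin, sample)
    _in, _out, frac = neighbors.partition_by_elevation(offsets, config.elevation_slice_ws)

    sampled_kin = kin
    if sample is not None:
        parts = [kin[(kin["bird_id"] == b) & (kin["frame"].isin(f))]
                 for b, f in sample.items()]
        sampled_kin = pd.concat(parts, ignore_index=True)

    row = {"flock_id": flock.flock_id, "n_birds": flock.n_birds,
           "n_frames": flock.n_frames}
    for label, series in (
        ("nnd_m", offsets["distance3d"]),
        ("nnd_ws", offsets["distance3d_ws"]),
        ("ground_speed", sampled_kin["ground_speed"]),
        ("airspeed", sampled_kin["airspeed"]),
        ("z_speed", sampled_kin["z_speed"]),
        ("turn_rate", sampled_kin["turn_rate"].abs()),
    ):
        med, lo, hi = _pct_fmt(series)
        row[f"{label}_median"] = med
        row[f"{label}_p10"] = lo
        row[f"{label}_p90"] = hi

    row["wind_speed"] = wind_speed
    mean_heading = float(
        np.degrees(np.arctan2(sampled_kin["vy"].mean(), sampled_kin["vx"].mean())) % 360
    )
    row["wind_dir_rel"] = (
        wind.relative_wind_direction(mean_heading, wind_vec)
        if np.isfinite(wind_speed) and wind_speed > 0 else np.nan
    )
    try:
        row["nn_power"] = structure.nn_power_exponent(kin, sample, k=config.nn_power_k)
    except structure.InsufficientDataError:
        row["nn_power"] = np.nan

    try:
        mode = neighbors.modal_position(offsets, bandwidth=config.kde_bandwidth_ws,
                                        grid_res=config.kde_grid_ws)
        row["lateral_mode_ws"] = mode.lateral_mode
        row["fb_mode_ws"] = mode.front_back_mode
        row["alignment_angle_deg"] = mode.alignment_angle
    except neighbors.InsufficientDataError:
        row["lateral_mode_ws"] = row["fb_mode_ws"] = row["alignment_angle_deg"] = np.nan
    row["in_slice_fraction"] = frac

    row["_kinematics"] = kin
    row["_offsets"] = offsets
    row["_wind"] = west
    row["_sample_frames"] = sample
    return row


def run_pipeline(flocks, config: PipelineConfig | None = None,
                 out_dir=None) -> pd.DataFrame:
    """Run the summary pipeline over several flocks.

    Returns the per-flock summary DataFrame (intermediate products are
    dropped).  With ``out_dir`` set, writes ``summary.csv``, one wind
    JSON per flock, and a provenance stamp with the config hash.
    """
    config = config or PipelineConfig()
    rows = []
    for flock in flocks:
        logger.info("pipeline: flock %s (%d birds)", flock.flock_id, flock.n_birds)
        try:
            rows.append(flock_summary_row(flock, config))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at flock {flock.flock_id}: {exc}") from exc

    summary = pd.DataFrame(
        [{k: v for k, v in r.items() if not k.startswith("_")} for r in rows]
    )
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        for r in rows:
            if r["_wind"] is not None:
                r["_wind"].to_json(out / f"wind_{r['flock_id']}.json")
        with open(out / "provenance.json", "w") as f:
            json.dump({"config_hash": config.config_hash(), "seed": config.seed,
                       "config": asdict(config)}, f, indent=1, default=str)
    return summary
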