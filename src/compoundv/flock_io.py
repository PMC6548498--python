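"""Core data model and I/O for 3D flock trajectories.

A :class:`FlockRecording` holds per-bird 3D tracks sampled on a shared
frame clock (default 29.97 Hz) plus species metadata.  Readers accept
long-format trajectory CSVs (one row per bird per frame) and a wide
per-bird layout; headers are sniffed so column order does not matter.
Kinematics (velocity, ground speed, heading, climb rate, turn rate) are
derived by central differences, with short track gaps (up to four
frames, mirroring the tolerance of the upstream tracker) linearly
interpolated first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FRAME_RATE = 29.97
MAX_GAP_FRAMES = 4

__all__ = [
    "SpeciesSpec",
    "BirdTrack",
    "FlockRecording",
    "SPECIES",
    "SchemaError",
    "DataError",
    "read_flock",
    "write_flock",
    "read_species_table",
    "compute_kinematics",
    "wingbeat_sample_frames",
]


class SchemaError(ValueError):
    """A required column is missing or unrecognisable."""


class DataError(ValueError):
    """Input rows violate a structural invariant (e.g. frame order)."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Morphological constants for one species.

    Wingspan in metres, body mass in grams, and an optional cruising
    wingbeat frequency in Hz used when no per-bird measurement exists.
    """

    name: str
    wingspan: float
    body_mass: float
    default_wingbeat_hz: float | None = None

    def __post_init__(self):
        if not self.wingspan > 0:
            raise ValueError("wingspan must be positive")


#: Study species.  Wingbeat defaults are the cruising frequencies implied by
#: the species terms of the wingbeat-frequency model (dowitcher intercept
#: 8.82 Hz, godwit -2.19, avocet -1.91); dunlin wingbeats were not
#: measurable at field recording distances, so no default is set.
SPECIES = {
    "dunlin": SpeciesSpec("dunlin", 0.34, 56.0, None),
    "dowitcher": SpeciesSpec("dowitcher", 0.52, 110.0, 8.82),
    "avocet": SpeciesSpec("avocet", 0.72, 312.0, 6.91),
    "godwit": SpeciesSpec("godwit", 0.78, 370.0, 6.63),
}


@dataclass
class BirdTrack:
    bird_id: str
    species: SpeciesSpec
    frames: np.ndarray  # int, strictly increasing
    positions: np.ndarray  # (n, 3) metres; x,y horizontal, z up

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frames.ndim != 1 or self.positions.shape != (self.frames.size, 3):
            raise DataError(f"track {self.bird_id}: frames/positions shape mismatch")
        d = np.diff(self.frames)
        if np.any(d <= 0):
            raise DataError(f"track {self.bird_id}: frames not strictly increasing")
        if np.any(d > MAX_GAP_FRAMES + 1):
            raise DataError(
                f"track {self.bird_id}: gap longer than {MAX_GAP_FRAMES} frames; "
                "split into separate tracks upstream"
            )
        if not np.all(np.isfinite(self.positions)):
            raise DataError(f"track {self.bird_id}: non-finite positions")

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    def interpolated(self) -> "BirdTrack":
        """Return a copy with interior gaps (<= 4 frames) filled linearly."""
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        if full.size == self.frames.size:
            return self
        pos = np.column_stack(
            [np.interp(full, self.frames, self.positions[:, k]) for k in range(3)]
        )
        return replace(self, frames=full, positions=pos)


@dataclass
class FlockRecording:
    flock_id: str
    tracks: list[BirdTrack] = field(default_factory=list)
    frame_rate: float = DEFAULT_FRAME_RATE
    station_wind: tuple[float, float] | None = None  # (speed m/s, direction deg)

    @property
    def n_birds(self) -> int:
        return len(self.tracks)

    @property
    def frame_range(self) -> tuple[int, int]:
        lo = min(int(t.frames[0]) for t in self.tracks)
        hi = max(int(t.frames[-1]) for t in self.tracks)
        return lo, hi

    @property
    def n_frames(self) -> int:
        lo, hi = self.frame_range
        return hi - lo + 1

    def track(self, bird_id) -> BirdTrack:
        for t in self.tracks:
            if t.bird_id == bird_id:
                return t
        raise KeyError(bird_id)


# ---------------------------------------------------------------------------
# readers / writers

_COLUMN_ALIASES = {
    "bird_id": {"bird_id", "bird", "id", "track_id", "track", "individual"},
    "frame": {"frame", "frame_idx", "t", "time_frame"},
    "x": {"x_m", "x", "xm", "pos_x"},
    "y": {"y_m", "y", "ym", "pos_y"},
    "z": {"z_m", "z", "zm", "pos_z"},
    "species": {"species", "sp", "species_name"},
    "flock_id": {"flock_id", "flock"},
}


def _sniff_columns(columns) -> dict:
    """Map canonical field names to actual column names, case-insensitive."""
    lower = {str(c).strip().lower(): c for c in columns}
    out = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                out[canon] = lower[alias]
                break
    return out


def read_flock(
    source,
    species_map=None,
    flock_id: str | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    default_species: str | SpeciesSpec = "godwit",
    station_wind=None,
) -> FlockRecording:
    """Read a long-format trajectory table into a :class:`FlockRecording`.

    ``source`` may be a path or a DataFrame with columns for bird id,
    frame and x/y/z in metres (header names are sniffed).  ``species_map``
    maps bird ids or species-column labels to :class:`SpeciesSpec`; birds
    not covered fall back to ``default_species``.  Birds with fewer than
    two frames are dropped with a warning.
    """
    df = (
        pd.read_csv(source, float_precision="round_trip")
        if not isinstance(source, pd.DataFrame)
        else source.copy()
    )
    cols = _sniff_columns(df.columns)
    for required in ("bird_id", "frame", "x", "y", "z"):
        if required not in cols:
            raise SchemaError(f"trajectory table lacks a recognisable '{required}' column")

    if isinstance(default_species, str):
        default_species = SPECIES[default_species]
    species_map = species_map or {}

    if flock_id is None:
        if "flock_id" in cols and df[cols["flock_id"]].nunique() == 1:
            flock_id = str(df[cols["flock_id"]].iloc[0])
        else:
            flock_id = "flock"

    tracks = []
    n_dropped = 0
    for bird_id, sub in df.groupby(cols["bird_id"], sort=True):
        if len(sub) < 2:
            n_dropped += 1
            continue
        frames = sub[cols["frame"]].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise DataError(f"bird {bird_id}: non-monotone frame sequence")
        sp = default_species
        if bird_id in species_map:
            sp = species_map[bird_id]
        elif "species" in cols:
            label = str(sub[cols["species"]].iloc[0]).lower()
            sp = species_map.get(label) or SPECIES.get(label, default_species)
        pos = sub[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        tracks.append(BirdTrack(str(bird_id), sp, frames, pos))

    if n_dropped:
        logger.warning("%s: dropped %d birds with < 2 frames", flock_id, n_dropped)
    if not tracks:
        logger.warning("%s: empty trajectory table, 0 tracks", flock_id)
    logger.info("%s: retained %d tracks", flock_id, len(tracks))
    return FlockRecording(flock_id, tracks, frame_rate=frame_rate, station_wind=station_wind)


def read_flock_wide(source, **kwargs) -> FlockRecording:
    """Read a wide per-bird layout (columns like ``<bird>_x, <bird>_y,
    <bird>_z`` plus a ``frame`` column) by reshaping to long form."""
    df = (
        pd.read_csv(source, float_precision="round_trip")
        if not isinstance(source, pd.DataFrame)
        else source.copy()
    )
    frame_col = _sniff_columns(df.columns).get("frame")
    if frame_col is None:
        raise SchemaError("wide trajectory table lacks a 'frame' column")
    records = []
    for col in df.columns:
        name = str(col)
        if name == frame_col or "_" not in name:
            continue
        bird, axis = name.rsplit("_", 1)
        if axis.lower() in ("x", "y", "z"):
            records.append((bird, axis.lower(), col))
    birds = sorted({b for b, _, _ in records})
    rows = []
    for bird in birds:
        axes = {a: c for b, a, c in records if b == bird}
        if set(axes) != {"x", "y", "z"}:
            raise SchemaError(f"bird {bird}: incomplete x/y/z columns in wide table")
        sub = pd.DataFrame(
            {
                "bird_id": bird,
                "frame": df[frame_col],
                "x_m": df[axes["x"]],
                "y_m": df[axes["y"]],
                "z_m": df[axes["z"]],
            }
        ).dropna()
        rows.append(sub)
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["bird_id", "frame", "x_m", "y_m", "z_m"]
    )
    return read_flock(long, **kwargs)


def write_flock(flock: FlockRecording, path) -> None:
    """Write the long-format trajectory CSV (full float precision)."""
    rows = []
    for t in flock.tracks:
        rows.append(
            pd.DataFrame(
                {
                    "flock_id": flock.flock_id,
                    "bird_id": t.bird_id,
                    "frame": t.frames,
                    "x_m": t.positions[:, 0],
                    "y_m": t.positions[:, 1],
                    "z_m": t.positions[:, 2],
                    "species": t.species.name,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["flock_id", "bird_id", "frame", "x_m", "y_m", "z_m", "species"]
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_species_table(source) -> dict:
    """Read a species CSV (name, wingspan_m, mass_g, default_wingbeat_hz)."""
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    out = {}
    for _, row in df.iterrows():
        hz = row.get("default_wingbeat_hz")
        hz = None if hz is None or (isinstance(hz, float) and np.isnan(hz)) else float(hz)
        out[str(row["name"]).lower()] = SpeciesSpec(
            str(row["name"]).lower(), float(row["wingspan_m"]), float(row["mass_g"]), hz
        )
    return out


# ---------------------------------------------------------------------------
# kinematics


def compute_kinematics(flock: FlockRecording) -> pd.DataFrame:
    """Per-bird per-frame kinematics derived from positions.

    Velocities use central differences on interior frames and one-sided
    differences at track ends (``numpy.gradient``); gaps of up to four
    frames are linearly interpolated first.  Returns a DataFrame with
    columns ``bird_id, frame, x, y, z, vx, vy, vz, ground_speed,
    z_speed, heading_deg, turn_rate`` (heading in [0, 360), measured
    anticlockwise from the +x axis; turn rate in deg/s).  Tracks with
    fewer than three frames are excluded with a log message.  An
    ``airspeed`` column is appended later by the wind module.
    """
    if flock.frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    dt = 1.0 / flock.frame_rate
    frames_out = []
    for track in flock.tracks:
        ti = track.interpolated()
        if ti.n_frames < 3:
            logger.info("%s: track %s has < 3 frames, excluded from kinematics",
                        flock.flock_id, track.bird_id)
            continue
        vel = np.gradient(ti.positions, dt, axis=0)
        ground_speed = np.hypot(vel[:, 0], vel[:, 1])
        heading = np.degrees(np.arctan2(vel[:, 1], vel[:, 0])) % 360.0
        unwrapped = np.unwrap(np.radians(heading))
        turn_rate = np.degrees(np.gradient(unwrapped, dt))
        frames_out.append(
            pd.DataFrame(
                {
                    "bird_id": ti.bird_id,
                    "frame": ti.frames,
                    "x": ti.positions[:, 0],
                    "y": ti.positions[:, 1],
                    "z": ti.positions[:, 2],
                    "vx": vel[:, 0],
                    "vy": vel[:, 1],
                    "vz": vel[:, 2],
                    "ground_speed": ground_speed,
                    "z_speed": vel[:, 2],
                    "heading_deg": heading,
                    "turn_rate": turn_rate,
                    "species": ti.species.name,
                    "wingspan": ti.species.wingspan,
                }
            )
        )
    if not frames_out:
        return pd.DataFrame(
            columns=["bird_id", "frame", "x", "y", "z", "vx", "vy", "vz",
                     "ground_speed", "z_speed", "heading_deg", "turn_rate",
                     "species", "wingspan"]
        )
    return pd.concat(frames_out, ignore_index=True)


def wingbeat_sample_frames(flock: FlockRecording, wingbeat_hz_per_bird=None) -> dict:
    """Frame subsets spaced one wingbeat period apart, per bird.

    ``wingbeat_hz_per_bird`` maps bird id to a measured frequency; birds
    not covered use their species default.  The spacing is
    ``round(frame_rate / hz)`` frames, floored at one frame (with a
    warning when the requested frequency is at or above the frame rate).
    Returns a dict bird_id -> array of frame indices.
    """
    wingbeat_hz_per_bird = wingbeat_hz_per_bird or {}
    out = {}
    for track in flock.tracks:
        hz = wingbeat_hz_per_bird.get(track.bird_id, track.species.default_wingbeat_hz)
        if hz is None:
            hz = 6.0  # conservative shorebird cruising default
        if hz <= 0:
            raise ValueError(f"bird {track.bird_id}: non-positive wingbeat frequency")
        spacing = int(round(flock.frame_rate / hz))
        if spacing < 1:
            logger.warning(
                "bird %s: wingbeat %.2f Hz at or above frame rate; sampling every frame",
                track.bird_id, hz,
            )
            spacing = 1
        ti = track.interpolated()
        out[track.bird_id] = ti.frames[::spacing]
    return out
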