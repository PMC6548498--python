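"""Synthetic flock generators with stored ground truth.

These generators build kinematic scaffolds — not behavioural
simulations — that reproduce the structural features the analysis
pipeline is designed to measure: cluster flocks obeying a one-wingspan
lateral alignment rule with variable trailing distance and elevations
concentrated within about a wingspan of the leader; a constant wind
vector added to a shared air velocity; sinusoidal wingbeat oscillations
imprinted on bounding-box descriptors; two-species size mixtures; and
simple-V (echelon) files.  Every generator draws from one explicitly
passed seeded generator and records its parameters in a
:class:`SyntheticTruth` so downstream estimates can be scored against
known values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .flock_io import DEFAULT_FRAME_RATE, SPECIES, BirdTrack, FlockRecording, SpeciesSpec

__all__ = [
    "SyntheticTruth",
    "generate_compound_v",
    "generate_simple_v",
    "generate_bbox_series",
    "generate_mixed_species",
    "generate_heading_sweep",
]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters stored alongside every generated dataset.

    Alignment offsets are in wingspan units; wind in m/s (east, north);
    per-pair wingbeat phase offsets in radians; the species size mixture
    as (mu1, sigma1, mu2, sigma2, weight of component 1).
    """

    lateral_offset_mean: float = 1.0
    lateral_sd: float = 0.15
    trailing_mean: float = 0.8
    trailing_sd: float = 0.4
    elevation_sd: float = 1.3
    wind: tuple[float, float] = (0.0, 0.0)
    airspeed_mean: float = 9.0
    wingbeat_hz: dict = field(default_factory=dict)  # species -> Hz
    phase_offsets: dict = field(default_factory=dict)  # (a, b) -> rad
    species_mixture: tuple = (1.0, 0.1, 1.5, 0.1, 0.5)
    right_bias: float = 0.5  # P(attach to the right); 0.5 = symmetric
    jitter_sd: float = 0.05  # positional white noise, wingspans per axis
    seed: int = 0

    def __post_init__(self):
        for name in ("lateral_sd", "trailing_sd", "elevation_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        w = self.species_mixture[4]
        if not 0 < w < 1:
            raise ValueError("mixture weight must be in (0, 1)")
        if not 0 <= self.right_bias <= 1:
            raise ValueError("right_bias must be in [0, 1]")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["phase_offsets"] = {f"{a}|{b}": v for (a, b), v in self.phase_offsets.items()}
        with open(path, "w") as f:
            json.dump(d, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as f:
            d = json.load(f)
        d["wind"] = tuple(d["wind"])
        d["species_mixture"] = tuple(d["species_mixture"])
        d["phase_offsets"] = {
            tuple(k.split("|")): v for k, v in d.get("phase_offsets", {}).items()
        }
        return cls(**d)


def _advect(anchor_xy: np.ndarray, z0: np.ndarray, ground_v: np.ndarray,
            n_frames: int, dt: float, jitter_m: float, rng) -> np.ndarray:
    """Translate initial positions by a shared ground velocity, adding
    white positional jitter.  Returns (n_birds, n_frames, 3)."""
    t = np.arange(n_frames) * dt
    base = np.empty((anchor_xy.shape[0], n_frames, 3))
    base[:, :, 0] = anchor_xy[:, 0, None] + ground_v[0] * t
    base[:, :, 1] = anchor_xy[:, 1, None] + ground_v[1] * t
    base[:, :, 2] = z0[:, None]
    if jitter_m > 0:
        base += rng.normal(0.0, jitter_m, size=base.shape)
    return base


def generate_compound_v(
    n_birds: int,
    species: SpeciesSpec | str = "godwit",
    truth: SyntheticTruth | None = None,
    duration_s: float = 4.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    heading_deg: float = 90.0,
    min_separation_ws: float | None = None,
    rng=None,
    flock_id: str = "synthetic-cv",
) -> tuple[FlockRecording, SyntheticTruth]:
    """Generate a compound-V cluster flock by iterated attachment.

    Each new bird attaches behind an existing bird with a free follower
    slot, at a lateral offset ~ Normal(lateral_offset_mean, lateral_sd)
    wingspans, a trailing distance ~ Normal(trailing_mean, trailing_sd)
    and an elevation ~ Normal(0, elevation_sd).  Every bird carries at
    most one follower per side (sign Bernoulli(right_bias) among free
    sides), which propagates echelons through the cluster the way real
    compound-V flocks do; a candidate placement is additionally redrawn
    unless its anchor is its nearest existing flockmate (and it clears
    ``min_separation_ws`` when set), since the alignment rule is a
    *nearest-neighbor* rule and accidental near-coincident pairs would
    otherwise dominate the neighbor statistics.  All birds share an air
    velocity of magnitude ``airspeed_mean`` along ``heading_deg``
    (degrees anticlockwise from +x); the wind vector is added to obtain
    ground velocity.
    """
    if n_birds < 2:
        raise ValueError("need at least 2 birds")
    sp = SPECIES[species] if isinstance(species, str) else species
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(truth.seed if rng is None else rng)
    ws = sp.wingspan
    min_sep_m = (min_separation_ws or 0.0) * ws
    # exclusion requirement is capped at the planar rule length so that
    # large elevation draws (which lengthen the 3D link) are not truncated
    rule_len_m = float(np.hypot(truth.lateral_offset_mean, truth.trailing_mean)) * ws

    th = np.radians(heading_deg)
    fwd = np.array([np.cos(th), np.sin(th)])
    right = np.array([fwd[1], -fwd[0]])

    xy = np.zeros((n_birds, 2))
    z = np.zeros(n_birds)
    free_slots = {(0, 1.0), (0, -1.0)}  # (bird index, side)
    for i in range(1, n_birds):
        best = None
        best_margin = -np.inf
        for _attempt in range(100):
            # draw the side first so the bias is respected, then an anchor
            # with that side free (falling back to the other side)
            sign = 1.0 if rng.random() < truth.right_bias else -1.0
            sided = sorted(a for a, s in free_slots if s == sign)
            if not sided:
                sign = -sign
                sided = sorted(a for a, s in free_slots if s == sign)
            anchor = sided[rng.integers(0, len(sided))]
            lat = rng.normal(truth.lateral_offset_mean, truth.lateral_sd)
            trail = rng.normal(truth.trailing_mean, truth.trailing_sd)
            cand_xy = xy[anchor] + (sign * lat * right - trail * fwd) * ws
            cand_z = z[anchor] + rng.normal(0.0, truth.elevation_sd) * ws
            d_all = np.sqrt(np.sum((xy[:i] - cand_xy) ** 2, axis=1) + (z[:i] - cand_z) ** 2)
            d_anchor = d_all[anchor]
            d_others = np.min(np.delete(d_all, anchor)) if i > 1 else np.inf
            margin = d_others - max(min(d_anchor, rule_len_m), min_sep_m)
            if margin >= 0:
                best = (cand_xy, cand_z, anchor, sign)
                break
            if margin > best_margin:
                best_margin = margin
                best = (cand_xy, cand_z, anchor, sign)
        xy[i], z[i], anchor, sign = best
        free_slots.discard((anchor, sign))
        free_slots.update({(i, 1.0), (i, -1.0)})

    air_v = truth.airspeed_mean * fwd
    ground_v = np.array([air_v[0] + truth.wind[0], air_v[1] + truth.wind[1]])
    n_frames = max(3, int(round(duration_s * frame_rate)))
    pos = _advect(xy, z, ground_v, n_frames, 1.0 / frame_rate, truth.jitter_sd * ws, rng)

    tracks = [
        BirdTrack(f"b{i:04d}", sp, np.arange(n_frames), pos[i]) for i in range(n_birds)
    ]
    return FlockRecording(flock_id, tracks, frame_rate=frame_rate), truth


def generate_simple_v(
    n_birds: int,
    species: SpeciesSpec | str = "godwit",
    lateral: float = 0.8,
    trailing: float = 0.5,
    mirrored: bool = False,
    airspeed: float = 9.0,
    wind: tuple[float, float] = (0.0, 0.0),
    duration_s: float = 3.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    heading_deg: float = 90.0,
    noise_sd: float = 0.0,
    rng=None,
    flock_id: str = "synthetic-v",
) -> FlockRecording:
    """Generate a simple-V / echelon file.

    ``lateral`` and ``trailing`` are the per-link offsets in wingspans.
    With ``mirrored=True`` birds alternate between the two arms of a V;
    otherwise a single echelon trails to the right.  All birds lie in
    one horizontal plane.
    """
    if n_birds < 2:
        raise ValueError("need at least 2 birds")
    sp = SPECIES[species] if isinstance(species, str) else species
    rng = np.random.default_rng(rng)
    ws = sp.wingspan
    th = np.radians(heading_deg)
    fwd = np.array([np.cos(th), np.sin(th)])
    right = np.array([fwd[1], -fwd[0]])

    xy = np.zeros((n_birds, 2))
    arm_pos = {1: 0, -1: 0}  # rank along each arm
    for i in range(1, n_birds):
        side = (1 if i % 2 else -1) if mirrored else 1
        arm_pos[side] += 1
        k = arm_pos[side]
        xy[i] = (side * k * lateral * right - k * trailing * fwd) * ws

    ground_v = airspeed * fwd + np.asarray(wind)
    n_frames = max(3, int(round(duration_s * frame_rate)))
    pos = _advect(xy, np.zeros(n_birds), ground_v, n_frames, 1.0 / frame_rate,
                  noise_sd * ws, rng)
    tracks = [
        BirdTrack(f"b{i:04d}", sp, np.arange(n_frames), pos[i]) for i in range(n_birds)
    ]
    return FlockRecording(flock_id, tracks, frame_rate=frame_rate)


def generate_bbox_series(
    flock: FlockRecording,
    truth: SyntheticTruth,
    camera_distance_fn=None,
    amplitude: float = 0.3,
    base_height_px: float = 20.0,
    base_width_px: float = 30.0,
    body_size: float = 400.0,
    noise_sd: float = 0.0,
    drift_px_per_s: float = 2.0,
    camera_id: str = "cam0",
    rng=None,
) -> pd.DataFrame:
    """Imprint sinusoidal wingbeat oscillations on bounding-box descriptors.

    Per bird, height varies as ``1 + a*sin(2*pi*f*t + phi)``, width in
    antiphase as ``1 - a*sin(...)``; the top-left corner oscillates with
    the same phase in x and in antiphase in y, superimposed on a slow
    linear drift.  Pixel area scales as ``(body_size / distance)**2``.
    Wingbeat frequencies come from ``truth.wingbeat_hz`` (keyed by
    species, with per-bird overrides keyed by bird id) and per-bird phase
    offsets from ``truth.phase_offsets`` (keyed by ("", bird_id));
    unspecified phases are drawn uniformly.
    """
    rng = np.random.default_rng(truth.seed + 1 if rng is None else rng)
    camera_distance_fn = camera_distance_fn or (lambda bird_id, t: np.full_like(t, 100.0))
    dt = 1.0 / flock.frame_rate
    rows = []
    for track in flock.tracks:
        f_hz = truth.wingbeat_hz.get(track.bird_id,
                                     truth.wingbeat_hz.get(track.species.name, 6.0))
        phi = truth.phase_offsets.get(("", track.bird_id))
        if phi is None:
            phi = float(rng.uniform(0, 2 * np.pi))
            truth.phase_offsets[("", track.bird_id)] = phi
        t = track.frames * dt
        osc = np.sin(2 * np.pi * f_hz * t + phi)
        dist = np.asarray(camera_distance_fn(track.bird_id, t), dtype=float)
        noise = lambda: rng.normal(0, noise_sd, size=t.size) if noise_sd > 0 else 0.0
        corner_px = amplitude * 6.0  # corner sway scales with stroke amplitude
        height = base_height_px * (1 + amplitude * osc) + noise()
        width = base_width_px * (1 - amplitude * osc) + noise()
        tlx = drift_px_per_s * t + corner_px * osc + noise()
        tly = -drift_px_per_s * t - corner_px * osc + noise()
        area = (body_size / dist) ** 2 * (1 + amplitude * osc)
        rows.append(
            pd.DataFrame(
                {
                    "bird_id": track.bird_id,
                    "frame": track.frames,
                    "camera_id": camera_id,
                    "height_px": height,
                    "width_px": width,
                    "topleft_x_px": tlx,
                    "topleft_y_px": tly,
                    "area_px2": area,
                    "distance_m": dist,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_mixed_species(
    n1: int,
    n2: int,
    species1: SpeciesSpec | str = "dowitcher",
    species2: SpeciesSpec | str = "godwit",
    truth: SyntheticTruth | None = None,
    duration_s: float = 3.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    rng=None,
) -> tuple[FlockRecording, pd.DataFrame, pd.Series]:
    """Generate a two-species flock plus a bounding-box table whose
    distance-scaled sizes follow the truth's two-normal mixture.

    Returns ``(flock, bbox_table, true_labels)`` where ``true_labels``
    maps bird id to species name.  Component 1 of the mixture (mu1,
    sigma1, weight) is ``species1`` (the smaller bird).
    """
    sp1 = SPECIES[species1] if isinstance(species1, str) else species1
    sp2 = SPECIES[species2] if isinstance(species2, str) else species2
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(truth.seed + 2 if rng is None else rng)
    mu1, s1, mu2, s2, _w = truth.species_mixture

    flock, _ = generate_compound_v(
        n1 + n2, sp2, truth, duration_s=duration_s, frame_rate=frame_rate,
        rng=rng, flock_id="synthetic-mixed",
    )
    which = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    rng.shuffle(which)
    labels = {}
    sizes = {}
    for track, k in zip(flock.tracks, which):
        sp = (sp1, sp2)[k]
        track.species = sp
        labels[track.bird_id] = sp.name
        sizes[track.bird_id] = rng.normal((mu1, mu2)[k], (s1, s2)[k])

    dist0 = 100.0
    rows = []
    for track in flock.tracks:
        # area chosen so that sqrt(area) * distance inverts exactly to the
        # drawn scaled size (units are arbitrary for synthetic imagery)
        area = (sizes[track.bird_id] / dist0) ** 2
        rows.append(
            pd.DataFrame(
                {
                    "bird_id": track.bird_id,
                    "frame": track.frames,
                    "camera_id": "cam0",
                    "height_px": np.nan,
                    "width_px": np.nan,
                    "topleft_x_px": np.nan,
                    "topleft_y_px": np.nan,
                    "area_px2": area,
                    "distance_m": dist0,
                }
            )
        )
    bbox = pd.concat(rows, ignore_index=True)
    return flock, bbox, pd.Series(labels, name="species")


def generate_heading_sweep(
    wind: tuple[float, float],
    airspeed: float,
    n: int,
    speed_sd: float = 0.5,
    heading_range_deg: tuple[float, float] = (0.0, 360.0),
    rng=None,
) -> pd.DataFrame:
    """Ground-velocity samples from birds flying at a common airspeed in
    uniformly distributed directions, plus a constant wind — the setting
    the circle-fit wind estimator assumes.

    Returns a kinematics-like DataFrame (ground_speed, heading_deg,
    vx, vy) suitable for :func:`compoundv.wind.estimate_wind`.
    """
    rng = np.random.default_rng(rng)
    th = np.radians(rng.uniform(*heading_range_deg, size=n))
    spd = airspeed + rng.normal(0, speed_sd, size=n)
    vx = spd * np.cos(th) + wind[0]
    vy = spd * np.sin(th) + wind[1]
    return pd.DataFrame(
        {
            "bird_id": [f"b{i}" for i in range(n)],
            "frame": np.zeros(n, dtype=int),
            "vx": vx,
            "vy": vy,
            "ground_speed": np.hypot(vx, vy),
            "heading_deg": np.degrees(np.arctan2(vy, vx)) % 360.0,
        }
    )
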