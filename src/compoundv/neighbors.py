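"""Nearest-neighbor alignment metrics.

For each focal bird at each sampled frame the 3D-Euclidean nearest
flockmate is found and the displacement decomposed in the focal bird's
flight-aligned frame: front-back along the horizontal velocity, lateral
perpendicular to it (positive to the bird's right), elevation vertical.
Distances are reported both in metres and non-dimensionalized by
wingspan (the species wingspan for same-species pairs, the mean of the
two wingspans for mixed pairs).  The modal neighbor position is the
peak of a fixed-bandwidth Gaussian product-kernel density over
(lateral, front-back), following the convention of using modal rather
than mean values because distances are truncated at zero and hence
skewed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

MIN_GROUND_SPEED = 0.5  # m/s; below this the heading is undefined
DEFAULT_BANDWIDTH_WS = 0.25  # KDE smoothing bandwidth, wingspans
DEFAULT_GRID_WS = 0.05  # KDE grid resolution, wingspans
ELEVATION_SLICE_WS = 1.0  # "same horizontal plane" half-width, wingspans

__all__ = [
    "nearest_neighbor_offsets",
    "partition_by_elevation",
    "modal_position",
    "ModalPosition",
    "compare_lateral_by_neighbor_species",
    "cross_flock_scaling_regression",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


def pair_wingspan(ws_a: float, ws_b: float) -> float:
    """Scaling wingspan for a pair: the shared wingspan for conspecifics,
    the average of the two for mixed pairs."""
    return ws_a if ws_a == ws_b else 0.5 * (ws_a + ws_b)


def nearest_neighbor_offsets(
    flock,
    kinematics: pd.DataFrame,
    sample_frames: dict | None = None,
    min_ground_speed: float = MIN_GROUND_SPEED,
    restrict: str = "any",
) -> pd.DataFrame:
    """Nearest-neighbor displacement records for every sampled bird-frame.

    ``sample_frames`` maps bird id to the frames at which that bird is a
    focal sample (typically one-wingbeat spacing); ``None`` samples every
    frame.  Neighbors are always searched among *all* birds present in
    the frame regardless of sampling.  Focal samples whose ground speed
    is below ``min_ground_speed`` are skipped (undefined heading).

    ``restrict`` selects the neighbor pool: ``"any"`` takes the 3D
    nearest flockmate (the flock-density measure), ``"leading"`` the
    nearest bird *ahead* of the focal (the alignment-partner measure the
    positional models use; a nearest neighbor is then only defined when
    it leads the focal bird).

    Returns a DataFrame with one row per (focal, frame): neighbor id,
    front_back / lateral_signed / lateral_abs / elevation / distance3d in
    metres and wingspan units (``*_ws``), the ``leading`` flag and the
    neighbor-species code (-1 smaller, 0 same, +1 larger).
    """
    if restrict not in ("any", "leading"):
        raise ValueError("restrict must be 'any' or 'leading'")
    wingspans = {t.bird_id: t.species.wingspan for t in flock.tracks}

    by_frame = kinematics.groupby("frame")
    sampled = None
    if sample_frames is not None:
        sampled = {b: set(np.asarray(f).tolist()) for b, f in sample_frames.items()}

    chunks = []
    n_slow = 0
    for frame, sub in by_frame:
        if len(sub) < 2:
            continue
        ids = sub["bird_id"].to_numpy()
        pos = sub[["x", "y", "z"]].to_numpy()
        keep = np.ones(len(ids), dtype=bool)
        if sampled is not None:
            keep = np.array([frame in sampled.get(b, ()) for b in ids])
        gs = sub["ground_speed"].to_numpy()
        slow = keep & (gs < min_ground_speed)
        n_slow += int(slow.sum())
        keep &= ~slow
        if not keep.any():
            continue
        i = np.flatnonzero(keep)
        vel_all = sub[["vx", "vy"]].to_numpy()
        if restrict == "any":
            tree = cKDTree(pos)
            dist, idx = tree.query(pos, k=2)
            j = idx[i, 1]
            dij = dist[i, 1]
        else:
            # nearest bird ahead of each focal: full pairwise scan
            diff = pos[None, :, :] - pos[:, None, :]
            with np.errstate(invalid="ignore"):
                fwd_all = vel_all / np.hypot(vel_all[:, 0], vel_all[:, 1])[:, None]
            fb_all = diff[:, :, 0] * fwd_all[:, None, 0] + diff[:, :, 1] * fwd_all[:, None, 1]
            dall = np.linalg.norm(diff, axis=2)
            dall[np.arange(len(ids)), np.arange(len(ids))] = np.inf
            dall = np.where(fb_all > 0, dall, np.inf)
            j_all = np.argmin(dall, axis=1)
            d_min = dall[np.arange(len(ids)), j_all]
            has = np.isfinite(d_min[i])
            i = i[has]
            if i.size == 0:
                continue
            j = j_all[i]
            dij = dall[i, j]
        d = pos[j] - pos[i]
        hv = vel_all[i]
        fwd = hv / np.hypot(hv[:, 0], hv[:, 1])[:, None]
        fb = d[:, 0] * fwd[:, 0] + d[:, 1] * fwd[:, 1]
        lat = d[:, 0] * fwd[:, 1] - d[:, 1] * fwd[:, 0]  # + = neighbor to the right
        ws = np.array([wingspans[b] for b in ids])
        scale = np.where(ws[i] == ws[j], ws[i], 0.5 * (ws[i] + ws[j]))
        chunks.append(
            pd.DataFrame(
                {
                    "focal_id": ids[i],
                    "neighbor_id": ids[j],
                    "frame": frame,
                    "front_back": fb,
                    "lateral_signed": lat,
                    "lateral_abs": np.abs(lat),
                    "elevation": d[:, 2],
                    "distance3d": dij,
                    "pair_wingspan": scale,
                    "leading": fb > 0,
                    "nn_species_code": np.sign(ws[j] - ws[i]).astype(int),
                }
            )
        )
    if n_slow:
        logger.info("skipped %d focal samples below %.2f m/s", n_slow, min_ground_speed)

    cols = [
        "focal_id", "neighbor_id", "frame", "front_back", "lateral_signed",
        "lateral_abs", "elevation", "distance3d", "pair_wingspan",
        "leading", "nn_species_code",
    ]
    out = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=cols)
    )
    for col in ("front_back", "lateral_signed", "lateral_abs", "elevation", "distance3d"):
        out[col + "_ws"] = out[col] / out["pair_wingspan"]
    return out


def partition_by_elevation(
    offsets: pd.DataFrame, slice_halfwidth_ws: float = ELEVATION_SLICE_WS
):
    """Split offsets into the same-horizontal-plane slice and the rest.

    Returns ``(in_slice, out_slice, fraction_in_slice)`` where the slice
    is |elevation| <= halfwidth in wingspan units.
    """
    mask = offsets["elevation_ws"].abs() <= slice_halfwidth_ws
    frac = float(mask.mean()) if len(offsets) else float("nan")
    return offsets[mask], offsets[~mask], frac


def _kde_grid(x, y, bandwidth, grid_res):
    gx = np.arange(x.min(), x.max() + grid_res, grid_res)
    gy = np.arange(y.min(), y.max() + grid_res, grid_res)
    # product Gaussian kernel, evaluated separably then combined
    dx = (gx[:, None] - x[None, :]) / bandwidth
    dy = (gy[:, None] - y[None, :]) / bandwidth
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = kx @ ky.T  # (len(gx), len(gy))
    dens /= 2 * np.pi * bandwidth**2 * x.size
    return gx, gy, dens


class ModalPosition:
    """Peak of the 2D neighbor-position density.

    Attributes: ``lateral_mode`` and ``front_back_mode`` (in the units of
    the input columns), ``alignment_angle`` in degrees from the travel
    direction, ``bandwidth``, ``n_samples``.
    """

    def __init__(self, lateral_mode, front_back_mode, bandwidth, n_samples):
        self.lateral_mode = float(lateral_mode)
        self.front_back_mode = float(front_back_mode)
        self.bandwidth = float(bandwidth)
        self.n_samples = int(n_samples)

    @property
    def alignment_angle(self) -> float:
        return float(np.degrees(np.arctan2(self.lateral_mode, self.front_back_mode)))

    def __repr__(self):
        return (
            f"ModalPosition(lateral={self.lateral_mode:.3f}, "
            f"front_back={self.front_back_mode:.3f}, "
            f"angle={self.alignment_angle:.1f} deg, n={self.n_samples})"
        )


def modal_position(
    offsets: pd.DataFrame,
    bandwidth: float = DEFAULT_BANDWIDTH_WS,
    grid_res: float = DEFAULT_GRID_WS,
    units: str = "ws",
    leading_only: bool = True,
    in_slice_only: bool = True,
) -> ModalPosition:
    """Modal (lateral, front-back) neighbor position from a KDE peak.

    Uses unsigned lateral distance of leading-neighbor pairs within the
    ±1-wingspan elevation slice (both filters switchable).  The density
    is a Gaussian product kernel with fixed ``bandwidth``, evaluated on a
    regular grid of ``grid_res`` spacing spanning the data range; the
    mode is the grid argmax, ties broken toward the smallest distance
    from the focal bird.  ``units`` selects wingspan ("ws") or metric
    ("m") columns; bandwidth and grid are interpreted in those units.
    """
    sub = offsets
    if leading_only:
        sub = sub[sub["leading"]]
    if in_slice_only:
        sub, _, _ = partition_by_elevation(sub)
    if len(sub) < 10:
        raise InsufficientDataError(f"only {len(sub)} offsets after filtering; need >= 10")
    suffix = "_ws" if units == "ws" else ""
    x = sub["lateral_abs" + suffix].to_numpy()
    y = sub["front_back" + suffix].to_numpy()
    gx, gy, dens = _kde_grid(x, y, bandwidth, grid_res)
    best = np.flatnonzero(dens == dens.max())
    ii, jj = np.unravel_index(best, dens.shape)
    k = int(np.argmin(np.hypot(gx[ii], gy[jj])))  # tie-break: closest to focal
    return ModalPosition(gx[ii[k]], gy[jj[k]], bandwidth, len(sub))


def compare_lateral_by_neighbor_species(group_a, group_b):
    """Two-sided Mann-Whitney rank-sum comparison of two sets of lateral
    distances (tie-corrected).  Returns ``(U_a, n1, n2, p)`` with U
    reported for the first group."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), int(a.size), int(b.size), float(res.pvalue)


def cross_flock_scaling_regression(y, x) -> dict:
    """OLS of a per-flock modal statistic on a per-flock predictor
    (e.g. modal metric lateral distance on species wingspan).

    Returns slope, intercept, r2, F and p of the slope.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 flocks for the scaling regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r2": float(fit.rsquared),
        "F": float(fit.fvalue),
        "p": float(fit.f_pvalue),
        "n": int(x.size),
    }
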