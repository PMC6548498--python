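"""Global flock structure: boundary, edge distances, angular
distributions of neighbors at multiple ranges, left/right asymmetry and
the k-nearest-neighbor density power law.

The flock boundary is a concave ("compact") hull over the horizontal
positions — an alpha shape built from the Delaunay triangulation with
the circumradius threshold tied to the flock's own density scale (twice
the median nearest-neighbor distance), falling back to the convex hull
for degenerate point sets.  A bird's edge distance is its minimum
horizontal distance to the boundary, and the flock's maximum radius is
the median edge distance, which guarantees analyses bounded by it keep
at least half the flock and avoid edge effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from . import circstats

logger = logging.getLogger(__name__)

DEFAULT_ELEVATION_HALFANGLE_DEG = 15.0
DEFAULT_BIN_HALFWIDTH_WS = 1.0

__all__ = [
    "HullSummary",
    "AngularDistribution",
    "compact_hull",
    "edge_distances_per_bird",
    "neighbor_angles",
    "nn_power_exponent",
    "orientation_tests",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class HullSummary:
    boundary: Polygon
    bird_ids: np.ndarray
    edge_distance_m: np.ndarray  # per bird, horizontal distance to boundary
    wingspan: float

    @property
    def edge_distance_ws(self) -> np.ndarray:
        return self.edge_distance_m / self.wingspan

    @property
    def maximum_radius_ws(self) -> float:
        """Median edge distance in wingspans."""
        return float(np.median(self.edge_distance_ws))

    @property
    def maximum_radius_m(self) -> float:
        return float(np.median(self.edge_distance_m))


def _alpha_polygon(xy: np.ndarray, alpha_radius: float) -> Polygon | None:
    """Union of Delaunay triangles whose circumradius <= alpha_radius."""
    try:
        tri = Delaunay(xy)
    except Exception:
        return None
    pa, pb, pc = (xy[tri.simplices[:, k]] for k in range(3))
    a = np.linalg.norm(pb - pc, axis=1)
    b = np.linalg.norm(pa - pc, axis=1)
    c = np.linalg.norm(pa - pb, axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area > 0, a * b * c / (4.0 * area), np.inf)
    keep = circum_r <= alpha_radius
    if not keep.any():
        return None
    polys = [Polygon(t) for t in xy[tri.simplices[keep]]]
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":  # keep the dominant component
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged if merged.geom_type == "Polygon" and merged.area > 0 else None


def compact_hull(xy: np.ndarray, bird_ids=None, wingspan: float = 1.0,
                 alpha_radius: float | None = None) -> HullSummary:
    """Concave boundary of one frame's horizontal positions plus per-bird
    edge distances.

    ``alpha_radius`` defaults to twice the median nearest-neighbor
    distance of the frame.  Degenerate or over-aggressive alpha shapes
    fall back to the convex hull with a warning.  Birds outside the
    boundary polygon get edge distance 0.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 4:
        raise InsufficientDataError("need >= 4 birds for a hull")
    if bird_ids is None:
        bird_ids = np.arange(xy.shape[0])

    if alpha_radius is None:
        tree = cKDTree(xy)
        d, _ = tree.query(xy, k=2)
        alpha_radius = 2.0 * float(np.median(d[:, 1]))

    # grow alpha until the shape is valid and covers nearly all birds;
    # an over-aggressive alpha fragments the hull and strands points
    poly = None
    pts = MultiPoint(xy)
    for _ in range(8):
        cand = _alpha_polygon(xy, alpha_radius)
        if cand is not None and cand.is_valid:
            covered = sum(cand.covers(p) for p in pts.geoms)
            if covered == xy.shape[0]:
                poly = cand
                break
        alpha_radius *= 1.6
    if poly is None:
        try:
            hull = ConvexHull(xy)
            poly = Polygon(xy[hull.vertices])
            logger.warning("alpha shape degenerate; fell back to convex hull")
        except Exception as exc:
            raise InsufficientDataError(f"degenerate point set: {exc}") from exc

    boundary = poly.exterior
    edge = np.empty(xy.shape[0])
    for i, p in enumerate(MultiPoint(xy).geoms):
        edge[i] = boundary.distance(p) if poly.covers(p) else 0.0
    return HullSummary(poly, np.asarray(bird_ids), edge, wingspan)


def edge_distances_per_bird(kinematics: pd.DataFrame, sample_frames: dict | None = None,
                            wingspan: float = 1.0) -> pd.Series:
    """Per-bird edge distance (m), averaged over per-frame hulls.

    The hull is computed independently for each sampled frame and each
    bird's distances averaged over the frames in which it appears.
    """
    frames = sorted(kinematics["frame"].unique())
    if sample_frames is not None:
        wanted = set()
        for f in sample_frames.values():
            wanted.update(np.asarray(f).tolist())
        frames = [f for f in frames if f in wanted]
    acc: dict = {}
    for f in frames:
        sub = kinematics[kinematics["frame"] == f]
        if len(sub) < 4:
            continue
        hull = compact_hull(sub[["x", "y"]].to_numpy(), sub["bird_id"].to_numpy(),
                            wingspan=wingspan)
        for b, e in zip(hull.bird_ids, hull.edge_distance_m):
            acc.setdefault(b, []).append(e)
    return pd.Series({b: float(np.mean(v)) for b, v in acc.items()}, name="edge_distance_m")


@dataclass
class AngularDistribution:
    reference_distance_ws: float
    angles_deg: np.ndarray = field(repr=False)  # signed, 0 = dead ahead, + = right
    n_focal: int = 0

    @property
    def mean_angle_deg(self) -> float:
        m = circstats.circ_mean(np.radians(self.angles_deg))
        return float(np.degrees(np.angle(np.exp(1j * m))))

    @property
    def resultant_length(self) -> float:
        return circstats.resultant_length(np.radians(self.angles_deg))

    @property
    def axial_mean_deg(self) -> float:
        """Mean neighbor *axis* in (-90, 90], from the circular mean of
        doubled angles.  Echelon structure is axial — every leading
        neighbor at angle a pairs with a trailing one near a+180 — so
        the plain circular mean cancels while the axial mean captures
        the left-front/right-rear tilt of the formation."""
        m = circstats.circ_mean(np.radians(2.0 * self.angles_deg))
        return float(np.degrees(np.angle(np.exp(1j * m))) / 2.0)

    @property
    def asymmetry(self) -> str:
        """"right" when the neighbor axis tilts right of the track."""
        return "right" if self.axial_mean_deg > 0 else "left"


def neighbor_angles(
    kinematics: pd.DataFrame,
    edge_distance_ws: pd.Series,
    reference_distance_ws: float,
    wingspan: float,
    sample_frames: dict | None = None,
    bin_halfwidth_ws: float = DEFAULT_BIN_HALFWIDTH_WS,
    elevation_halfangle_deg: float = DEFAULT_ELEVATION_HALFANGLE_DEG,
) -> AngularDistribution:
    """Signed horizontal angles of all neighbors in a distance band.

    Focal birds whose edge distance is below ``reference + bin_halfwidth``
    wingspans are excluded (edge-effect control).  Neighbors qualify when
    their 3D distance lies within ``reference ± bin_halfwidth`` wingspans
    and their elevation angle is within ``±elevation_halfangle_deg``.
    Angles are measured from the focal bird's travel direction, positive
    to its right, in (-180, 180].
    """
    ok_focal = set(edge_distance_ws[edge_distance_ws >= reference_distance_ws
                                    + bin_halfwidth_ws].index)
    if not ok_focal:
        raise InsufficientDataError(
            f"no focal birds clear of the edge at {reference_distance_ws} wingspans"
        )
    sampled = None
    if sample_frames is not None:
        sampled = {b: set(np.asarray(f).tolist()) for b, f in sample_frames.items()}

    lo = (reference_distance_ws - bin_halfwidth_ws) * wingspan
    hi = (reference_distance_ws + bin_halfwidth_ws) * wingspan
    tan_elev = np.tan(np.radians(elevation_halfangle_deg))

    angles = []
    focals = set()
    for frame, sub in kinematics.groupby("frame"):
        if len(sub) < 2:
            continue
        ids = sub["bird_id"].to_numpy()
        pos = sub[["x", "y", "z"]].to_numpy()
        vel = sub[["vx", "vy"]].to_numpy()
        keep = np.array([b in ok_focal for b in ids])
        if sampled is not None:
            keep &= np.array([frame in sampled.get(b, ()) for b in ids])
        for i in np.flatnonzero(keep):
            d = pos - pos[i]
            r3 = np.linalg.norm(d, axis=1)
            horiz = np.hypot(d[:, 0], d[:, 1])
            with np.errstate(divide="ignore", invalid="ignore"):
                in_elev = np.abs(d[:, 2]) <= tan_elev * horiz
            sel = (r3 >= lo) & (r3 <= hi) & in_elev
            sel[i] = False
            if not sel.any():
                continue
            hv = vel[i]
            fwd = hv / np.hypot(*hv)
            fb = d[sel, 0] * fwd[0] + d[sel, 1] * fwd[1]
            lat = d[sel, 0] * fwd[1] - d[sel, 1] * fwd[0]
            angles.extend(np.degrees(np.arctan2(lat, fb)))
            focals.add(ids[i])
    if not angles:
        raise InsufficientDataError(
            f"no qualifying neighbors at {reference_distance_ws} wingspans"
        )
    a = np.asarray(angles)
    a = np.where(a <= -180.0, a + 360.0, a)
    return AngularDistribution(reference_distance_ws, a, n_focal=len(focals))


def nn_power_exponent(kinematics: pd.DataFrame, sample_frames: dict | None = None,
                      k: int = 10) -> float:
    """Exponent of the power law relating k-nearest-neighbor distance to
    neighbor rank.

    For every sampled bird-frame the distances to its ``k`` nearest
    neighbors are collected; the exponent is the least-squares slope of
    ``log(mean distance at rank j)`` against ``log(j)``, pooled over all
    samples.  For uniformly random points the exponent approaches 1/D in
    D dimensions, so lower values indicate locally structured spacing.
    """
    sampled = None
    if sample_frames is not None:
        sampled = {b: set(np.asarray(f).tolist()) for b, f in sample_frames.items()}
    sums = np.zeros(k)
    count = 0
    for frame, sub in kinematics.groupby("frame"):
        if len(sub) < k + 1:
            continue
        ids = sub["bird_id"].to_numpy()
        pos = sub[["x", "y", "z"]].to_numpy()
        tree = cKDTree(pos)
        d, _ = tree.query(pos, k=k + 1)
        keep = np.ones(len(ids), dtype=bool)
        if sampled is not None:
            keep = np.array([frame in sampled.get(b, ()) for b in ids])
        if keep.any():
            sums += d[keep, 1:].sum(axis=0)
            count += int(keep.sum())
    if count == 0:
        raise InsufficientDataError(f"need >= {k + 1} birds per frame")
    mean_d = sums / count
    j = np.arange(1, k + 1)
    slope = np.polyfit(np.log(j), np.log(mean_d), 1)[0]
    return float(slope)


def orientation_tests(asymmetry_deg, wind_dir_deg, turn_dir, camera_dir_deg) -> pd.DataFrame:
    """Relate per-flock left/right orientation to environmental factors.

    ``asymmetry_deg`` is one signed mean neighbor angle per flock;
    circular-circular correlation is used against wind and camera
    directions and a linear regression against (linear) turn direction.
    Returns a table with columns variable, test, n, r2, stat, p.  With
    fewer than five flocks a low-power flag is logged.
    """
    import statsmodels.api as sm

    asym = np.asarray(asymmetry_deg, dtype=float)
    n = asym.size
    if n < 5:
        logger.warning("orientation tests on %d flocks: low power", n)
    rows = []
    for name, other in (("wind_direction", wind_dir_deg), ("camera_direction", camera_dir_deg)):
        r, t, p = circstats.circ_corr(np.radians(asym), np.radians(np.asarray(other, float)))
        rows.append((name, "circular correlation", n, r**2, t, p))
    x = np.asarray(turn_dir, dtype=float)
    fit = sm.OLS(asym, sm.add_constant(x)).fit()
    rows.append(("turn_direction", "linear regression", n, float(fit.rsquared),
                 float(fit.fvalue), float(fit.f_pvalue)))
    return pd.DataFrame(rows, columns=["variable", "test", "n", "r2", "stat", "p"])
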