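"""Wind estimation from heading-dependence of ground speed.

A bird holding a fixed airspeed has a ground velocity that is its air
velocity plus the wind vector, so across flight directions the tips of
the ground-velocity vectors lie on a circle of radius equal to the
airspeed, centred on the wind vector.  The estimator bins sampled
headings into 10-degree bins, takes the median ground speed of each
sufficiently populated bin, places one point per bin at
``(median*cos(theta), median*sin(theta))`` and fits a circle: the
centre is the wind vector and the radius a characteristic airspeed.
Airspeed per bird-frame is then ``|ground velocity - wind|``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_DEG = 10.0
DEFAULT_MIN_BIN_N = 500
MIN_BIN_FLOOR = 50

__all__ = ["WindEstimate", "WindEstimationError", "estimate_wind", "airspeed",
           "relative_wind_direction"]


class WindEstimationError(RuntimeError):
    """Too few qualifying heading bins; fall back to station wind."""


@dataclass
class WindEstimate:
    wind_east: float
    wind_north: float
    fitted_airspeed_radius: float
    rms_residual: float
    bin_table: pd.DataFrame = field(repr=False)  # theta_deg, n, median_speed

    @property
    def speed(self) -> float:
        return float(np.hypot(self.wind_east, self.wind_north))

    @property
    def direction_met(self) -> float:
        """Meteorological direction the wind blows *from*, degrees
        clockwise from north."""
        to_math = np.degrees(np.arctan2(self.wind_north, self.wind_east))
        return float((270.0 - to_math) % 360.0)

    def to_json(self, path) -> None:
        d = {
            "wind_east": self.wind_east,
            "wind_north": self.wind_north,
            "speed": self.speed,
            "direction_met": self.direction_met,
            "radius": self.fitted_airspeed_radius,
            "rms_residual": self.rms_residual,
            "bins": self.bin_table.to_dict(orient="records"),
        }
        with open(path, "w") as f:
            json.dump(d, f, indent=1)


def _kasa_circle(points: np.ndarray):
    """Algebraic (Kåsa) circle fit: minimise sum ((x-a)^2+(y-b)^2-r^2)^2."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(c + cx**2 + cy**2)
    return cx, cy, r


def _gauss_newton_step(points, cx, cy, r):
    """One Gauss-Newton step on the geometric residuals |p - c| - r."""
    d = points - [cx, cy]
    rho = np.hypot(d[:, 0], d[:, 1])
    rho = np.where(rho == 0, 1e-12, rho)
    resid = rho - r
    J = np.column_stack([-d[:, 0] / rho, -d[:, 1] / rho, -np.ones_like(rho)])
    step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
    return cx + step[0], cy + step[1], r + step[2]


def estimate_wind(
    kinematics: pd.DataFrame,
    sample_frames: dict | None = None,
    bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG,
    min_bin_n: int = DEFAULT_MIN_BIN_N,
    adaptive_min_bin: bool = True,
) -> WindEstimate:
    """Fit the wind vector from heading-binned median ground speeds.

    ``sample_frames`` restricts the input to one-wingbeat samples per
    bird (dict bird_id -> frames); ``None`` uses every frame.  Bins of
    ``bin_width_deg`` need at least ``min_bin_n`` samples; when the
    dataset holds fewer than 10,000 samples the threshold scales down
    proportionally (floor 50) so that smaller recordings remain
    estimable.  Requires at least three qualifying bins spanning at
    least 60 degrees of heading.
    """
    kin = kinematics
    if sample_frames is not None:
        masks = []
        for b, frames in sample_frames.items():
            masks.append(
                kin[(kin["bird_id"] == b) & (kin["frame"].isin(np.asarray(frames)))]
            )
        kin = pd.concat(masks, ignore_index=True) if masks else kin.iloc[:0]

    n_total = len(kin)
    bins = (kin["heading_deg"] // bin_width_deg).astype(int)
    threshold = min_bin_n
    if adaptive_min_bin:
        # The fixed 500-point rule presumes large recordings whose headings
        # concentrate in few bins.  For smaller or uniformly spread samples
        # scale the threshold to half the mean occupied-bin count (floor 50)
        # so coverage is not discarded wholesale.
        n_occupied = max(1, bins.nunique())
        scaled = max(MIN_BIN_FLOOR, int(0.5 * n_total / n_occupied))
        if scaled < threshold:
            threshold = scaled
            logger.info(
                "wind: %d samples over %d bins; per-bin threshold scaled to %d",
                n_total, n_occupied, threshold,
            )
    table = (
        kin.assign(_bin=bins)
        .groupby("_bin")["ground_speed"]
        .agg(n="size", median_speed="median")
        .reset_index()
    )
    table["theta_deg"] = (table["_bin"] + 0.5) * bin_width_deg
    table = table[table["n"] >= threshold][["theta_deg", "n", "median_speed"]]

    if len(table) < 3:
        raise WindEstimationError(
            f"only {len(table)} heading bins with >= {threshold} samples; "
            "use station wind instead"
        )
    span = np.ptp(np.sort(table["theta_deg"].to_numpy()))
    if span < 60.0:
        raise WindEstimationError(
            f"qualifying bins span only {span:.0f} degrees of heading (< 60)"
        )

    th = np.radians(table["theta_deg"].to_numpy())
    m = table["median_speed"].to_numpy()
    pts = np.column_stack([m * np.cos(th), m * np.sin(th)])
    cx, cy, r = _kasa_circle(pts)
    cx, cy, r = _gauss_newton_step(pts, cx, cy, r)
    resid = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
    return WindEstimate(
        wind_east=float(cx),
        wind_north=float(cy),
        fitted_airspeed_radius=float(r),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        bin_table=table.reset_index(drop=True),
    )


def airspeed(kinematics: pd.DataFrame, wind: WindEstimate | tuple) -> pd.DataFrame:
    """Append an ``airspeed`` column: |ground velocity - wind vector|."""
    we, wn = (wind.wind_east, wind.wind_north) if isinstance(wind, WindEstimate) else wind
    out = kinematics.copy()
    out["airspeed"] = np.hypot(out["vx"] - we, out["vy"] - wn)
    return out


def relative_wind_direction(flock_mean_heading_deg: float, wind: WindEstimate | tuple) -> float:
    """Angle between the flight direction and the direction the wind
    comes from, folded to [0, 180]: 0 = pure headwind, 180 = pure
    tailwind.  Heading in degrees anticlockwise from +x (east)."""
    we, wn = (wind.wind_east, wind.wind_north) if isinstance(wind, WindEstimate) else wind
    from_dir = np.arctan2(-wn, -we)  # direction the wind comes from (math frame)
    diff = np.degrees(
        np.angle(np.exp(1j * (np.radians(flock_mean_heading_deg) - from_dir)))
    )
    return float(abs(diff))
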