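"""Species classification in mixed flocks from distance-scaled pixel area.

A bird's pixel area falls off with the square of its camera distance,
so ``sqrt(area) * distance`` is a range-invariant size score.  In a
two-species flock the per-bird scores form a two-component normal
mixture; the density intersection between the component means is the
classification threshold, and the overlap integral of the weighted
component tails gives the expected misclassification rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gaussian_kde, norm
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

MIN_FRAMES_PER_BIRD = 5
MIN_BIRDS_FOR_FIT = 50

__all__ = ["SpeciesSizeModel", "UnimodalSizeDistribution", "scaled_size_per_track",
           "fit_species_model", "classify"]


class UnimodalSizeDistribution(RuntimeError):
    """Size scores show no bimodality: single-species verdict."""


@dataclass
class SpeciesSizeModel:
    """Two-normal mixture over scaled sizes, with the intersection
    threshold and the expected misclassification fraction."""

    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float
    threshold: float
    expected_error: float

    def __post_init__(self):
        assert self.mu1 < self.mu2, "components must be ordered by mean"
        assert self.mu1 < self.threshold < self.mu2

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=1)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Zero-phase moving average (centred, edge-padded)."""
    width = max(1, int(width))
    if width == 1 or x.size < 2:
        return x
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(width) / width
    out = np.convolve(xp, kernel, mode="same")
    return out[pad : pad + x.size]


def scaled_size_per_track(
    bbox: pd.DataFrame,
    frame_rate: float = 29.97,
    wingbeat_hz: float = 6.0,
    min_frames: int = MIN_FRAMES_PER_BIRD,
) -> pd.Series:
    """Per-bird distance-scaled size: sqrt(low-pass area) x distance,
    averaged over frames and cameras.

    The low-pass filter is a zero-phase moving average one wingbeat
    period wide, removing the flapping modulation of the silhouette
    area.  Rows flagged ``merged`` (bounding box containing two birds)
    are excluded when that column is present.  Birds with fewer than
    ``min_frames`` usable frames are returned as NaN (unclassifiable).
    """
    df = bbox
    if "merged" in df.columns:
        df = df[~df["merged"].astype(bool)]
    width = max(1, int(round(frame_rate / wingbeat_hz)))
    out = {}
    for bird, sub in df.groupby("bird_id"):
        vals = []
        for _cam, cam_sub in sub.groupby("camera_id"):
            cam_sub = cam_sub.sort_values("frame")
            area = cam_sub["area_px2"].to_numpy(dtype=float)
            dist = cam_sub["distance_m"].to_numpy(dtype=float)
            ok = np.isfinite(area) & np.isfinite(dist)
            if ok.sum() == 0:
                continue
            filt = _moving_average(area[ok], width)
            vals.extend(np.sqrt(np.maximum(filt, 0.0)) * dist[ok])
        if len(vals) < min_frames:
            logger.info("bird %s: %d usable frames (< %d), unclassifiable",
                        bird, len(vals), min_frames)
            out[bird] = np.nan
        else:
            out[bird] = float(np.mean(vals))
    return pd.Series(out, name="scaled_size")


def _is_bimodal(x: np.ndarray) -> bool:
    """Dip check: the KDE must have a local minimum between its two
    highest local maxima."""
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    d = kde(grid)
    interior = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    if interior.size < 2:
        return False
    top2 = interior[np.argsort(d[interior])][-2:]
    lo, hi = np.sort(top2)
    dip = d[lo : hi + 1].min()
    return dip < 0.95 * min(d[lo], d[hi])


def fit_species_model(scaled_sizes, random_state: int = 0) -> SpeciesSizeModel:
    """Fit the two-normal mixture and locate the intersection threshold.

    The mixture is fit by expectation-maximization (five seeded
    restarts).  The threshold is the root of the weighted component
    density difference between the two means; the expected error is
    ``w1*P(X1 > thr) + w2*P(X2 < thr)``.  Unimodal inputs raise
    :class:`UnimodalSizeDistribution` (single-species verdict).
    """
    x = np.asarray(pd.Series(scaled_sizes).dropna(), dtype=float)
    if x.size < MIN_BIRDS_FOR_FIT:
        raise ValueError(f"need >= {MIN_BIRDS_FOR_FIT} classifiable birds, got {x.size}")
    if not _is_bimodal(x):
        raise UnimodalSizeDistribution("no dip between modes: single species")

    gm = GaussianMixture(n_components=2, n_init=5, random_state=random_state)
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    mus = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    ws = gm.weights_.ravel()[order]

    def ddiff(v):
        return ws[0] * norm.pdf(v, mus[0], sds[0]) - ws[1] * norm.pdf(v, mus[1], sds[1])

    # the weighted densities must cross between the means; find the root
    grid = np.linspace(mus[0], mus[1], 2048)
    vals = ddiff(grid)
    sgn = np.sign(vals)
    crossings = np.flatnonzero(np.diff(sgn) != 0)
    if crossings.size == 0:
        raise UnimodalSizeDistribution("weighted densities do not cross between means")
    k = crossings[0]
    thr = brentq(ddiff, grid[k], grid[k + 1])

    err = float(ws[0] * norm.sf(thr, mus[0], sds[0]) + ws[1] * norm.cdf(thr, mus[1], sds[1]))
    return SpeciesSizeModel(
        mu1=float(mus[0]), sigma1=float(sds[0]), w1=float(ws[0]),
        mu2=float(mus[1]), sigma2=float(sds[1]), w2=float(ws[1]),
        threshold=float(thr), expected_error=err,
    )


def classify(scaled_sizes, model: SpeciesSizeModel,
             smaller: str = "small", larger: str = "large") -> pd.Series:
    """Threshold classification: at or below the threshold -> smaller
    species, above -> larger.  NaN sizes stay unclassified (NaN)."""
    s = pd.Series(scaled_sizes, dtype=float)
    out = pd.Series(np.where(s <= model.threshold, smaller, larger), index=s.index,
                    dtype=object)
    out[s.isna()] = np.nan
    return out.rename("species_label")
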