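"""Wingbeat frequency and phase from bounding-box oscillations.

As a bird flaps, its image-space bounding box pulses: the box gets
taller and narrower at the top of the upstroke and shorter and wider
mid-stroke, and the top-left corner shifts accordingly.  Averaging
four standardized components — height, inverse width, detrended
top-left x and the negated detrended top-left y — yields a composite
oscillation score that tracks wingbeat phase independent of the bird's
orientation to the camera.  The composite is band-pass filtered and a
128-point FFT locates the wingbeat frequency; cross-correlation of two
neighbors' composites gives their temporal phase offset, and
subtracting the phase implied by their along-track separation (in
wingbeat wavelengths) gives the spatial phase offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import circstats
from .flock_io import DEFAULT_FRAME_RATE

logger = logging.getLogger(__name__)

DEFAULT_FFT_LEN = 128
DEFAULT_BAND_HZ = (2.0, 15.0)
MIN_OVERLAP_FRAMES = 20
# No-wingbeat criterion: the peak must carry ~25x the median in-band
# power (5x in magnitude).  For white noise over ~50 independent bins the
# expected max/median power ratio is ~7, so false detections are rare.
PEAK_SNR = 5.0

__all__ = [
    "composite_wingbeat_signal",
    "wingbeat_frequency",
    "temporal_phase",
    "spatial_phase",
    "phase_pairs",
    "synchronization_test",
    "PhasePair",
    "DegenerateSignalError",
]


class DegenerateSignalError(ValueError):
    pass


def _standardize(x: np.ndarray, window: int) -> np.ndarray:
    """Zero mean, unit variance over a centred rolling window."""
    s = pd.Series(x)
    mu = s.rolling(window, center=True, min_periods=1).mean()
    sd = s.rolling(window, center=True, min_periods=1).std().replace(0, np.nan)
    out = (s - mu) / sd
    return out.fillna(0.0).to_numpy()


def composite_wingbeat_signal(
    bbox: pd.DataFrame,
    frame_rate: float = DEFAULT_FRAME_RATE,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Per-bird composite oscillation score from bounding-box components.

    Components per camera: height, 1/width, detrended top-left x, and
    the negated detrended top-left y (detrending by the rolling mean;
    the negation plays the role of an "inverse" for a zero-mean
    quantity).  Each component is standardized over a rolling window of
    ``window_s`` seconds, then averaged across components and cameras.
    Requires >= 20 frames per bird; a bird whose components are all
    constant raises :class:`DegenerateSignalError`.

    Returns a DataFrame (bird_id, frame, composite).
    """
    window = max(3, int(round(window_s * frame_rate)))
    out = []
    for (bird, _cam), sub in bbox.groupby(["bird_id", "camera_id"]):
        sub = sub.sort_values("frame")
        if len(sub) < MIN_OVERLAP_FRAMES:
            continue
        h = sub["height_px"].to_numpy(dtype=float)
        w = sub["width_px"].to_numpy(dtype=float)
        tx = sub["topleft_x_px"].to_numpy(dtype=float)
        ty = sub["topleft_y_px"].to_numpy(dtype=float)
        if max(np.ptp(h), np.ptp(w), np.ptp(tx), np.ptp(ty)) == 0:
            raise DegenerateSignalError(f"bird {bird}: all bounding-box components constant")
        with np.errstate(divide="ignore"):
            inv_w = np.where(w != 0, 1.0 / w, 0.0)
        comps = np.column_stack(
            [
                _standardize(h, window),
                _standardize(inv_w, window),
                _standardize(tx - pd.Series(tx).rolling(window, center=True, min_periods=1).mean(), window),
                _standardize(-(ty - pd.Series(ty).rolling(window, center=True, min_periods=1).mean()), window),
            ]
        )
        out.append(
            pd.DataFrame(
                {"bird_id": bird, "frame": sub["frame"].to_numpy(),
                 "composite": comps.mean(axis=1)}
            )
        )
    if not out:
        return pd.DataFrame(columns=["bird_id", "frame", "composite"])
    # average across cameras at matching frames
    allc = pd.concat(out, ignore_index=True)
    return allc.groupby(["bird_id", "frame"], as_index=False)["composite"].mean()


def _bandpass(x: np.ndarray, frame_rate: float, band) -> np.ndarray:
    nyq = frame_rate / 2.0
    lo, hi = band[0] / nyq, min(band[1] / nyq, 0.99)
    sos = sps.butter(2, [lo, hi], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def wingbeat_frequency(
    composite: np.ndarray,
    frame_rate: float = DEFAULT_FRAME_RATE,
    fft_len: int = DEFAULT_FFT_LEN,
    band_hz=DEFAULT_BAND_HZ,
    refine: bool = True,
) -> float | None:
    """Dominant in-band frequency of a composite signal, in Hz.

    The signal is band-pass filtered (4th-order zero-phase Butterworth)
    and its magnitude spectrum taken with an ``fft_len``-point FFT
    (Welch-averaged for longer signals, zero-padded for shorter ones,
    down to ``fft_len / 2`` samples).  The peak bin within ``band_hz``
    is refined by parabolic interpolation of the three surrounding
    log-magnitudes.  Returns ``None`` when no in-band peak rises above
    the noise floor (no detectable wingbeat).
    """
    x = np.asarray(composite, dtype=float)
    if x.size < fft_len // 2:
        raise ValueError(f"signal too short: {x.size} < {fft_len // 2}")
    x = x - x.mean()
    if np.ptp(x) == 0:
        return None
    x = _bandpass(x, frame_rate, band_hz)
    if x.size >= fft_len:
        freqs, psd = sps.welch(x, fs=frame_rate, nperseg=fft_len,
                               noverlap=fft_len // 2, nfft=fft_len)
        mag = np.sqrt(psd)
    else:
        spec = np.fft.rfft(x, n=fft_len)
        freqs = np.fft.rfftfreq(fft_len, d=1.0 / frame_rate)
        mag = np.abs(spec)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        return None
    band_mag = np.where(in_band, mag, 0.0)
    k = int(np.argmax(band_mag))
    if mag[k] < PEAK_SNR * np.median(mag[in_band]):
        return None
    f = freqs[k]
    if refine and 0 < k < mag.size - 1 and mag[k - 1] > 0 and mag[k + 1] > 0:
        la, lb, lc = np.log(mag[k - 1 : k + 2])
        denom = la - 2 * lb + lc
        if denom < 0:
            f = f + 0.5 * (la - lc) / denom * (freqs[1] - freqs[0])
    return float(f)


def temporal_phase(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    wingbeat_duration_s: float,
    frame_rate: float = DEFAULT_FRAME_RATE,
):
    """Temporal phase offset of b relative to a, in [0, 2*pi).

    The lag of maximum cross-correlation, restricted to within one
    wingbeat duration ``d``, is converted to phase as
    ``2*pi * ((lag mod d) / d)``.  Returns ``(phase_rad, lag_s)``.
    """
    a = np.asarray(sig_a, float)
    b = np.asarray(sig_b, float)
    if a.size != b.size:
        raise ValueError("signals must share a frame window")
    if a.size < MIN_OVERLAP_FRAMES:
        raise ValueError(f"overlap {a.size} < {MIN_OVERLAP_FRAMES} frames")
    d = wingbeat_duration_s
    if d <= 0:
        raise ValueError("wingbeat duration must be positive")
    a = (a - a.mean()) / (a.std() or 1.0)
    b = (b - b.mean()) / (b.std() or 1.0)
    cc = sps.correlate(b, a, mode="full")
    lags = sps.correlation_lags(b.size, a.size, mode="full")
    ok = np.abs(lags / frame_rate) < d
    k = np.flatnonzero(ok)[np.argmax(cc[ok])]
    lag_frames = float(lags[k])
    # sub-frame refinement: parabola through the peak and its neighbours
    if 0 < k < cc.size - 1:
        ya, yb, yc = cc[k - 1 : k + 2]
        denom = ya - 2 * yb + yc
        if denom < 0:
            lag_frames += 0.5 * (ya - yc) / denom
    lag = lag_frames / frame_rate
    phase = 2 * np.pi * ((lag % d) / d)
    return float(phase % (2 * np.pi)), lag


def spatial_phase(temporal_phase_rad: float, along_track_separation_m: float,
                  wavelength_m: float) -> float:
    """Spatial phase offset: the temporal phase minus the phase implied
    by the along-track separation in wingbeat wavelengths
    (wavelength = airspeed x wingbeat duration), wrapped to [0, 2*pi)."""
    if wavelength_m <= 0:
        raise ValueError("wavelength must be positive")
    return float(
        (temporal_phase_rad - 2 * np.pi * along_track_separation_m / wavelength_m)
        % (2 * np.pi)
    )


@dataclass
class PhasePair:
    focal_id: str
    neighbor_id: str
    overlap_frames: int
    freq_focal_hz: float
    freq_neighbor_hz: float
    wingbeat_duration_s: float
    lag_s: float
    temporal_phase_rad: float
    along_track_separation_m: float
    wavelength_m: float
    spatial_phase_rad: float


def phase_pairs(
    offsets: pd.DataFrame,
    composites: pd.DataFrame,
    airspeed_by_bird: dict,
    frame_rate: float = DEFAULT_FRAME_RATE,
    min_overlap: int = MIN_OVERLAP_FRAMES,
    max_freq_ratio_dev: float = 0.15,
) -> pd.DataFrame:
    """Temporal and spatial phase offsets for nearest-neighbor pairs.

    Pairs are the unique (focal, neighbor) combinations in ``offsets``;
    a pair is retained when both birds' composite signals overlap for at
    least ``min_overlap`` frames and their wingbeat frequencies agree
    within ``max_freq_ratio_dev``.  The along-track separation is the
    mean front-back offset of the pair over its rows in ``offsets``;
    wavelength is the focal bird's airspeed times the pair's mean
    wingbeat duration.
    """
    sig = {b: sub.set_index("frame")["composite"]
           for b, sub in composites.groupby("bird_id")}
    rows = []
    pairs = offsets.groupby(["focal_id", "neighbor_id"])["front_back"].mean()
    for (fa, fb_id), sep in pairs.items():
        if fa not in sig or fb_id not in sig:
            continue
        common = sig[fa].index.intersection(sig[fb_id].index)
        if len(common) < min_overlap:
            continue
        xa = sig[fa].loc[common].to_numpy()
        xb = sig[fb_id].loc[common].to_numpy()
        f1 = wingbeat_frequency(xa, frame_rate) if xa.size >= DEFAULT_FFT_LEN // 2 else None
        f2 = wingbeat_frequency(xb, frame_rate) if xb.size >= DEFAULT_FFT_LEN // 2 else None
        if f1 is None or f2 is None:
            continue
        if abs(f1 - f2) / max(f1, f2) > max_freq_ratio_dev:
            continue
        d = 2.0 / (f1 + f2)
        phase, lag = temporal_phase(xa, xb, d, frame_rate)
        v = airspeed_by_bird.get(fa)
        if v is None or v <= 0:
            continue
        lam = v * d
        sp_phase = spatial_phase(phase, float(sep), lam)
        rows.append(PhasePair(fa, fb_id, len(common), f1, f2, d, lag, phase,
                              float(sep), lam, sp_phase))
    return pd.DataFrame([r.__dict__ for r in rows])


def synchronization_test(phases_rad, rng=None) -> dict:
    """Rayleigh test of phase concentration.

    Returns ``{"n", "Z", "p"}``.  Below ten samples the analytic
    approximation is unreliable, so an exact permutation-style p-value is
    substituted via seeded Monte Carlo and a warning logged.
    """
    a = np.asarray(phases_rad, dtype=float)
    n = a.size
    z, p = circstats.rayleigh(a)
    if n < 10:
        logger.warning("synchronization test on n=%d: Monte-Carlo p substituted", n)
        gen = np.random.default_rng(rng if rng is not None else 0)
        sims = gen.uniform(0, 2 * np.pi, size=(10_000, n))
        rbar = np.abs(np.exp(1j * sims).mean(axis=1))
        z_null = n * rbar**2
        p = float((np.sum(z_null >= z) + 1) / (len(z_null) + 1))
    return {"n": int(n), "Z": float(z), "p": float(p)}
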