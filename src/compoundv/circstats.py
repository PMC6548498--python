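"""Circular statistics shared by the flock-analysis modules.

Angles are radians throughout; helpers accept optional non-negative
weights.  The module provides the mean resultant vector, the Rayleigh
and Rao spacing tests of uniformity, the Jammalamadaka–SenGupta
circular–circular correlation, and a von Mises kernel density estimate
of the modal direction.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0

from ._rao_table import RAO_ALPHAS, RAO_NS, RAO_QUANTILES

__all__ = [
    "wrap_angles",
    "circ_mean",
    "resultant_length",
    "rayleigh",
    "rao_spacing",
    "circ_corr",
    "circ_mode",
]


def wrap_angles(angles):
    """Wrap angles into [0, 2*pi). Idempotent."""
    out = np.mod(np.asarray(angles, dtype=float), 2.0 * np.pi)
    # tiny negatives round up to exactly 2*pi under fmod
    return np.where(out >= 2.0 * np.pi, 0.0, out)


def _check_sample(angles, min_n):
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.ndim != 1:
        raise ValueError("angles must be one-dimensional")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} angles, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return wrap_angles(a)


def circ_mean(angles, weights=None):
    """Circular mean direction in [0, 2*pi)."""
    a = _check_sample(angles, 1)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return float(np.mod(np.arctan2(np.sum(w * np.sin(a)), np.sum(w * np.cos(a))), 2 * np.pi))


def resultant_length(angles, weights=None):
    """Mean resultant length R-bar in [0, 1]."""
    a = _check_sample(angles, 1)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    c = np.sum(w * np.cos(a)) / w.sum()
    s = np.sum(w * np.sin(a)) / w.sum()
    return float(np.hypot(c, s))


def rayleigh(angles):
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p)`` with Z = n * R-bar**2 and the standard finite-n
    series approximation for the p-value (Zar 1999, eq. 27.4):

        p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))

    where Rn = n * R-bar.
    """
    a = _check_sample(angles, 3)
    n = a.size
    rbar = resultant_length(a)
    z = n * rbar**2
    rn = n * rbar
    p = float(np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n**2 - rn**2)) - (1.0 + 2 * n)))
    return float(z), min(p, 1.0)


def rao_spacing_statistic(angles):
    """Rao spacing statistic U (radians): half the total deviation of the
    sorted arc gaps from the uniform gap 2*pi/n."""
    a = np.sort(_check_sample(angles, 4))
    n = a.size
    gaps = np.diff(a, append=a[0] + 2 * np.pi)
    return float(0.5 * np.sum(np.abs(gaps - 2 * np.pi / n)))


def rao_spacing(angles, rng=None, n_mc=10_000):
    """Rao's spacing test of circular uniformity.

    Returns ``(U, p)``.  U is in radians.  The p-value is interpolated
    from an embedded quantile table of the null distribution (derived by
    large-scale simulation; see docs/methods.md); for sample sizes
    outside the table a seeded Monte-Carlo null of ``n_mc`` replicates
    is simulated instead.
    """
    a = _check_sample(angles, 4)
    n = a.size
    u = rao_spacing_statistic(a)
    if RAO_NS[0] <= n <= RAO_NS[-1]:
        quants = np.empty(len(RAO_ALPHAS))
        for j in range(len(RAO_ALPHAS)):
            quants[j] = np.interp(n, RAO_NS, RAO_QUANTILES[:, j])
        # quants ascend in U as alpha descends; interpolate p from the table
        p = float(np.interp(u, quants, RAO_ALPHAS))
        return u, float(np.clip(p, RAO_ALPHAS[-1] / 2, 1.0))
    rng = np.random.default_rng(rng if rng is not None else 0)
    sims = np.sort(rng.uniform(0, 2 * np.pi, size=(n_mc, n)), axis=1)
    gaps = np.diff(sims, axis=1)
    last = 2 * np.pi - (sims[:, -1] - sims[:, 0])
    total = np.sum(np.abs(gaps - 2 * np.pi / n), axis=1) + np.abs(last - 2 * np.pi / n)
    u_null = 0.5 * total
    p = float((np.sum(u_null >= u) + 1) / (n_mc + 1))
    return u, p


def rao_null_quantile(n, alpha, n_reps=100_000, rng=None):
    """Upper-tail critical value of the Rao spacing statistic by simulation."""
    rng = np.random.default_rng(rng if rng is not None else 0)
    out = np.empty(n_reps)
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        sims = np.sort(rng.uniform(0, 2 * np.pi, size=(m, n)), axis=1)
        gaps = np.diff(sims, axis=1)
        last = 2 * np.pi - (sims[:, -1] - sims[:, 0])
        total = np.sum(np.abs(gaps - 2 * np.pi / n), axis=1) + np.abs(last - 2 * np.pi / n)
        out[done : done + m] = 0.5 * total
        done += m
    return float(np.quantile(out, 1.0 - alpha))


def circ_corr(a, b):
    """Jammalamadaka–SenGupta circular–circular correlation.

    Returns ``(r, t, p)`` where t is the asymptotic test statistic
    (standard normal under independence) and p is two-sided.
    """
    a = _check_sample(a, 5)
    b = _check_sample(b, 5)
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    sa = np.sin(a - circ_mean(a))
    sb = np.sin(b - circ_mean(b))
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        raise ValueError("undefined correlation: zero resultant deviation in a sample")
    r = float(np.sum(sa * sb) / denom)
    n = a.size
    l20 = np.mean(sa**2)
    l02 = np.mean(sb**2)
    l22 = np.mean(sa**2 * sb**2)
    if l22 <= 0:
        raise ValueError("undefined test statistic")
    t = float(np.sqrt(n * l20 * l02 / l22) * r)
    from scipy.stats import norm

    p = float(2 * norm.sf(abs(t)))
    return r, t, p


def circ_mode(angles, concentration=50.0, grid_deg=1.0, weights=None):
    """Modal direction from a von Mises kernel density estimate.

    A von Mises kernel of concentration ``concentration`` (default 50,
    roughly a 4.6-degree sd) is evaluated on a regular grid (default 1
    degree) and the argmax direction returned, together with the mean
    resultant length as a dispersion caveat.

    Returns ``(mode_rad, resultant)``.
    """
    a = _check_sample(angles, 5)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    grid = np.arange(0.0, 2 * np.pi, np.deg2rad(grid_deg))
    dens = np.exp(concentration * np.cos(grid[:, None] - a[None, :])) @ w
    dens /= 2 * np.pi * i0(concentration) * w.sum()
    return float(grid[int(np.argmax(dens))]), resultant_length(a, weights=w)
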