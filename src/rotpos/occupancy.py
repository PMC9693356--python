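"""Occupancy prediction from energy tracks.

Model #1: Boltzmann positioning scores smoothed with a Gaussian kernel
over the 147-bp nucleosome footprint.  Model #2: a Gabor-like wave packet
correlated against the positioning scores gives a signed rotational
positioning index (nucleosome center score); the upper contour of that
oscillating landscape, fitted through its local maxima, is the occupancy.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import EmptyTrackError, InvalidArgumentError, InvalidStateError
from .track import (
    EnergyTrack,
    OccupancyTrack,
    PositioningScoreTrack,
    RPITrack,
    Track,
    correlate_kernel,
)

__all__ = [
    "KERNEL_HALF_WIDTH",
    "GAUSSIAN_SD",
    "DEFAULT_WAVE_PERIOD",
    "gaussian_weights",
    "wave_packet",
    "positioning_scores",
    "occupancy_model1",
    "rotational_positioning_index",
    "envelope_occupancy",
    "local_maxima",
]

KERNEL_HALF_WIDTH = 73  # k in [-73, 73]: the 147-bp footprint
GAUSSIAN_SD = 20.0
DEFAULT_WAVE_PERIOD = 9.906  # bp; ~10-bp helical repeat
DEFAULT_SIGMA2 = 400.0  # variance of the wave-packet Gaussian envelope


def _offsets() -> np.ndarray:
    return np.arange(-KERNEL_HALF_WIDTH, KERNEL_HALF_WIDTH + 1)


def gaussian_weights() -> np.ndarray:
    """w_k = exp(-(1/2)(k/20)^2) for k in [-73, 73]."""
    k = _offsets()
    return np.exp(-0.5 * (k / GAUSSIAN_SD) ** 2)


def wave_packet(sigma2: float = DEFAULT_SIGMA2, period: float = DEFAULT_WAVE_PERIOD) -> np.ndarray:
    """Complex wave packet f(k) = exp(-k^2/(2 sigma2)) * exp(i 2 pi k / period)."""
    if period <= 0:
        raise InvalidArgumentError("period must be positive")
    if sigma2 <= 0:
        raise InvalidArgumentError("sigma2 must be positive")
    k = _offsets()
    return np.exp(-(k**2) / (2.0 * sigma2)) * np.exp(2j * np.pi * k / period)


def positioning_scores(track: EnergyTrack, beta: float = 1.0) -> PositioningScoreTrack:
    """Boltzmann score p_i = exp(-beta * E_i) on a unit-range energy track."""
    if not getattr(track, "normalized", False):
        raise InvalidStateError("positioning scores require a unit-range normalized energy track")
    return PositioningScoreTrack(
        chrom=track.chrom,
        start=track.start,
        values=np.exp(-beta * track.values),
        beta=beta,
        source_kind=track.kind,
    )


def occupancy_model1(p: Track) -> OccupancyTrack:
    """Gaussian-kernel occupancy: occ_i = sum_{k=-73}^{73} w_k p_{i+k}."""
    start, values = correlate_kernel(p, gaussian_weights())
    if not np.isfinite(values).any():
        raise EmptyTrackError("no position has the full 147 defined neighbors")
    return OccupancyTrack(chrom=p.chrom, start=start, values=values, model="model1")


def rotational_positioning_index(
    p: Track,
    sigma2: float = DEFAULT_SIGMA2,
    period: float = DEFAULT_WAVE_PERIOD,
    store_complex: bool = False,
) -> RPITrack:
    """Real part of the inner product between p and the wave packet.

    High values mark positions whose surrounding 147 scores oscillate in
    phase with the packet — candidate nucleosome centers; the value is
    also called the nucleosome center score.
    """
    if isinstance(p, PositioningScoreTrack) and p.source_kind != "bending":
        warnings.warn(
            f"rotational positioning index is defined on bending energy; "
            f"got scores derived from {p.source_kind!r}",
            stacklevel=2,
        )
    f = wave_packet(sigma2, period)
    start, real = correlate_kernel(p, f.real)
    imag = None
    if store_complex:
        _, imag = correlate_kernel(p, f.imag)
    return RPITrack(
        chrom=p.chrom,
        start=start,
        values=real,
        sigma2=sigma2,
        period=period,
        imag_values=imag,
    )


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima: strict 3-point peaks; a flat plateau with
    strictly lower neighbors on both sides counts once, at its midpoint
    (left-of-middle for even plateau lengths).  Endpoints never qualify.
    """
    n = len(values)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if i > 0 and j < n - 1 and values[i - 1] < values[i] and values[j + 1] < values[i]:
            peaks.append((i + j) // 2)
        i = j + 1
    return np.asarray(peaks, dtype=int)


def envelope_occupancy(rpi: RPITrack) -> OccupancyTrack:
    """Model #2: upper contour of the rotational positioning index.

    Monotone-preserving piecewise-cubic interpolation through the local
    maxima of the index, held constant beyond the outermost maxima and
    floored at zero.  With fewer than two maxima the result degenerates
    to the constant max(RPI, 0) and is flagged.
    """
    mask = rpi.defined_mask
    if not mask.any():
        raise EmptyTrackError("rotational positioning index track has no defined values")
    idx = np.flatnonzero(mask)
    first, last = idx[0], idx[-1]
    if not mask[first : last + 1].all():
        raise InvalidStateError("envelope fitting requires a contiguous defined interval")
    seg = rpi.values[first : last + 1]

    knots = local_maxima(seg)
    if len(knots) < 2:
        warnings.warn("fewer than 2 local maxima; returning constant envelope", stacklevel=2)
        const = max(float(seg.max()), 0.0)
        values = np.full_like(rpi.values, np.nan)
        values[first : last + 1] = const
        return OccupancyTrack(
            chrom=rpi.chrom, start=rpi.start, values=values, model="model2", degenerate=True
        )

    interp = PchipInterpolator(knots, seg[knots], extrapolate=False)
    x = np.arange(len(seg), dtype=float)
    env = interp(x)
    env[: knots[0]] = seg[knots[0]]  # hold boundary knot values outside the span
    env[knots[-1] + 1 :] = seg[knots[-1]]
    env = np.maximum(env, 0.0)

    values = np.full_like(rpi.values, np.nan)
    values[first : last + 1] = env
    return OccupancyTrack(chrom=rpi.chrom, start=rpi.start, values=values, model="model2")
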