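"""Per-base genomic tracks.

A :class:`Track` is a dense, 0-based vector of float values anchored at
``start`` on one sequence.  Undefined positions are ``NaN``; the defined
region of derived tracks (sliding-window statistics, kernel correlations)
shrinks accordingly at the edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import EmptyTrackError, InvalidArgumentError

__all__ = [
    "Track",
    "EnergyTrack",
    "PositioningScoreTrack",
    "OccupancyTrack",
    "RPITrack",
    "StrengthTrack",
    "NCPTrack",
    "correlate_kernel",
]


@dataclass
class Track:
    """A per-base value vector on one named sequence.

    Parameters
    ----------
    chrom : str
        Sequence name the values are anchored on.
    start : int
        0-based position of ``values[0]``.
    values : ndarray
        Float vector; ``NaN`` marks undefined positions.
    """

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("track values must be 1-dimensional")
        if self.start < 0:
            raise InvalidArgumentError("track start must be non-negative")

    # -- geometry ---------------------------------------------------------
    @property
    def end(self) -> int:
        """0-based exclusive end coordinate."""
        return self.start + len(self.values)

    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())

    def defined_span(self) -> tuple[int, int]:
        """(first, last) defined genomic positions; raises if none."""
        idx = np.flatnonzero(self.defined_mask)
        if idx.size == 0:
            raise EmptyTrackError(f"track {self.chrom!r} has no defined values")
        return self.start + int(idx[0]), self.start + int(idx[-1])

    def value_at(self, pos: int) -> float:
        """Value at genomic position ``pos`` (NaN outside the track)."""
        if pos < self.start or pos >= self.end:
            return float("nan")
        return float(self.values[pos - self.start])

    def window(self, start: int, size: int) -> np.ndarray:
        """Extract ``size`` values beginning at genomic ``start``.

        Positions outside the track come back as NaN, so callers can do
        their own count bookkeeping.
        """
        out = np.full(size, np.nan)
        lo = max(start, self.start)
        hi = min(start + size, self.end)
        if hi > lo:
            out[lo - start : hi - start] = self.values[lo - self.start : hi - self.start]
        return out

    def shifted(self, offset: int) -> "Track":
        """Same values anchored ``offset`` bp to the right."""
        return replace(self, start=self.start + offset)


@dataclass
class EnergyTrack(Track):
    """Sliding-window deformation energy in kT per base-pair step."""

    kind: str = "bending"
    window_len: int = 101
    normalized: bool = False
    emin: Optional[float] = None
    emax: Optional[float] = None


@dataclass
class PositioningScoreTrack(Track):
    """Boltzmann positioning score p_i = exp(-beta * E_i)."""

    beta: float = 1.0
    source_kind: str = "bending"


@dataclass
class OccupancyTrack(Track):
    """Non-negative predicted or experimental occupancy."""

    model: str = "model1"
    degenerate: bool = False  # set when an envelope had < 2 knots


@dataclass
class RPITrack(Track):
    """Rotational positioning index (nucleosome center score)."""

    sigma2: float = 400.0
    period: float = 9.906
    imag_values: Optional[np.ndarray] = None


@dataclass
class StrengthTrack(Track):
    """Rotational-strength statistic (sliding std or FFT amplitude)."""

    stat: str = "std"
    window_len: int = 147
    period: Optional[float] = None


@dataclass
class NCPTrack(Track):
    """Experimental per-base nucleosome-center-positioning scores (>= 0)."""


def correlate_kernel(
    track: Track,
    kernel: np.ndarray,
    require_full: bool = True,
) -> tuple[int, np.ndarray]:
    """Centered sliding correlation of a track with an odd-length kernel.

    Returns ``(start, out)`` where ``out[i]`` corresponds to genomic
    position ``start + i`` and equals ``sum_k kernel[K+k] * v[center+k]``
    for ``k in [-K, K]``.  Windows touching an undefined (NaN) value are
    NaN when ``require_full`` is set.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or len(kernel) % 2 != 1:
        raise InvalidArgumentError("kernel must be 1-D with odd length")
    half = (len(kernel) - 1) // 2
    if len(track.values) < len(kernel):
        raise EmptyTrackError(
            f"track span {len(track.values)} shorter than kernel {len(kernel)}"
        )
    filled = np.nan_to_num(track.values, nan=0.0)
    out = np.correlate(filled, kernel, mode="valid")
    if require_full:
        cnt = np.correlate(
            track.defined_mask.astype(float), np.ones(len(kernel)), mode="valid"
        )
        out = np.where(cnt > len(kernel) - 0.5, out, np.nan)
    return track.start + half, out
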