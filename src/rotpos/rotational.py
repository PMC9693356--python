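"""Rotational-positioning strength statistics and dyad-prediction scoring."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyTrackError, InvalidArgumentError
from .track import EnergyTrack, RPITrack, StrengthTrack, Track

__all__ = [
    "rotational_strength_std",
    "periodic_power_fft",
    "bending_minimum_score",
    "predict_dyad",
    "evaluate_dyads",
    "DyadEvaluation",
]

DEFAULT_STD_WINDOW = 147
DEFAULT_FFT_WINDOW = 50
DEFAULT_FFT_PERIOD = 10.0


def _sliding_full_windows(track: Track, window: int):
    """Yield (center_start, matrix-free sliding sums) helpers.

    Returns (start, filled, mask, count) where ``filled`` has NaN replaced
    by 0 and ``count`` is the per-window number of defined values.
    """
    if len(track.values) < window:
        raise EmptyTrackError(f"track span {len(track.values)} shorter than window {window}")
    filled = np.nan_to_num(track.values, nan=0.0)
    mask = track.defined_mask.astype(float)
    count = np.correlate(mask, np.ones(window), mode="valid")
    start = track.start + window // 2
    return start, filled, mask, count


def rotational_strength_std(track: EnergyTrack, window: int = DEFAULT_STD_WINDOW) -> StrengthTrack:
    """Population standard deviation of energies in a sliding window.

    The window is centered on each position (an even window extends one
    bp further left of center).  Values are computed over the defined
    energies in the window; positions with fewer than 2 defined
    neighbors are NaN.
    """
    if window < 2:
        raise InvalidArgumentError(f"window must be >= 2, got {window}")
    start, filled, mask, count = _sliding_full_windows(track, window)
    s1 = np.correlate(filled, np.ones(window), mode="valid")
    s2 = np.correlate(filled**2, np.ones(window), mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / count
        var = s2 / count - mean**2
    var = np.where(count >= 2, np.maximum(var, 0.0), np.nan)
    return StrengthTrack(
        chrom=track.chrom, start=start, values=np.sqrt(var), stat="std", window_len=window
    )


def periodic_power_fft(
    track: EnergyTrack,
    window: int = DEFAULT_FFT_WINDOW,
    period: float = DEFAULT_FFT_PERIOD,
) -> StrengthTrack:
    """Magnitude of the windowed discrete-Fourier component near 1/period.

    The frequency bin is ``round(window / period)`` cycles per window;
    because that bin is non-zero, mean subtraction within the window does
    not change the magnitude and is therefore implicit.  Windows touching
    an undefined value are NaN.
    """
    if period <= 0:
        raise InvalidArgumentError("period must be positive")
    if period >= window:
        raise InvalidArgumentError(f"period ({period}) must be < window ({window})")
    if window < 2 * period:
        raise InvalidArgumentError(f"window ({window}) must be >= 2*period ({2 * period})")
    b = int(round(window / period))
    t = np.arange(window)
    cos_k = np.cos(2.0 * np.pi * b * t / window)
    sin_k = np.sin(2.0 * np.pi * b * t / window)
    start, filled, mask, count = _sliding_full_windows(track, window)
    # np.correlate(a, v)[j] = sum_m a[j+m] v[m]
    re = np.correlate(filled, cos_k, mode="valid")
    im = np.correlate(filled, sin_k, mode="valid")
    mag = np.hypot(re, im)
    mag = np.where(count > window - 0.5, mag, np.nan)
    return StrengthTrack(
        chrom=track.chrom, start=start, values=mag, stat="fft", window_len=window, period=period
    )


def bending_minimum_score(bend: EnergyTrack) -> Track:
    """Negated bending energy: a center score whose argmax is the energy
    minimum — the raw-bending baseline for dyad prediction."""
    return Track(chrom=bend.chrom, start=bend.start, values=-bend.values)


def predict_dyad(rpi: Track, center: int, half_width: int = 5) -> Optional[int]:
    """Position of the highest center score in [center-hw, center+hw].

    Leftmost wins on ties.  Returns None when any position in the search
    interval is undefined (the dyad is unevaluable).
    """
    if half_width < 0:
        raise InvalidArgumentError("half_width must be non-negative")
    w = rpi.window(center - half_width, 2 * half_width + 1)
    if not np.isfinite(w).all():
        return None
    return center - half_width + int(np.argmax(w))


@dataclass
class DyadEvaluation:
    """Per-dyad signed prediction offsets and the summary fraction."""

    dyads: np.ndarray
    predicted: np.ndarray
    offsets: np.ndarray  # predicted - dyad, evaluable dyads only
    n_evaluated: int
    n_skipped: int
    half_width: int
    tol: int

    @property
    def fraction_within(self) -> float:
        if self.n_evaluated == 0:
            return float("nan")
        return float(np.mean(np.abs(self.offsets) <= self.tol))

    def summary(self) -> str:
        return (
            f"{np.sum(np.abs(self.offsets) <= self.tol)}/{self.n_evaluated} dyads "
            f"within {self.tol} bp (fraction {self.fraction_within:.3f}); "
            f"{self.n_skipped} unevaluable"
        )

    def rows(self):
        """(dyad, predicted, offset) rows for TSV export."""
        return list(zip(self.dyads.tolist(), self.predicted.tolist(), self.offsets.tolist()))


def evaluate_dyads(
    rpi: Track,
    dyads: Sequence[int],
    half_width: int = 5,
    tol: int = 2,
) -> DyadEvaluation:
    """Score predicted vs. reference nucleosome centers.

    For each reference dyad the predicted center is the argmax of the
    score track within ``half_width`` bp; the summary is the fraction of
    evaluable dyads with |predicted - reference| <= ``tol``.
    """
    kept, preds, offs = [], [], []
    skipped = 0
    for d in dyads:
        p = predict_dyad(rpi, int(d), half_width)
        if p is None:
            skipped += 1
            continue
        kept.append(int(d))
        preds.append(p)
        offs.append(p - int(d))
    if not kept:
        raise EmptyTrackError(
            f"no evaluable dyads ({skipped} skipped: score track undefined in their windows)"
        )
    return DyadEvaluation(
        dyads=np.asarray(kept),
        predicted=np.asarray(preds),
        offsets=np.asarray(offs),
        n_evaluated=len(kept),
        n_skipped=skipped,
        half_width=half_width,
        tol=tol,
    )
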