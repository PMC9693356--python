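"""Processing of experimental nucleosome-center (NCP) score tracks.

Covers greedy dyad calling with a minimum-spacing rule and the
center-weighted occupancy map (Gaussian kernel over the 147-bp
footprint).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, ParseError
from .occupancy import KERNEL_HALF_WIDTH, gaussian_weights
from .track import NCPTrack, OccupancyTrack, Track

__all__ = [
    "DyadCall",
    "read_ncp",
    "call_dyads",
    "center_weighted_occupancy",
    "REDUNDANT_MIN_DIST",
    "UNIQUE_MIN_DIST",
]

REDUNDANT_MIN_DIST = 10
# Non-overlapping-nucleosome convention of the chemical-mapping literature,
# not a value fixed by the redundant-map rule.
UNIQUE_MIN_DIST = 107


@dataclass(frozen=True)
class DyadCall:
    """One called nucleosome center."""

    chrom: str
    pos: int  # 0-based
    score: float
    map_type: str = "redundant"


def read_ncp(path, dialect: str = "bedgraph", chrom: Optional[str] = None) -> NCPTrack:
    """Read a per-base NCP score track from bedGraph or wig.

    Uncovered positions inside the track span are score 0.  Negative
    scores are rejected; an empty file yields an empty track with a
    warning.
    """
    from .io import read_tracks  # local import: io depends on track only

    tracks = read_tracks(path, dialect=dialect, fill=0.0)
    if not tracks:
        warnings.warn(f"{path}: empty NCP file", stacklevel=2)
        return NCPTrack(chrom=chrom or "NA", start=0, values=np.empty(0))
    if chrom is None:
        if len(tracks) > 1:
            raise InvalidArgumentError(
                f"{path} contains {len(tracks)} sequences; pass chrom= to select one"
            )
        chrom = next(iter(tracks))
    try:
        t = tracks[chrom]
    except KeyError:
        raise InvalidArgumentError(f"{path}: no data for sequence {chrom!r}") from None
    vals = np.nan_to_num(t.values, nan=0.0)
    if (vals < 0).any():
        raise ParseError(f"{path}: negative NCP scores are not allowed")
    return NCPTrack(chrom=t.chrom, start=t.start, values=vals)


def call_dyads(
    ncp: NCPTrack,
    min_dist: int = REDUNDANT_MIN_DIST,
    map_type: Optional[str] = None,
) -> list[DyadCall]:
    """Greedy dyad calling under a minimum center-to-center spacing.

    Repeatedly accept the highest-scoring remaining position and discard
    every position strictly within ``min_dist`` of it (a distance of
    exactly ``min_dist`` is allowed).  Ties break by score descending,
    then position ascending.  Zero-score positions are never called.
    """
    if min_dist < 1:
        raise InvalidArgumentError(f"min_dist must be >= 1, got {min_dist}")
    if map_type is None:
        map_type = "redundant" if min_dist < UNIQUE_MIN_DIST else "unique"
    vals = np.nan_to_num(ncp.values, nan=0.0)
    cand = np.flatnonzero(vals > 0)
    if cand.size == 0:
        return []
    order = np.lexsort((cand, -vals[cand]))  # score desc, then position asc
    blocked = np.zeros(len(vals), dtype=bool)
    calls: list[DyadCall] = []
    for i in cand[order]:
        if blocked[i]:
            continue
        calls.append(
            DyadCall(chrom=ncp.chrom, pos=ncp.start + int(i), score=float(vals[i]), map_type=map_type)
        )
        lo = max(0, i - min_dist + 1)
        hi = min(len(vals), i + min_dist)
        blocked[lo:hi] = True
    calls.sort(key=lambda c: c.pos)
    return calls


def center_weighted_occupancy(
    dyads: Optional[Sequence[DyadCall] | Iterable[int]] = None,
    ncp: Optional[NCPTrack] = None,
    chrom: Optional[str] = None,
) -> OccupancyTrack:
    """Gaussian center-weighted occupancy from dyad calls or a raw track.

    occ_i = sum over dyads of score * exp(-((i - dyad)/20)^2 / 2),
    restricted to |i - dyad| <= 73.  Bare position lists get score 1.
    """
    if (dyads is None) == (ncp is None):
        raise InvalidArgumentError("provide exactly one of dyads= or ncp=")
    if ncp is not None:
        base = ncp
    else:
        dyads = list(dyads)
        if not dyads:
            raise InvalidArgumentError("empty dyad list")
        if isinstance(dyads[0], DyadCall):
            positions = [d.pos for d in dyads]
            scores = [d.score for d in dyads]
            chrom = chrom or dyads[0].chrom
        else:
            positions = [int(d) for d in dyads]
            scores = [1.0] * len(positions)
            chrom = chrom or "NA"
        lo = min(positions)
        vals = np.zeros(max(positions) - lo + 1)
        for p, s in zip(positions, scores):
            vals[p - lo] += s
        base = Track(chrom=chrom, start=lo, values=vals)
    filled = np.nan_to_num(base.values, nan=0.0)
    occ = np.convolve(filled, gaussian_weights(), mode="full")
    start = base.start - KERNEL_HALF_WIDTH
    if start < 0:  # clip the kernel tail that would fall before position 0
        occ = occ[-start:]
        start = 0
    return OccupancyTrack(chrom=base.chrom, start=start, values=occ, model="experimental")
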