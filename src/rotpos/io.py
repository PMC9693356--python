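"""Readers and writers for FASTA, bedGraph, wig, BED and TSV artifacts.

Coordinate dialects: bedGraph is 0-based half-open; wig fixedStep is
1-based.  Internally everything is 0-based.  Writers go through a
temporary file followed by an atomic rename, so failed runs never leave
partial output behind.
"""
from __future__ import annotations

import os
import warnings
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .chemmap import DyadCall
from .errors import InvalidArgumentError, ParseError
from .track import Track

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tracks",
    "read_single_track",
    "write_track",
    "write_dyads_bed",
    "read_positions_bed",
    "write_profiles_tsv",
]


def read_fasta(path) -> Dict[str, str]:
    """Read a (multi-)FASTA into {name: uppercased sequence}."""
    if not os.path.exists(path):
        raise InvalidArgumentError(f"no such file: {path}")
    seqs: Dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA ({exc})") from None
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    os.replace(tmp, path)


# -- track I/O ------------------------------------------------------------


def _detect_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            if s.startswith(("fixedStep", "variableStep")):
                return "wig"
            return "bedgraph"
    return "bedgraph"


def read_tracks(path, dialect: Optional[str] = None, fill: float = np.nan) -> Dict[str, Track]:
    """Read a bedGraph or wig file into dense per-chromosome tracks.

    ``fill`` is the value given to positions inside a track's span that
    the file does not cover (NaN by default; 0 suits score tracks).
    Overlapping bedGraph intervals are an error; unsorted input is sorted
    with a warning.
    """
    if dialect is None:
        dialect = _detect_dialect(path)
    dialect = dialect.lower()
    if dialect == "bedgraph":
        per_chrom = _read_bedgraph_intervals(path)
    elif dialect == "wig":
        per_chrom = _read_wig_intervals(path)
    else:
        raise InvalidArgumentError(f"dialect must be bedGraph|wig, got {dialect!r}")

    tracks: Dict[str, Track] = {}
    for chrom, ivals in per_chrom.items():
        if not ivals:
            continue
        if any(ivals[i][0] < ivals[i - 1][0] for i in range(1, len(ivals))):
            warnings.warn(f"{path}: intervals for {chrom} are unsorted; sorting", stacklevel=2)
        ivals.sort(key=lambda t: t[0])
        prev_end = None
        for s, e, _ in ivals:
            if prev_end is not None and s < prev_end:
                raise ParseError(f"{path}: overlapping intervals on {chrom} at {s}")
            prev_end = e
        lo = ivals[0][0]
        hi = max(e for _, e, _ in ivals)
        values = np.full(hi - lo, fill, dtype=float)
        for s, e, v in ivals:
            values[s - lo : e - lo] = v
        tracks[chrom] = Track(chrom=chrom, start=lo, values=values)
    if not tracks:
        warnings.warn(f"{path}: no track data found", stacklevel=2)
    return tracks


def _read_bedgraph_intervals(path):
    per_chrom: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty or inverted interval")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    return per_chrom


def _read_wig_intervals(path):
    per_chrom: Dict[str, list] = {}
    chrom = None
    pos = step = span = None
    mode = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            if s.startswith("fixedStep") or s.startswith("variableStep"):
                fields = dict(kv.split("=", 1) for kv in s.split()[1:])
                chrom = fields.get("chrom")
                if chrom is None:
                    raise ParseError(f"{path}:{lineno}: wig header lacks chrom=")
                span = int(fields.get("span", 1))
                if s.startswith("fixedStep"):
                    mode = "fixed"
                    pos = int(fields["start"]) - 1  # wig is 1-based
                    step = int(fields.get("step", 1))
                else:
                    mode = "variable"
                continue
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: data before wig header")
            if mode == "fixed":
                value = float(s)
                per_chrom.setdefault(chrom, []).append((pos, pos + span, value))
                pos += step
            else:
                parts = s.split()
                p = int(parts[0]) - 1
                value = float(parts[1])
                per_chrom.setdefault(chrom, []).append((p, p + span, value))
    return per_chrom


def read_single_track(path, dialect: Optional[str] = None, fill: float = np.nan) -> Track:
    tracks = read_tracks(path, dialect=dialect, fill=fill)
    if not tracks:
        raise ParseError(f"{path}: file contains no track data")
    if len(tracks) > 1:
        raise InvalidArgumentError(f"{path}: expected one sequence, found {len(tracks)}")
    return next(iter(tracks.values()))


def write_track(track: Track, path, dialect: str = "bedgraph") -> None:
    """Write a track; undefined (NaN) positions are omitted.

    bedGraph merges runs of equal consecutive values; wig emits one
    fixedStep block per contiguous defined run.  Values are written with
    ``repr`` so a read-back reproduces them bit-for-bit.
    """
    dialect = dialect.lower()
    if dialect not in ("bedgraph", "wig"):
        raise InvalidArgumentError(f"dialect must be bedGraph|wig, got {dialect!r}")
    v = track.values
    finite = np.isfinite(v)
    if not finite.any():
        warnings.warn(f"{path}: track has no defined values; writing empty file", stacklevel=2)
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        if dialect == "bedgraph":
            i = 0
            n = len(v)
            while i < n:
                if not finite[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and finite[j + 1] and v[j + 1] == v[i]:
                    j += 1
                fh.write(
                    f"{track.chrom}\t{track.start + i}\t{track.start + j + 1}\t{float(v[i])!r}\n"
                )
                i = j + 1
        else:
            i = 0
            n = len(v)
            while i < n:
                if not finite[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and finite[j + 1]:
                    j += 1
                fh.write(f"fixedStep chrom={track.chrom} start={track.start + i + 1} step=1 span=1\n")
                for t in range(i, j + 1):
                    fh.write(f"{float(v[t])!r}\n")
                i = j + 1
    os.replace(tmp, path)


# -- BED / TSV ------------------------------------------------------------


def write_dyads_bed(calls: Sequence[DyadCall], path) -> None:
    """Dyad calls as 1-bp BED intervals (0-based half-open) with scores."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.map_type}\t{float(c.score)!r}\t.\n")
    os.replace(tmp, path)


def read_positions_bed(path) -> list[DyadCall]:
    """BED intervals as dyad calls: position = interval midpoint (floor)."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "dyad"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 1.0
            calls.append(DyadCall(chrom=chrom, pos=(start + end) // 2, score=score, map_type=name))
    return calls


def write_profiles_tsv(profiles, path) -> None:
    """Metagene profiles (dict label -> MetageneProfile) as one TSV."""
    import pandas as pd

    frames = [p.to_frame() for p in profiles.values()]
    if not frames:
        raise InvalidArgumentError("no profiles to write")
    tmp = f"{path}.tmp"
    pd.concat(frames, ignore_index=True).to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)
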