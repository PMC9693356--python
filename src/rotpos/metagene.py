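"""Strand-aware average profiles of per-base tracks around anchor sets."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParseError
from .track import Track

__all__ = ["AnchorSet", "MetageneProfile", "read_anchors", "profile"]

_STRANDS = {"+", "-", "."}

# UCSC refGene column order (headerless dumps)
_REFGENE_COLS = (
    "bin name chrom strand txStart txEnd cdsStart cdsEnd exonCount "
    "exonStarts exonEnds score name2 cdsStartStat cdsEndStat exonFrames"
).split()


@dataclass
class AnchorSet:
    """Records of (chrom, pos, strand, label); strand '.' behaves as '+'."""

    frame: pd.DataFrame  # columns: chrom, pos, strand, label

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand", "label"}
        if not required.issubset(self.frame.columns):
            raise InvalidArgumentError(f"anchor frame needs columns {sorted(required)}")
        if (self.frame["pos"] < 0).any():
            raise InvalidArgumentError("anchor positions must be non-negative")
        bad = ~self.frame["strand"].isin(_STRANDS)
        if bad.any():
            raise InvalidArgumentError(
                f"unknown strand characters: {sorted(self.frame.loc[bad, 'strand'].unique())}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.frame["label"]))

    def subset(self, label: str) -> "AnchorSet":
        return AnchorSet(self.frame[self.frame["label"] == label].reset_index(drop=True))

    def pooled(self, label: str = "all") -> "AnchorSet":
        f = self.frame.copy()
        f["label"] = label
        return AnchorSet(f)


@dataclass
class MetageneProfile:
    """Mean track value vs. signed offset from aligned anchors."""

    offsets: np.ndarray
    mean: np.ndarray  # NaN where count == 0
    count: np.ndarray
    label: str
    flank: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "count": self.count, "label": self.label}
        )


def _resolve_anchor(start: int, end: int, strand: str, anchor: str) -> tuple[int, str]:
    """Map a 0-based half-open interval to its anchor position."""
    if strand == ".":
        strand = "+"
    if anchor == "tss":
        pos = start if strand == "+" else end - 1
    elif anchor == "tts":
        pos = end - 1 if strand == "+" else start
    elif anchor == "midpoint":
        pos = (start + end) // 2
    else:
        raise InvalidArgumentError(f"anchor must be tss|tts|midpoint, got {anchor!r}")
    return pos, strand


def read_anchors(
    path,
    format: str = "bed",
    anchor: str = "tss",
    classes: Optional[Union[Mapping[str, str], str]] = None,
) -> AnchorSet:
    """Read anchors from BED or a refGene-style table.

    TSS is txStart for '+' genes and txEnd-1 for '-' genes (0-based); TTS
    is mirrored; interval midpoints round down.  Duplicate (chrom, pos,
    strand) records collapse to one.  ``classes`` maps record names to
    class labels (dict or a two-column id<TAB>class file); unmapped
    records get the BED name field, or 'all'.
    """
    if isinstance(classes, str):
        cmap = {}
        with open(classes) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0]:
                    cmap[parts[0]] = parts[1]
        classes = cmap

    records = []
    bad_lines = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\n")
            if not raw.strip() or raw.startswith(("track", "browser")):
                continue
            if raw.startswith("#"):
                if format == "refgene" and header is None:
                    cols = raw.lstrip("#").split("\t")
                    if "txStart" in cols:
                        header = cols
                continue
            parts = raw.split("\t") if "\t" in raw else raw.split()
            if format == "bed":
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
                strand = parts[5] if len(parts) > 5 else "."
            elif format == "refgene":
                if header is not None:
                    row = dict(zip(header, parts))
                else:
                    row = dict(zip(_REFGENE_COLS, parts))
                try:
                    chrom = row["chrom"]
                    start, end = int(row["txStart"]), int(row["txEnd"])
                    strand = row["strand"]
                    name = row.get("name", "")
                except (KeyError, ValueError):
                    raise ParseError(
                        f"{path}:{lineno}: refGene row lacks chrom/strand/txStart/txEnd"
                    ) from None
            else:
                raise InvalidArgumentError(f"format must be bed|refgene, got {format!r}")
            if strand not in _STRANDS:
                bad_lines.append((lineno, strand))
                continue
            pos, strand = _resolve_anchor(start, end, strand, anchor)
            if classes and name in classes:
                label = classes[name]
            elif name:
                label = name
            else:
                label = "all"
            records.append((chrom, pos, strand, label))
    if bad_lines:
        listing = ", ".join(f"line {ln} ({s!r})" for ln, s in bad_lines[:10])
        raise ParseError(f"{path}: unknown strand characters at {listing}")
    frame = pd.DataFrame(records, columns=["chrom", "pos", "strand", "label"])
    frame = frame.drop_duplicates(subset=["chrom", "pos", "strand"], keep="first")
    return AnchorSet(frame.reset_index(drop=True))


def profile(
    track: Union[Track, Mapping[str, Track]],
    anchors: AnchorSet,
    flank: int = 1000,
    stat: str = "mean",
) -> Dict[str, MetageneProfile]:
    """Average a track around each anchor class, strand-aware.

    For each anchor the window [pos-flank, pos+flank] is extracted and
    reversed for '-' strand anchors so positive offsets always point in
    the anchor's own direction.  Undefined (NaN) positions are skipped
    per offset, with counts reported.
    """
    if stat not in ("mean", "median"):
        raise InvalidArgumentError(f"stat must be mean|median, got {stat!r}")
    tracks: Mapping[str, Track]
    if isinstance(track, Track):
        tracks = {track.chrom: track}
    else:
        tracks = track
    width = 2 * flank + 1
    offsets = np.arange(-flank, flank + 1)

    out: Dict[str, MetageneProfile] = {}
    for label in anchors.labels():
        sub = anchors.subset(label).frame
        rows = []
        for chrom, pos, strand in zip(sub["chrom"], sub["pos"], sub["strand"]):
            t = tracks.get(chrom)
            if t is None:
                continue
            w = t.window(int(pos) - flank, width)
            if strand == "-":
                w = w[::-1]
            rows.append(w)
        if not rows:
            warnings.warn(f"metagene class {label!r}: no usable anchors; skipped", stacklevel=2)
            continue
        mat = np.vstack(rows)
        count = np.isfinite(mat).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
            center = np.nanmean(mat, axis=0) if stat == "mean" else np.nanmedian(mat, axis=0)
        out[label] = MetageneProfile(
            offsets=offsets, mean=center, count=count, label=label, flank=flank
        )
    return out
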