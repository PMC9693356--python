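"""Ground-truth synthetic fixtures.

Generates DNA with 10-bp-periodic dinucleotide signals planted around
known dyads, matching NCP score tracks with controllable jitter/noise,
and small gene fixtures with promoter NDRs — everything a pure function
of (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidArgumentError
from .metagene import AnchorSet
from .track import NCPTrack

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_periodic_sequence",
    "generate_ncp_track",
    "generate_gene_fixture",
    "FOOTPRINT_HALF",
]

FOOTPRINT_HALF = 73  # planted signal spans +/- 73 bp around each dyad

_BASES = np.array(list("ACGT"))
# in-phase (minor-groove-in) and half-phase (major-groove-in) dimers
_PHASE0_DIMERS = ("AA", "TT", "TA")
_PHASE5_DIMERS = ("GC", "CG", "GG")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted periodic-nucleosome genome."""

    n_nucleosomes: int = 8
    spacing: int = 167  # dyad-to-dyad, bp
    period: float = 10.0  # P_sig of the planted rotational signal
    signal_strength: float = 1.0  # probability a phased position is planted
    linker: str = "random"  # or "A-tract"
    seed: int = 0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    phase_offset: int = 0  # shift of planted phases relative to the dyad
    pad: int = 200  # background padding before the first / after the last dyad

    def __post_init__(self) -> None:
        if self.n_nucleosomes < 1:
            raise InvalidArgumentError("need at least one nucleosome")
        if self.spacing < 147:
            raise InvalidArgumentError(f"spacing must be >= 147 bp, got {self.spacing}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise InvalidArgumentError("signal_strength must be in [0, 1]")
        if self.linker not in ("random", "A-tract"):
            raise InvalidArgumentError(f"unknown linker model {self.linker!r}")
        if self.period <= 0:
            raise InvalidArgumentError("period must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise InvalidArgumentError("background composition must sum to 1")
        if self.pad < FOOTPRINT_HALF:
            raise InvalidArgumentError(f"pad must be >= {FOOTPRINT_HALF}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted dyads and layout of a synthetic genome."""

    chrom: str
    length: int
    dyads: np.ndarray
    phases: np.ndarray  # planted phase offset of each dyad (bp)
    ndr_intervals: tuple[tuple[int, int], ...] = ()


def _phase_positions(period: float, phase_offset: int, half: bool) -> np.ndarray:
    """Signed offsets from the dyad that fall on phase 0 (or phase P/2)."""
    shift = 0.5 if half else 0.0
    m_lo = math.ceil((-FOOTPRINT_HALF) / period - shift)
    m_hi = math.floor(FOOTPRINT_HALF / period - shift)
    m = np.arange(m_lo, m_hi + 1)
    return np.round((m + shift) * period).astype(int) + phase_offset


def generate_periodic_sequence(spec: SyntheticSpec) -> tuple[str, GroundTruth]:
    """A genome of planted rotationally phased nucleosomes.

    Within +/-73 bp of each dyad, offsets at phase 0 (mod the signal
    period) receive an AA/TT/TA dimer with probability ``signal_strength``
    and offsets at half phase receive GC/CG/GG; everything else comes from
    the background composition (or poly-A linkers under the 'A-tract'
    linker model).
    """
    rng = np.random.default_rng(spec.seed)
    dyads = spec.pad + spec.spacing * np.arange(spec.n_nucleosomes)
    length = 2 * spec.pad + spec.spacing * (spec.n_nucleosomes - 1)
    codes = rng.choice(4, size=length, p=spec.background)

    if spec.linker == "A-tract":
        in_footprint = np.zeros(length, dtype=bool)
        for d in dyads:
            in_footprint[max(0, d - FOOTPRINT_HALF) : d + FOOTPRINT_HALF + 1] = True
        codes[~in_footprint] = 0  # 'A'

    off0 = _phase_positions(spec.period, spec.phase_offset, half=False)
    off5 = _phase_positions(spec.period, spec.phase_offset, half=True)
    for d in dyads:
        for offs, dimers in ((off0, _PHASE0_DIMERS), (off5, _PHASE5_DIMERS)):
            for o in offs:
                q = d + int(o)
                planted = rng.random() < spec.signal_strength
                dimer = dimers[rng.integers(len(dimers))]
                if planted and 0 <= q < length - 1:
                    codes[q] = "ACGT".index(dimer[0])
                    codes[q + 1] = "ACGT".index(dimer[1])

    seq = "".join(_BASES[codes])
    truth = GroundTruth(
        chrom="synth",
        length=length,
        dyads=dyads,
        phases=np.full(len(dyads), spec.phase_offset),
    )
    return seq, truth


def generate_ncp_track(
    truth: GroundTruth,
    peak_score: float = 10.0,
    jitter_sd: float = 0.0,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> NCPTrack:
    """An NCP score track with a peak at each (possibly jittered) dyad and
    sparse low-score background noise."""
    if peak_score <= 0:
        raise InvalidArgumentError("peak_score must be positive")
    if jitter_sd < 0:
        raise InvalidArgumentError("jitter_sd must be non-negative")
    if not 0.0 <= noise_rate <= 1.0:
        raise InvalidArgumentError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.zeros(truth.length)
    for d in truth.dyads:
        p = int(d)
        if jitter_sd > 0:
            p += int(round(rng.normal(0.0, jitter_sd)))
        if 0 <= p < truth.length:
            scores[p] += peak_score
    if noise_rate > 0:
        noisy = rng.random(truth.length) < noise_rate
        noisy &= scores == 0
        scores[noisy] = rng.uniform(0.0, 0.1 * peak_score, size=int(noisy.sum()))
    return NCPTrack(chrom=truth.chrom, start=0, values=scores)


_RC = str.maketrans("ACGT", "TGCA")

NDR_LEN = 120  # A-tract immediately upstream of each fixture TSS
FIRST_DYAD_OFFSET = 100  # first planted dyad downstream of the TSS
GENE_ARRAY_N = 5
GENE_ARRAY_SPACING = 180


def generate_gene_fixture(
    n_plus: int,
    n_minus: int,
    flank: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], AnchorSet, GroundTruth]:
    """A one-chromosome genome of genes with planted nucleosome arrays.

    Each gene unit is built in plus orientation — background upstream, an
    A-tract NDR ending at the TSS, then a phased array of planted
    nucleosomes downstream — and reverse-complemented for '-' genes, so
    both strands share the same gene-relative structure.  Returns the
    genome, TSS anchors labelled 'plus'/'minus', and the planted dyads in
    genome coordinates.
    """
    import pandas as pd

    if n_plus + n_minus < 1:
        raise InvalidArgumentError("need at least one gene")
    rng = np.random.default_rng(seed)
    array_len = FIRST_DYAD_OFFSET + GENE_ARRAY_SPACING * (GENE_ARRAY_N - 1) + FOOTPRINT_HALF + 27
    unit_len = flank + NDR_LEN + array_len + flank

    chrom_parts: list[str] = []
    anchors = []
    dyads_genome: list[int] = []
    offset = 0
    strands = ["+"] * n_plus + ["-"] * n_minus
    for strand in strands:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = np.random.default_rng(sub_seed)
        spec = SyntheticSpec(
            n_nucleosomes=GENE_ARRAY_N,
            spacing=GENE_ARRAY_SPACING,
            seed=sub_seed,
            pad=FOOTPRINT_HALF + 27,
        )
        array_seq, array_truth = generate_periodic_sequence(spec)
        up = "".join(_BASES[sub.choice(4, size=flank)])
        down = "".join(_BASES[sub.choice(4, size=flank)])
        ndr = "A" * NDR_LEN
        # TSS sits right after the NDR; first planted dyad at TSS + FIRST_DYAD_OFFSET
        tss_local = flank + NDR_LEN
        lead = array_truth.dyads[0] - FIRST_DYAD_OFFSET  # trim so dyad 0 lands correctly
        body = array_seq[lead:]
        unit = (up + ndr + body + down)[:unit_len].ljust(unit_len, "A")
        local_dyads = [tss_local + FIRST_DYAD_OFFSET + GENE_ARRAY_SPACING * i for i in range(GENE_ARRAY_N)]
        if strand == "-":
            unit = unit.translate(_RC)[::-1]
            tss_local = unit_len - 1 - tss_local
            local_dyads = [unit_len - 1 - d for d in local_dyads]
        anchors.append(("genome", offset + tss_local, strand, "plus" if strand == "+" else "minus"))
        dyads_genome.extend(offset + d for d in local_dyads)
        chrom_parts.append(unit)
        offset += unit_len
    genome = "".join(chrom_parts)
    frame = pd.DataFrame(anchors, columns=["chrom", "pos", "strand", "label"])
    truth = GroundTruth(
        chrom="genome",
        length=len(genome),
        dyads=np.array(sorted(dyads_genome)),
        phases=np.zeros(len(dyads_genome), dtype=int),
    )
    return {"genome": genome}, AnchorSet(frame), truth
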