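"""Sliding-window DNA deformation energies.

A nucleosome is modelled as a harmonic deformation of each base-pair step
toward a superhelical template whose roll/tilt targets are sinusoids in
quadrature at the helical frequency.  The bending energy charges only the
rotational (roll, tilt) deviations; the shearing energy charges only the
translational (shift, slide) ones.  Window sums are normalized by the
number of base-pair steps, so the unit is kT per base-pair step.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import EmptyTrackError, InvalidArgumentError, InvalidStateError
from .params import DIMERS, StepParameterTable, default_table
from .track import EnergyTrack

__all__ = [
    "NucleosomeTemplate",
    "build_nucleosome_template",
    "window_energy",
    "energy_track",
    "normalize_unit_range",
    "DEFAULT_WINDOW",
    "DEFAULT_PERIOD",
    "DEFAULT_CURVATURE",
]

DEFAULT_WINDOW = 101
DEFAULT_PERIOD = 10.0
DEFAULT_CURVATURE = 4.5  # degrees per step
SHEAR_SLIDE_AMPLITUDE = 0.3  # Angstrom, in phase with the roll target

# indices into (twist, tilt, roll, shift, slide, rise)
KIND_DIMS = {"bending": (1, 2), "shearing": (3, 4)}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class NucleosomeTemplate:
    """Per-step target deformations for an L-bp superhelical window.

    Step ``j`` (0-based, ``0..L-2``) joins bases ``j`` and ``j+1``; the
    central step index is ``(L-1)//2``, where the roll target peaks.
    """

    window_len: int
    helical_period: float
    curvature_amplitude: float
    omega: float  # radians per step
    roll_t: np.ndarray
    tilt_t: np.ndarray
    twist_t: np.ndarray
    shift_t: np.ndarray
    slide_t: np.ndarray

    @property
    def half(self) -> int:
        return (self.window_len - 1) // 2

    def targets(self) -> np.ndarray:
        """(L-1, 6) target matrix over (twist, tilt, roll, shift, slide, rise).

        The rise column is zero; it never enters either energy kind.
        """
        n = self.window_len - 1
        out = np.zeros((n, 6))
        out[:, 0] = self.twist_t
        out[:, 1] = self.tilt_t
        out[:, 2] = self.roll_t
        out[:, 3] = self.shift_t
        out[:, 4] = self.slide_t
        return out


def build_nucleosome_template(
    window_len: int = DEFAULT_WINDOW,
    helical_period: float = DEFAULT_PERIOD,
    curvature_amplitude: float = DEFAULT_CURVATURE,
) -> NucleosomeTemplate:
    """Build the superhelical deformation template for one window.

    ``roll_t(j) = rho * cos(omega * (j - c))`` and
    ``tilt_t(j) = rho * sin(omega * (j - c))`` with ``c`` the central step,
    so the two sinusoids are in quadrature and their vector norm is the
    constant curvature amplitude.  Twist is held at ``360/period`` degrees;
    the shearing targets are zero shift and a small slide sinusoid in phase
    with the roll target.
    """
    if window_len % 2 == 0:
        raise InvalidArgumentError(f"window_len must be odd, got {window_len}")
    if not 75 <= window_len <= 147:
        raise InvalidArgumentError(f"window_len must be within [75, 147], got {window_len}")
    if helical_period <= 0:
        raise InvalidArgumentError("helical_period must be positive")
    if curvature_amplitude < 0:
        raise InvalidArgumentError("curvature_amplitude must be non-negative")
    omega = 2.0 * np.pi / helical_period
    c = (window_len - 1) // 2
    j = np.arange(window_len - 1)
    phase = omega * (j - c)
    roll_t = curvature_amplitude * np.cos(phase)
    tilt_t = curvature_amplitude * np.sin(phase)
    twist_t = np.full(window_len - 1, 360.0 / helical_period)
    shift_t = np.zeros(window_len - 1)
    slide_t = SHEAR_SLIDE_AMPLITUDE * np.cos(phase)
    return NucleosomeTemplate(
        window_len=window_len,
        helical_period=helical_period,
        curvature_amplitude=curvature_amplitude,
        omega=omega,
        roll_t=roll_t,
        tilt_t=tilt_t,
        twist_t=twist_t,
        shift_t=shift_t,
        slide_t=slide_t,
    )


def _step_cost_matrix(
    template: NucleosomeTemplate, params: StepParameterTable, kind: str
) -> np.ndarray:
    """(17, L-1) harmonic cost of dimer code ``a`` at template step ``j``.

    Row 16 is the average over the 16 dimers, used for the
    ``ambiguous='average'`` policy.
    """
    dims = list(KIND_DIMS[kind])
    T = template.targets()[:, dims]  # (L-1, k)
    C = np.empty((17, template.window_len - 1))
    for a, dimer in enumerate(DIMERS):
        eq = np.asarray(params.equilibrium[dimer], dtype=float)[dims]
        F = np.asarray(params.stiffness[dimer], dtype=float)[np.ix_(dims, dims)]
        d = T - eq  # (L-1, k)
        C[a] = 0.5 * np.einsum("ja,ab,jb->j", d, F, d)
    C[16] = C[:16].mean(axis=0)
    return C


def _encode(seq: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3; anything else -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def energy_track(
    seq: str,
    template: Optional[NucleosomeTemplate] = None,
    params: Optional[StepParameterTable] = None,
    kind: str = "bending",
    name: str = "seq",
    ambiguous: str = "reject",
) -> EnergyTrack:
    """Deformation energy of every full window along ``seq``.

    The value at position ``i`` is the window energy of the L-bp window
    centered at ``i``; positions where no full window fits are outside the
    track.  Windows containing non-ACGT bases are NaN under the default
    ``ambiguous='reject'`` policy, or use dimer-averaged step costs under
    ``'average'``.
    """
    if kind not in KIND_DIMS:
        raise InvalidArgumentError(f"kind must be 'bending' or 'shearing', got {kind!r}")
    if ambiguous not in ("reject", "average"):
        raise InvalidArgumentError(f"unknown ambiguous-base policy {ambiguous!r}")
    if template is None:
        template = build_nucleosome_template()
    if params is None:
        params = default_table()
    L = template.window_len
    if len(seq) < L:
        raise EmptyTrackError(f"sequence length {len(seq)} < window {L}")

    codes = _encode(seq)
    # dimer code of step starting at base s; -1 when either base ambiguous
    good = (codes[:-1] >= 0) & (codes[1:] >= 0)
    dimer_codes = np.where(good, 4 * codes[:-1] + codes[1:], 16)

    C = _step_cost_matrix(template, params, kind)
    n = len(seq) - L + 1
    total = np.zeros(n)
    for t in range(L - 1):
        total += C[dimer_codes[t : t + n], t]
    values = total / (L - 1)

    if ambiguous == "reject":
        bad = (~good).astype(float)
        bad_in_window = np.correlate(bad, np.ones(L - 1), mode="valid")
        values = np.where(bad_in_window < 0.5, values, np.nan)

    return EnergyTrack(
        chrom=name,
        start=template.half,
        values=values,
        kind=kind,
        window_len=L,
        normalized=False,
    )


def window_energy(
    seq: str,
    template: Optional[NucleosomeTemplate] = None,
    params: Optional[StepParameterTable] = None,
    kind: str = "bending",
    ambiguous: str = "reject",
) -> float:
    """Deformation energy (kT/bps) of a single window-length sequence."""
    if template is None:
        template = build_nucleosome_template()
    if len(seq) != template.window_len:
        raise InvalidArgumentError(
            f"sequence length {len(seq)} != template window {template.window_len}"
        )
    track = energy_track(seq, template, params, kind, ambiguous=ambiguous)
    value = float(track.values[0])
    if np.isnan(value) and ambiguous == "reject":
        raise InvalidArgumentError("window contains ambiguous bases (policy 'reject')")
    return value


def normalize_unit_range(
    track: EnergyTrack,
    emin: Optional[float] = None,
    emax: Optional[float] = None,
) -> EnergyTrack:
    """Affine rescale of a raw energy track into [-1, 1].

    With no explicit ``emin``/``emax`` the track's own defined min/max are
    used; externally supplied bounds (e.g. genome-scale extremes) may not
    cover the track, so values are clipped to [-1, 1] afterwards.
    """
    if track.normalized:
        raise InvalidStateError("track is already unit-range normalized")
    defined = track.values[track.defined_mask]
    if defined.size == 0:
        raise EmptyTrackError("cannot normalize a track with no defined values")
    lo = float(defined.min()) if emin is None else float(emin)
    hi = float(defined.max()) if emax is None else float(emax)
    if lo >= hi:
        raise InvalidArgumentError(f"emin ({lo}) must be < emax ({hi})")
    values = 2.0 * (track.values - lo) / (hi - lo) - 1.0
    values = np.clip(values, -1.0, 1.0)
    return replace(track, values=values, normalized=True, emin=lo, emax=hi)
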