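"""Base-pair step elastic parameters.

Each of the 16 dinucleotide steps carries six equilibrium step values
(twist, tilt, roll in degrees; shift, slide, rise in Angstrom) and a
symmetric 6x6 stiffness matrix in kT per squared unit.  The packaged
default table uses a dimer-resolved harmonic parameterization in which
the sign convention for roll is anchored to the nucleosome template:
positive roll bends the duplex toward the histone-proximal minor groove,
so A/T-rich steps (minor-groove-in) carry positive equilibrium roll and
G/C-rich steps negative roll.  The table is swappable via ``from_file``.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable

import numpy as np

from .errors import InvalidArgumentError, ParseError

__all__ = [
    "PARAM_NAMES",
    "DIMERS",
    "StepParameterTable",
    "reverse_complement_step",
    "default_table",
]

PARAM_NAMES = ("twist", "tilt", "roll", "shift", "slide", "rise")
DIMERS = tuple(a + b for a in "ACGT" for b in "ACGT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Under strand reversal twist/roll/slide/rise are invariant while tilt and
# shift change sign.
_RC_SIGNS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, 1.0])

_TRIU = np.triu_indices(6)


def reverse_complement_step(dimer: str) -> str:
    return _COMPLEMENT[dimer[1]] + _COMPLEMENT[dimer[0]]


@dataclass(frozen=True)
class StepParameterTable:
    """Equilibrium values and stiffness matrices for the 16 dimer steps."""

    equilibrium: Dict[str, np.ndarray]  # dimer -> (6,)
    stiffness: Dict[str, np.ndarray]  # dimer -> (6, 6)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [d for d in DIMERS if d not in self.equilibrium or d not in self.stiffness]
        if missing:
            raise InvalidArgumentError(f"missing dimer steps: {missing}")
        for d in DIMERS:
            eq = np.asarray(self.equilibrium[d], dtype=float)
            F = np.asarray(self.stiffness[d], dtype=float)
            if eq.shape != (6,):
                raise InvalidArgumentError(f"{d}: equilibrium must have 6 entries")
            if F.shape != (6, 6):
                raise InvalidArgumentError(f"{d}: stiffness must be 6x6")
            if not np.allclose(F, F.T, atol=1e-9):
                raise InvalidArgumentError(f"{d}: stiffness matrix not symmetric")
            if np.any(np.diag(F) <= 0):
                raise InvalidArgumentError(f"{d}: stiffness diagonal must be positive")
            if np.linalg.eigvalsh(F).min() < -1e-9:
                raise InvalidArgumentError(f"{d}: stiffness matrix not positive semidefinite")
        # reverse-complement symmetry between a step and its complement
        for d in DIMERS:
            rc = reverse_complement_step(d)
            eq_rc = _RC_SIGNS * np.asarray(self.equilibrium[d], dtype=float)
            if not np.allclose(eq_rc, self.equilibrium[rc], atol=1e-6):
                raise InvalidArgumentError(
                    f"equilibrium values of {d} and {rc} violate reverse-complement symmetry"
                )
            S = np.diag(_RC_SIGNS)
            F_rc = S @ np.asarray(self.stiffness[d], dtype=float) @ S
            if not np.allclose(F_rc, self.stiffness[rc], atol=1e-6):
                raise InvalidArgumentError(
                    f"stiffness of {d} and {rc} violate reverse-complement symmetry"
                )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, np.ndarray, np.ndarray]]) -> "StepParameterTable":
        eq = {}
        F = {}
        for dimer, e, f in rows:
            eq[dimer] = np.asarray(e, dtype=float)
            F[dimer] = np.asarray(f, dtype=float)
        return cls(eq, F)

    @classmethod
    def from_file(cls, path) -> "StepParameterTable":
        """Read a plain-text table.

        One row per dinucleotide: the dimer, 6 equilibrium values
        (twist tilt roll shift slide rise), then the 21 unique entries of
        the symmetric stiffness matrix in row-major upper-triangle order.
        ``#`` starts a comment.
        """
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 1 + 6 + 21:
                    raise ParseError(
                        f"{path}:{lineno}: expected dimer + 27 numbers, got {len(parts)} fields"
                    )
                dimer = parts[0].upper()
                if dimer not in DIMERS:
                    raise ParseError(f"{path}:{lineno}: unknown dimer {dimer!r}")
                try:
                    nums = np.array([float(x) for x in parts[1:]])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
                eq = nums[:6]
                F = np.zeros((6, 6))
                F[_TRIU] = nums[6:]
                F = F + F.T - np.diag(np.diag(F))
                rows.append((dimer, eq, F))
        return cls.from_rows(rows)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# dimer  twist tilt roll shift slide rise  then 21 upper-triangle stiffness entries\n")
            fh.write("# angles in degrees, translations in Angstrom; stiffness in kT per squared unit\n")
            for d in DIMERS:
                eq = " ".join(f"{x:.6g}" for x in self.equilibrium[d])
                tri = " ".join(f"{x:.6g}" for x in np.asarray(self.stiffness[d])[_TRIU])
                fh.write(f"{d} {eq} {tri}\n")


@functools.lru_cache(maxsize=1)
def default_table() -> StepParameterTable:
    """The packaged dimer-step table (see module docstring)."""
    ref = resources.files("rotpos").joinpath("data/step_parameters.txt")
    with resources.as_file(ref) as path:
        return StepParameterTable.from_file(path)
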