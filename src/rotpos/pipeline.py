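"""End-to-end pipeline: FASTA -> energies -> scores -> occupancy models."""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .energy import (
    DEFAULT_CURVATURE,
    DEFAULT_PERIOD,
    DEFAULT_WINDOW,
    build_nucleosome_template,
    energy_track,
    normalize_unit_range,
)
from .errors import InvalidArgumentError, RotposError
from .io import read_fasta, write_track
from .occupancy import (
    DEFAULT_SIGMA2,
    DEFAULT_WAVE_PERIOD,
    envelope_occupancy,
    occupancy_model1,
    positioning_scores,
    rotational_positioning_index,
)
from .params import StepParameterTable, default_table

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    fasta: str
    outdir: str
    window: int = DEFAULT_WINDOW
    helical_period: float = DEFAULT_PERIOD
    curvature: float = DEFAULT_CURVATURE
    beta: float = 1.0
    sigma2: float = DEFAULT_SIGMA2
    wave_period: float = DEFAULT_WAVE_PERIOD
    params_path: Optional[str] = None
    emin: Optional[float] = None
    emax: Optional[float] = None
    dialect: str = "bedgraph"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or not 75 <= self.window <= 147:
            raise InvalidArgumentError(f"window must be odd in [75, 147], got {self.window}")
        if self.helical_period <= 0 or self.wave_period <= 0 or self.sigma2 <= 0:
            raise InvalidArgumentError("periods and sigma2 must be positive")
        if (self.emin is None) != (self.emax is None):
            raise InvalidArgumentError("emin and emax must be given together")
        if self.emin is not None and self.emin >= self.emax:
            raise InvalidArgumentError("emin must be < emax")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Key = value config file mirroring the CLI flags; CLI overrides win."""
        fields = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.split("#", 1)[0].strip()
                if not s:
                    continue
                if "=" not in s:
                    raise InvalidArgumentError(f"{path}:{lineno}: expected key = value")
                key, val = (x.strip() for x in s.split("=", 1))
                fields[key] = val
        typed = {}
        hints = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for key, val in fields.items():
            if key not in cls.__dataclass_fields__:
                raise InvalidArgumentError(f"{path}: unknown config key {key!r}")
            if key in ("window",):
                typed[key] = int(val)
            elif key in ("helical_period", "curvature", "beta", "sigma2", "wave_period", "emin", "emax"):
                typed[key] = float(val)
            else:
                typed[key] = val
        typed.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**typed)


def run_pipeline(config: RunConfig) -> dict:
    """Run FASTA -> energy -> scores -> model #1 and model #2 occupancy.

    Writes per-sequence bedGraph/wig tracks plus a ``manifest.json``
    recording every parameter and output; returns the manifest dict.
    Normalization bounds are taken over the whole input set unless fixed
    in the config, mirroring genome-scale min/max usage.
    """
    stage = "read-fasta"
    try:
        seqs = read_fasta(config.fasta)
        os.makedirs(config.outdir, exist_ok=True)
        params = (
            StepParameterTable.from_file(config.params_path)
            if config.params_path
            else default_table()
        )
        template = build_nucleosome_template(config.window, config.helical_period, config.curvature)

        stage = "energy"
        raw = {}
        for name, seq in seqs.items():
            raw[name] = {
                kind: energy_track(seq, template, params, kind, name=name)
                for kind in ("bending", "shearing")
            }

        stage = "normalize"
        bounds = {}
        for kind in ("bending", "shearing"):
            if config.emin is not None:
                lo, hi = config.emin, config.emax
            else:
                allv = np.concatenate(
                    [t[kind].values[np.isfinite(t[kind].values)] for t in raw.values()]
                )
                lo, hi = float(allv.min()), float(allv.max())
            bounds[kind] = (lo, hi)

        outputs = []
        ext = "bedGraph" if config.dialect == "bedgraph" else "wig"
        for name in seqs:
            stage = "scores"
            norm = {
                kind: normalize_unit_range(raw[name][kind], *bounds[kind])
                for kind in ("bending", "shearing")
            }
            p_bend = positioning_scores(norm["bending"], beta=config.beta)
            p_shear = positioning_scores(norm["shearing"], beta=config.beta)

            stage = "model1"
            occ1 = occupancy_model1(p_shear)
            stage = "model2"
            rpi = rotational_positioning_index(p_bend, config.sigma2, config.wave_period)
            occ2 = envelope_occupancy(rpi)

            stage = "write"
            for tag, tr in (
                ("bending", norm["bending"]),
                ("shearing", norm["shearing"]),
                ("occ_model1", occ1),
                ("rpi", rpi),
                ("occ_model2", occ2),
            ):
                fn = os.path.join(config.outdir, f"{name}.{tag}.{ext}")
                write_track(tr, fn, dialect=config.dialect)
                outputs.append(fn)
    except RotposError as exc:
        raise RotposError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "normalization": {k: list(v) for k, v in bounds.items()},
        "sequences": {name: len(seq) for name, seq in seqs.items()},
        "outputs": [os.path.basename(f) for f in outputs],
    }
    tmp = os.path.join(config.outdir, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, os.path.join(config.outdir, "manifest.json"))
    return manifest
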