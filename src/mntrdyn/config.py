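"""Run configuration and provenance for the pipeline front end.

Defaults are the analysis settings the pipeline is calibrated to: strip the
first 3 / last 7 residues per chain, cluster with the gromos algorithm at a
1.8 Å cutoff on frames from 20 ns onward, and fit PCA on the 200–500 ns
window of Cα coordinates.  Any override is logged at warning level so runs
that deviate from the reference settings are visible in their provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

log = logging.getLogger("mntrdyn")

__all__ = ["RunConfig", "write_provenance"]


@dataclass
class RunConfig:
    inputs: list[tuple[str, str]] = field(default_factory=list)  # (label, path)
    strip_head: int = 3
    strip_tail: int = 7
    cutoff: float = 1.8  # Å, gromos clustering
    cluster_start_ps: float = 20_000.0  # discard frames before 20 ns
    pca_window_ps: tuple[float, float] = (200_000.0, 500_000.0)
    dbh_residues: tuple[int, int, int, int] = (47, 36, 189, 178)
    hinge_residues: tuple[int, int, int] = (64, 75, 86)
    descriptor_atom: str = "C"  # backbone carbonyl carbon
    lys_residue: int = 41
    outdir: str = "results"
    seed: int = 0

    _REFERENCE = {
        "strip_head": 3,
        "strip_tail": 7,
        "cutoff": 1.8,
        "cluster_start_ps": 20_000.0,
        "pca_window_ps": (200_000.0, 500_000.0),
        "dbh_residues": (47, 36, 189, 178),
        "hinge_residues": (64, 75, 86),
        "descriptor_atom": "C",
        "lys_residue": 41,
    }

    def __post_init__(self):
        if self.strip_head < 0 or self.strip_tail < 0:
            raise ParameterError("strip counts must be >= 0")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be > 0")
        for name, ref in self._REFERENCE.items():
            val = getattr(self, name)
            if tuple(val) != tuple(ref) if isinstance(ref, tuple) else val != ref:
                log.warning("non-default setting %s=%r (reference: %r)", name, val, ref)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from JSON or YAML (by extension; YAML reads JSON too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} does not hold a mapping")
        if "inputs" in data:
            data["inputs"] = [tuple(x) for x in data["inputs"]]
        for key in ("pca_window_ps", "dbh_residues", "hinge_residues"):
            if key in data:
                data[key] = tuple(data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = [list(x) for x in self.inputs]
        return d


def write_provenance(config: RunConfig, outdir, extra: dict | None = None) -> Path:
    """Write a machine-readable record of the run beside its outputs."""
    import numpy

    from . import __version__

    record = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"mntrdyn": __version__, "numpy": numpy.__version__},
    }
    if extra:
        record.update(extra)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2))
    return path
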