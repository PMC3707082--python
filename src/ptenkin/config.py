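"""Run configuration: YAML-serializable options for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .exceptions import DesignError

STAGES = ("interfacial", "soluble", "doseresponse", "decay", "binding", "saxs")


@dataclass
class RunConfig:
    """Inputs and fit options for :mod:`ptenkin.reports`.

    ``inputs`` maps stage names (subset of {interfacial, soluble,
    doseresponse, decay, binding, saxs}) to CSV/.dat paths; the saxs entry
    may be a mapping of sample name to file.  Options carry their defaults:
    ``n_keep`` surface-dilution points kept before the apparent fit,
    Guinier ``qRg_limit``, P(r) smoothness ``alpha``, the synthetic-noise CV
    used by ``simulate``, and the Dmax scan window in Å.
    """

    inputs: dict = field(default_factory=dict)
    outdir: str = "ptenkin_out"
    seed: int = 0
    n_keep: int = 4
    qRg_limit: float = 1.3
    alpha: float = 1.0
    noise_cv: float = 0.05
    dmax_scan: tuple = (20.0, 150.0)
    ref_cip_uM: Optional[float] = None

    def __post_init__(self):
        self.dmax_scan = tuple(float(x) for x in self.dmax_scan)
        unknown = set(self.inputs) - set(STAGES)
        if unknown:
            raise DesignError(f"unknown stages in config: {sorted(unknown)}")

    def validate_paths(self) -> None:
        for stage, entry in self.inputs.items():
            paths = entry.values() if isinstance(entry, dict) else [entry]
            for p in paths:
                if not Path(p).exists():
                    raise DesignError(f"input for stage {stage!r} not found: {p}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["dmax_scan"] = list(self.dmax_scan)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
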