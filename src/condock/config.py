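"""Run configuration for the consensus pipeline.

Every tunable of the workflow lives here with its default, and the
merged effective configuration is persisted next to the outputs so a
run is reproducible from its artefacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .alascan import EnergyParams
from .errors import ValidationError
from .structmodel import EnsembleLayout
from .pose_synth import DEFAULT_ENGINES


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one consensus run."""

    engines: tuple[str, ...] = DEFAULT_ENGINES
    pattern: str = "pose_*.pdb"
    receptor_chain: str = "A"
    ligand_chain: str = "B"
    top_k: int = 10
    rmsd_mode: str = "all_heavy"
    linkage: str = "average"
    kelley_norm_min: float = 1.0
    interface_cutoff: float = 5.0
    epsilon0: float = 0.2
    pair_cutoff: float = 10.0
    scan_side: str = "both"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.interface_cutoff <= 0:
            raise ValidationError("interface_cutoff must be positive")

    @property
    def layout(self) -> EnsembleLayout:
        return EnsembleLayout(engines=tuple(self.engines), pattern=self.pattern,
                              receptor_chain=self.receptor_chain,
                              ligand_chain=self.ligand_chain)

    @property
    def energy_params(self) -> EnergyParams:
        return EnergyParams(epsilon0=self.epsilon0, pair_cutoff=self.pair_cutoff)

    def with_overrides(self, **overrides: Any) -> "RunConfig":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        if "engines" in overrides:
            overrides["engines"] = tuple(overrides["engines"])
        return replace(self, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "engines" in data:
            data["engines"] = tuple(data["engines"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["engines"] = list(data["engines"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
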