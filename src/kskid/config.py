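"""Run configuration: one JSON document covering every tunable stage
parameter, hashed into reports for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .pcr import BindingRules
from .primers import PrimerConstraints, TmConditions


@dataclass
class RunConfig:
    seed: int = 0
    bootstrap_replicates: int = 1000
    tolerance_bp: int = 10
    min_separation_bp: int = 30
    max_tm_spread: float = 6.0
    hca_metric: str = "jaccard"
    hca_linkage: str = "average"
    tm_method: str = "nearest_neighbor"
    tm_conditions: TmConditions = field(default_factory=TmConditions)
    pcr_rules: BindingRules = field(default_factory=BindingRules)
    primer_constraints: PrimerConstraints = field(
        default_factory=PrimerConstraints)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tm_conditions" in data:
            data["tm_conditions"] = TmConditions(**data["tm_conditions"])
        if "pcr_rules" in data:
            data["pcr_rules"] = BindingRules(**data["pcr_rules"])
        if "primer_constraints" in data:
            pc = data["primer_constraints"]
            for key in ("length", "gc", "tm"):
                if key in pc:
                    pc[key] = tuple(pc[key])
            data["primer_constraints"] = PrimerConstraints(**pc)
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
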