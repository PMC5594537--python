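"""Single-file YAML configuration for the whole pipeline.

Every tunable of every stage is a named field with a literature-default
value (E-value cutoff 1e-4, MFE threshold -15 kcal/mol, bulge bound 12,
duplex-mismatch bound 6, divergence time 15 MY, ...). A config serializes
to YAML and reloads with identical effect.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .homology import FilterThresholds, ScoringScheme
from .molevol import RateConfig
from .simulate import SimulationConfig


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    rate: RateConfig = field(default_factory=RateConfig)
    e_max: float = 1e-4
    min_locus_gap: int = 200
    te_min_identity: float = 0.8
    te_min_overlap: int = 50
    cluster_max_gap: int = 1000
    cluster_expected_deletion: int = 22
    neutrality_reps: int = 1000
    seed: int = 1

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scoring"].pop("lambda_", None)  # derived, recomputed on load
        data["simulation"]["cluster_spec"] = [
            list(t) for t in data["simulation"]["cluster_spec"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        sim = dict(kwargs.pop("simulation", {}))
        if "cluster_spec" in sim:
            sim["cluster_spec"] = [tuple(t) for t in sim["cluster_spec"]]
        if "background" in kwargs.get("scoring", {}):
            kwargs["scoring"]["background"] = tuple(kwargs["scoring"]["background"])
        cfg = cls(
            simulation=SimulationConfig(**sim),
            scoring=ScoringScheme(**kwargs.pop("scoring", {})),
            thresholds=FilterThresholds(**kwargs.pop("thresholds", {})),
            rate=RateConfig(**kwargs.pop("rate", {})),
            **kwargs,
        )
        return cfg

    def validate(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.neutrality_reps < 100:
            raise ValueError("neutrality_reps < 100 gives unusable p-values")
        for f in fields(self):
            getattr(self, f.name)  # dataclass invariants enforced in __post_init__s
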