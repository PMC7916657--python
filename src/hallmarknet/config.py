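"""Run configuration: a serializable record of every knob a run depends on."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import POLICIES


@dataclass
class RunConfig:
    """Everything a pipeline run needs; embedded verbatim in every report."""

    network: str = ""                      # SIF path or packaged fixture name
    policy: str = "inhibitor_wins"
    initial_mode: str = "zeros"            # zeros | ones
    initial_overrides: dict[str, int] = field(default_factory=dict)
    sweep_genes: list[list[str]] = field(default_factory=list)  # [gene, LOF|GOF]
    simulation_mode: str = "trajectory"    # trajectory | exhaustive
    exhaustive_bound: int = 25
    n_starts: int = 1
    seed: int = 0
    phenotype_names: list[str] = field(
        default_factory=lambda: ["proliferation", "differentiation", "apoptosis"]
    )
    normalized_scores: bool = False
    clinical: str = ""                     # optional clinical TSV path
    out_dir: str = "hallmarknet_out"

    def validate(self) -> None:
        if self.policy not in POLICIES[:2]:
            raise ValueError(
                f"unknown policy {self.policy!r}; expected one of {POLICIES[:2]}"
            )
        if self.initial_mode not in ("zeros", "ones"):
            raise ValueError(f"unknown initial_mode {self.initial_mode!r}")
        if self.simulation_mode not in ("trajectory", "exhaustive"):
            raise ValueError(f"unknown simulation_mode {self.simulation_mode!r}")
        for pair in self.sweep_genes:
            if len(pair) != 2 or pair[1] not in ("LOF", "GOF"):
                raise ValueError(f"bad sweep gene entry {pair!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
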