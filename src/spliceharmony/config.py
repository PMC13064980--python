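"""Run configuration: dialects, cutoffs, simulation grid, seed.

Every run writes its resolved configuration next to its outputs so a
result directory is self-describing and reproducible.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ParameterError
from .splice_sim import EmulatorNoise, SimConfig


@dataclass
class RunConfig:
    leafcutter_dialect: str = "regtools"
    majiq_dialect: str = "intronic"
    rmats_variant: str = "JC"
    junction_slop: int = 0
    dpsi_cutoff: float = 0.2
    confidence_cutoff: float = 0.95
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    noise: EmulatorNoise = field(default_factory=EmulatorNoise)

    def __post_init__(self) -> None:
        for name in ("dpsi_cutoff", "confidence_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} {v} outside [0, 1]")
        if self.junction_slop < 0:
            raise ParameterError("junction_slop must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["ratios"] = [list(r) for r in self.sim.ratios]
        d["sim"]["reads_per_transcript"] = list(self.sim.reads_per_transcript)
        return d

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sim_data = data.pop("sim", {}) or {}
        noise_data = data.pop("noise", {}) or {}
        if "ratios" in sim_data:
            sim_data["ratios"] = tuple(tuple(r) for r in sim_data["ratios"])
        if "reads_per_transcript" in sim_data:
            sim_data["reads_per_transcript"] = tuple(sim_data["reads_per_transcript"])
        return cls(sim=SimConfig(**sim_data), noise=EmulatorNoise(**noise_data), **data)


def write_resolved(config: RunConfig, outdir: str | os.PathLike) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "resolved_config.yaml"
    config.write(path)
    return path
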