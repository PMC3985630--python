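"""Pipeline configuration: a YAML-serializable parameter container.

One config object drives the whole pipeline (sites -> simulate -> align ->
stats).  The single top-level seed feeds every stochastic stage through
named substreams, so a config plus a seed reproduces a run byte-for-byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .align import AlignmentParams
from .simulate import (
    CombingModel,
    FragmentationParams,
    LabellingParams,
    SimulationParams,
)
from .stats import HistogramSpec

__all__ = ["PipelineConfig"]


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    enzyme: str = "M.TaqI"
    include_star: bool = False
    ligand: str = "TBTA"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    global_stretch: bool = False
    output_dir: str = "fluorocode_out"
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["length_bp_range"] = list(d["simulation"]["length_bp_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "length_bp_range" in sim:
            sim["length_bp_range"] = tuple(sim["length_bp_range"])
        for key, sub in (
            ("combing", CombingModel),
            ("fragmentation", FragmentationParams),
            ("labelling", LabellingParams),
        ):
            if key in sim:
                sim[key] = _build(sub, sim[key])
        d["simulation"] = _build(SimulationParams, sim)
        d["alignment"] = _build(AlignmentParams, dict(d.pop("alignment", {})))
        d["histogram"] = _build(HistogramSpec, dict(d.pop("histogram", {})))
        return _build(cls, d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
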