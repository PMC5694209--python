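"""Pipeline configuration: one YAML-round-trippable object.

Every run writes its fully resolved configuration next to its outputs so
results are reproducible from the report directory alone.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .classify import ClassifyParams
from .consensus import DEFAULT_PRIORITY
from .hydropathy import HydroParams

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PipelineConfig:
    hydro: HydroParams = field(default_factory=HydroParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    min_overlap: int = 5
    tmhmm_threshold: float = 0.90
    tmhmm_statistic: str = "mean"
    predictor_priority: tuple[str, ...] = DEFAULT_PRIORITY
    als_coverage_min: float = 0.9
    align_match: float = 2.0
    align_mismatch: float = -1.0
    align_gap_open: float = -5.0
    align_gap_extend: float = -1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["predictor_priority"] = list(self.predictor_priority)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "hydro" in d:
            d["hydro"] = HydroParams(**d["hydro"])
        if "classify" in d:
            d["classify"] = ClassifyParams(**d["classify"])
        if "predictor_priority" in d:
            d["predictor_priority"] = tuple(d["predictor_priority"])
        return cls(**d)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
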