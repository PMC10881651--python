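"""Run configuration: one object, one seed, lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ChipGeometry
from .hits import HitCriteria
from .imaging import DetectionParams
from .synth.library import EffectMixture
from .synth.phenotype import NoiseParams
from .synth.render import RenderParams


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end screen run depends on.

    Every stochastic stage derives its randomness from ``seed`` alone;
    two runs with equal configs produce byte-identical outputs.
    """

    seed: int = 0
    n_plates: int = 1
    n_compounds: int = 24
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    noise: NoiseParams = field(default_factory=NoiseParams)
    render: RenderParams = field(default_factory=RenderParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    criteria: HitCriteria = field(default_factory=HitCriteria)
    mixture: EffectMixture = field(default_factory=EffectMixture)
    use_imaging: bool = True          # False: score ground-truth positions directly
    write_images: bool = False        # persist per-chip TIFFs under images/
    min_plate_vehicle: int = 4        # below this, batch-pooled vehicle stats
    mad_consistency: bool = False     # scale MAD by 1.4826 in Z*

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        sub = {
            "geometry": ChipGeometry,
            "noise": NoiseParams,
            "render": RenderParams,
            "detection": DetectionParams,
            "criteria": HitCriteria,
            "mixture": EffectMixture,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                payload = dict(d[key])
                for f in dataclasses.fields(typ):
                    if f.name in payload and isinstance(payload[f.name], list):
                        payload[f.name] = tuple(payload[f.name])
                d[key] = typ(**payload)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
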