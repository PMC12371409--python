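"""Model declaration files: YAML/JSON round-trip of units, resources, toxin, parameters."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .parameters import ParameterSet
from .units import (
    PromoterSpec,
    ResourceSpec,
    ToxinConfig,
    TranscriptionUnitSpec,
    default_promoters,
)

__all__ = ["ModelConfig", "load_config", "save_config"]


class ModelConfig:
    """In-memory model declaration: units + resources + toxin + parameters."""

    def __init__(
        self,
        units: list[TranscriptionUnitSpec],
        resources: ResourceSpec,
        toxin: ToxinConfig,
        parameters: ParameterSet,
    ):
        self.units = units
        self.resources = resources
        self.toxin = toxin
        self.parameters = parameters

    def to_dict(self) -> dict:
        unit_dicts = []
        for u in self.units:
            d = asdict(u)
            d["promoter"] = u.promoter.name
            d["promoter_kinetics"] = {
                "polymerase_class": u.promoter.polymerase_class,
                "kf_tx": u.promoter.kf_tx,
                "kr_tx": u.promoter.kr_tx,
            }
            unit_dicts.append(d)
        return {
            "units": unit_dicts,
            "resources": asdict(self.resources),
            "toxin": asdict(self.toxin),
            "parameters": self.parameters.as_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        units = []
        for ud in d.get("units", []):
            ud = dict(ud)
            pk = ud.pop("promoter_kinetics", None)
            pname = ud.pop("promoter")
            if pk is not None:
                prom = PromoterSpec(pname, pk["polymerase_class"], pk["kf_tx"], pk["kr_tx"])
            else:
                prom = default_promoters()[pname]
            units.append(TranscriptionUnitSpec(promoter=prom, **ud))
        return cls(
            units=units,
            resources=ResourceSpec(**d.get("resources", {})),
            toxin=ToxinConfig(**d.get("toxin", {})),
            parameters=ParameterSet(d.get("parameters", {})),
        )


def save_config(config: ModelConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=2)


def load_config(path) -> ModelConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return ModelConfig.from_dict(d)
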