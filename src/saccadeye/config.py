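"""Experiment configuration: per-module parameter blocks, YAML/JSON I/O."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import GeometryConfig
from .kinematics import KineticsParams
from .phototransduction import PhotoreceptorParams

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Bundled per-module parameters plus reproducibility bookkeeping."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    photoreceptor: PhotoreceptorParams = field(default_factory=PhotoreceptorParams)
    inference: dict = field(default_factory=dict)  # depth-trial keyword overrides
    acuity: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        try:
            self.geometry.validate()
            self.kinetics.validate()
            self.photoreceptor.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "kinetics": dataclasses.asdict(self.kinetics),
            "photoreceptor": dataclasses.asdict(self.photoreceptor),
            "inference": dict(self.inference),
            "acuity": dict(self.acuity),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build_block(cls, block: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config block {name!r}")
    coerced = {}
    for k, v in block.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML/JSON file (defaults if None)."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    if overrides:
        data = {**data, **overrides}
    cfg = ExperimentConfig(
        geometry=_build_block(GeometryConfig, data.get("geometry", {}), "geometry"),
        kinetics=_build_block(KineticsParams, data.get("kinetics", {}), "kinetics"),
        photoreceptor=_build_block(PhotoreceptorParams,
                                   data.get("photoreceptor", {}), "photoreceptor"),
        inference=dict(data.get("inference", {})),
        acuity=dict(data.get("acuity", {})),
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "results")),
    )
    cfg.validate()
    return cfg
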