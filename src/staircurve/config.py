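"""Pipeline configuration: nested dataclasses, YAML/JSON loading and a
stable content hash for the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig, GainModel, Moments
from .learning_curve import FitConfig
from .staircase import ProtocolConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    welch: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        if "cohort" in data:
            kwargs["cohort"] = _cohort_from_dict(data.pop("cohort"))
        if "protocol" in data:
            kwargs["protocol"] = ProtocolConfig(**data.pop("protocol"))
        if "fit" in data:
            fit = data.pop("fit")
            for key in ("alpha_bounds", "beta_bounds", "gamma_bounds"):
                if key in fit:
                    fit[key] = tuple(fit[key])
            kwargs["fit"] = FitConfig(**fit)
        kwargs.update(data)
        config = cls(**kwargs)
        # one cohort seed, derived from the pipeline seed unless set explicitly
        if config.cohort.seed == 0 and config.seed != 0:
            config = dataclasses.replace(config, cohort=config.cohort.with_seed(config.seed))
        return config


def _cohort_from_dict(data: dict) -> CohortConfig:
    data = dict(data)
    for key in ("alpha", "beta", "gamma", "age",
                "moca_pre_training", "moca_pre_control",
                "mmse_pre_training", "mmse_pre_control"):
        if key in data and not isinstance(data[key], Moments):
            val = data[key]
            data[key] = Moments(**val) if isinstance(val, dict) else Moments(*val)
    for key in ("moca_gain_training", "mmse_gain_training",
                "moca_gain_control", "mmse_gain_control"):
        if key in data and not isinstance(data[key], GainModel):
            val = data[key]
            data[key] = GainModel(**val) if isinstance(val, dict) else GainModel(*val)
    if "latent_corr" in data:
        data["latent_corr"] = np.asarray(data["latent_corr"], dtype=float)
    return CohortConfig(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    """sha256 over the canonical JSON rendering; stable across platforms."""
    blob = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()
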