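"""YAML run configuration with dotted-key overrides.

A run config bundles the cohort spec, encoder/evidential-layer
settings, the fusion spec and the training hyperparameters; defaults
mirror the reference setup (20 prototypes, 32-dim structured features,
128 text hidden units, α=2, β=1, batch 32, ≤150 epochs, 5 folds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .encoders import StructuredEncoderConfig, TextEncoderConfig
from .evidence import EMConfig
from .fusion import FusionSpec
from .synthetic import CohortSpec
from .training import TrainConfig

__all__ = ["RunConfig", "load_run_config", "config_hash"]

_SECTIONS = {
    "cohort": CohortSpec,
    "encoder": StructuredEncoderConfig,
    "text": TextEncoderConfig,
    "em": EMConfig,
    "fusion": FusionSpec,
    "train": TrainConfig,
}


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    encoder: StructuredEncoderConfig = field(default_factory=StructuredEncoderConfig)
    text: TextEncoderConfig = field(default_factory=TextEncoderConfig)
    em: EMConfig = field(default_factory=EMConfig)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0


def _build_section(cls, payload: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(payload)
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    return cls(**kwargs)


def load_run_config(path=None, overrides: dict | None = None,
                    seed: int | None = None) -> RunConfig:
    """Load a YAML config (all sections optional), apply dotted-key
    overrides like ``train.alpha=1.5``, and force the seed if given."""
    payload: dict = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if not key:
            payload[section] = value
            continue
        payload.setdefault(section, {})[key] = value
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, payload.get(name, {}) or {})
    rc = RunConfig(**kwargs, seed=int(payload.get("seed", 0)))
    if seed is not None:
        rc.seed = seed
        rc.cohort.seed = seed
        rc.train.seed = seed
    return rc


def config_hash(rc: RunConfig) -> str:
    blob = json.dumps(asdict(rc), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
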