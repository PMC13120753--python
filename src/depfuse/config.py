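"""Run configuration: nested sections, YAML loading, strict key checking."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion_model import FusionConfig
from .synthetic_data import GeneratorConfig
from .training import TrainConfig


@dataclass
class EncodingConfig:
    window_length: float = 3.0
    codebook_k: int = 100
    max_tokens_per_window: int = 32
    d_w: int = 32
    d_s: int = 32
    include_agent: bool = False


@dataclass
class AugmentationConfig:
    resample: str = "within-window"
    paraphrases_per_session: int = 1


@dataclass
class EscConfig:
    k: int = 5
    noise_rate: float = 0.4
    context_sentences: int = 10


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    feature_encoding: EncodingConfig = field(default_factory=EncodingConfig)
    fusion_model: FusionConfig = field(default_factory=FusionConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    esc: EscConfig = field(default_factory=EscConfig)
    synthetic_data: GeneratorConfig = field(default_factory=GeneratorConfig)


def _field_default(f: dataclasses.Field):
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        return f.default_factory()  # type: ignore[misc]
    if f.default is not dataclasses.MISSING:
        return f.default
    return None


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        default = _field_default(fields[key])
        if dataclasses.is_dataclass(default) and isinstance(value, dict):
            kwargs[key] = _build(type(default), value, f"{path}.{key}")
        else:
            if isinstance(default, tuple) and isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return _build(RunConfig, data, "run")


class JsonLineFormatter(logging.Formatter):
    """One JSON object per log record: timestamp, module, level, event."""

    def format(self, record: logging.LogRecord) -> str:
        return json.dumps({
            "ts": self.formatTime(record, "%Y-%m-%dT%H:%M:%S"),
            "module": record.name,
            "level": record.levelname,
            "event": record.getMessage(),
        })


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(JsonLineFormatter())
    root = logging.getLogger("depfuse")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())
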