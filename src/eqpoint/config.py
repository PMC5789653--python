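"""YAML/JSON round-tripping for systems, population specs and run configs."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .feedback_core import FeedbackSystem
from .population_models import PopulationSpec

__all__ = [
    "system_to_yaml",
    "system_from_yaml",
    "population_spec_to_yaml",
    "population_spec_from_yaml",
    "load_yaml_block",
]


def load_yaml_block(text_or_path) -> dict:
    """Parse a YAML (or JSON — a YAML subset) mapping from a string or path."""
    text = str(text_or_path)
    looks_like_path = isinstance(text_or_path, Path) or (
        "\n" not in text and len(text) < 4096
    )
    if looks_like_path and Path(text).exists():
        try:
            text = Path(text).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config {text_or_path!r}: {exc}") from exc
    block = yaml.safe_load(text)
    if not isinstance(block, dict):
        raise ConfigError("config block must be a mapping")
    return block


def system_to_yaml(system: FeedbackSystem) -> str:
    return yaml.safe_dump(system.to_dict(), sort_keys=True)


def system_from_yaml(text_or_path) -> FeedbackSystem:
    return FeedbackSystem.from_dict(load_yaml_block(text_or_path))


def population_spec_to_yaml(spec: PopulationSpec) -> str:
    return yaml.safe_dump(spec.to_dict(), sort_keys=True)


def population_spec_from_yaml(text_or_path) -> PopulationSpec:
    return PopulationSpec.from_dict(load_yaml_block(text_or_path))


def to_json(obj: dict) -> str:
    return json.dumps(obj, indent=2, sort_keys=True)
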