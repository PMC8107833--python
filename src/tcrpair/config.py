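"""YAML run configuration and reproducibility manifests.

A run config is a flat YAML document with optional sections ``signal``,
``split``, ``features``, ``encoder`` and ``training`` whose keys map onto
the corresponding dataclasses. CLI flags override config keys, and all
randomness flows from a single root seed recorded in the manifest each
subcommand writes next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import yaml

from .encoders import SequenceEncoderSpec
from .model import FeatureConfig, TrainSpec
from .sampling import SplitSpec
from .simulate import SignalSpec

_SECTIONS = {
    "signal": SignalSpec,
    "split": SplitSpec,
    "features": FeatureConfig,
    "encoder": SequenceEncoderSpec,
    "training": TrainSpec,
}


class ConfigError(ValueError):
    pass


def _build(cls, section: dict, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    merged = {**section, **{k: v for k, v in overrides.items() if v is not None}}
    unknown = set(merged) - valid
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if "peptides" in merged and isinstance(merged["peptides"], list):
        merged["peptides"] = tuple(merged["peptides"])
    return cls(**merged)


def load_config(path: str | Path | None, **overrides_by_section) -> dict:
    """Parse a YAML config into spec dataclasses, applying CLI overrides.

    Returns ``{"signal": SignalSpec, "split": SplitSpec, ...}`` with
    defaults for omitted sections.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        unknown = set(raw) - set(_SECTIONS)
        if unknown:
            raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        out[name] = _build(cls, section, overrides_by_section.get(name, {}))
    return out


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, stage: str, seed: int,
                   config_snapshot: dict, inputs: list[str | Path],
                   outputs: list[str | Path]) -> None:
    """Record everything needed to reproduce one CLI run."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config_snapshot,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str),
                          encoding="utf-8")


def snapshot(specs: dict) -> dict:
    return {name: dataclasses.asdict(s) for name, s in specs.items()}
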