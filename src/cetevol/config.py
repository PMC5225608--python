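"""Run configuration (YAML) with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    alignment: str | None = None
    tree: str | None = None
    clades: str | None = None
    labels: str | None = None
    models: list[str] = field(default_factory=lambda: ["one-ratio", "M1", "M2"])
    freq: str = "F3x4"
    min_species: int = 3
    fdr_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    def validate_paths(self, base: Path | None = None) -> None:
        base = base or Path(".")
        for name in ("alignment", "tree", "clades", "labels"):
            value = getattr(self, name)
            if value is not None and not (base / value).exists():
                raise ConfigError(f"{name} file does not exist: {value}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate_paths(Path(path).parent)
    return cfg
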