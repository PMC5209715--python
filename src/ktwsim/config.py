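"""Run configuration files: YAML/JSON round-tripping of a full run setup."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .params import ConfigError, SimulationParams


@dataclass
class RunConfig:
    """Everything a run needs: simulation parameters plus output plumbing."""

    params: SimulationParams
    outdir: str = "."
    burn_in_fraction: float = 1.0 / 3.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in_fraction < 1:
            raise ConfigError("burn_in_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            outdir=self.outdir,
            burn_in_fraction=self.burn_in_fraction,
            label=self.label,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        extras = {
            name: d.pop(name)
            for name in ("outdir", "burn_in_fraction", "label")
            if name in d
        }
        return cls(params=SimulationParams.from_dict(d), **extras)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML or JSON config file; keyword overrides win over the file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    d.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(d)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path
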