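"""Run configuration: defaults, YAML loading, validation, provenance echo."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .core import OptimizerConfig, Toggles
from .kernels import MapKind

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Hierarchical run configuration with strict key checking."""

    optimizer: dict[str, Any] = field(default_factory=dict)
    toggles: dict[str, Any] = field(default_factory=dict)
    fs: dict[str, Any] = field(default_factory=dict)
    synth: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out: str = "results"

    def optimizer_config(self) -> OptimizerConfig:
        valid = {f.name for f in fields(OptimizerConfig)}
        unknown = set(self.optimizer) - valid
        if unknown:
            raise ValueError(f"unknown optimizer config key(s): {sorted(unknown)}")
        kw = dict(self.optimizer)
        if "map_kind" in kw:
            kw["map_kind"] = MapKind(kw["map_kind"])
        tog_valid = {f.name for f in fields(Toggles)}
        tog_unknown = set(self.toggles) - tog_valid
        if tog_unknown:
            raise ValueError(f"unknown toggle key(s): {sorted(tog_unknown)}")
        return OptimizerConfig(**kw, toggles=Toggles(**self.toggles))

    def echo(self, directory: Path) -> None:
        """Write the fully resolved config next to the outputs."""
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config_echo.json").write_text(json.dumps(asdict(self), indent=1))


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load YAML (or JSON) config; keyword overrides take precedence.

    Unknown top-level keys are rejected with the offending name.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for k, v in overrides.items():
        if v is None:
            continue
        if k not in valid:
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(data.get(k), dict) and isinstance(v, dict):
            data[k] = {**data[k], **v}
        else:
            data[k] = v
    return RunConfig(**data)
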