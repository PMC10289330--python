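"""Run configuration: defaults, YAML loading, CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    tau: float = 10.0
    beta: float = 45.0
    connectivity: int = 8
    f2_mode: str = "standard"
    reassign_line_pixels: bool = False
    seed: int = 0
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.f2_mode not in ("standard", "as_printed"):
            raise ValueError("f2_mode must be 'standard' or 'as_printed'")
        if self.log_level not in ("debug", "info", "warn"):
            raise ValueError("log_level must be debug, info or warn")

    def with_overrides(self, **kwargs) -> "RunConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path=None) -> RunConfig:
    """Load a flat key-value YAML config; missing file fields use defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
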