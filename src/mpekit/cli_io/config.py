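"""Run configuration: a YAML-backed record of everything needed to rerun a command."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]

_COMMANDS = ("fit", "predict", "simulate", "sweep", "mpe-test")


@dataclass
class RunConfig:
    """Declarative description of one CLI run.

    Every stochastic command must carry an explicit seed so any published
    output is exactly regenerable from its config file.
    """

    command: str
    inputs: dict = field(default_factory=dict)
    output: Optional[str] = None
    model: Optional[str] = None
    seed: Optional[int] = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; expected one of {_COMMANDS}")
        if self.command in ("simulate", "sweep", "mpe-test") and self.seed is None:
            raise ValueError(f"command {self.command!r} is stochastic and requires a seed")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)
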