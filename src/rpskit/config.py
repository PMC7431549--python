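"""Run configuration: a YAML mirror of the engine's knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit.

    ``opponent`` is a strategy spec mapping (name + parameters + seed) or
    the string ``"interactive"`` for a live session.
    """

    orders: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    focus: int = 5
    rounds: int = 300
    a: float = 2.0
    master_seed: int = 0
    policy: str = "argmax"
    opponent: dict | str = "interactive"
    out: str | None = None
    summary_out: str | None = None

    def __post_init__(self) -> None:
        self.orders = [int(m) for m in self.orders]
        if not self.orders:
            raise ValueError("config field 'orders' must be nonempty")
        if len(set(self.orders)) != len(self.orders) or min(self.orders) < 1:
            raise ValueError(
                f"config field 'orders' must be distinct positive integers, got {self.orders}"
            )
        if self.focus < 1:
            raise ValueError(f"config field 'focus' must be >= 1, got {self.focus}")
        if self.rounds < 0:
            raise ValueError(f"config field 'rounds' must be >= 0, got {self.rounds}")
        if self.a <= 0:
            raise ValueError(f"config field 'a' must be positive, got {self.a}")
        if self.policy not in ("argmax", "sample"):
            raise ValueError(f"config field 'policy' must be argmax|sample, got {self.policy!r}")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
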