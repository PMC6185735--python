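"""Run configuration: every pipeline tunable in one validated record.

Defaults follow the method's published operating point where one exists
(7x7 patches, 12 filters per stage, 7x7 similarity and 17x17 search
windows, PReLU slope 0.25, speckle exponent 0.5); the remaining values are
this package's frozen choices, documented in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    k1: int = 7
    k2: int = 7
    L1: int = 12
    L2: int = 12
    activation: str = "prelu"
    a: float = 0.25
    sim_window: int = 7
    search_window: int = 17
    beta: float = 20.0
    prefilter_beta: float = 0.6
    alpha: float | None = None
    gamma: float = 0.5
    passes: int = 2
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "sim_window", "search_window"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {v!r}")
        for name in ("L1", "L2", "passes"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.L1 > self.k1 * self.k2 or self.L2 > self.k1 * self.k2:
            raise ValueError("L1 and L2 cannot exceed the patch dimension k1*k2")
        if self.activation not in ("prelu", "relu", "sigmoid", "hash"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.a < 0:
            raise ValueError(f"a must be non-negative, got {self.a}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.prefilter_beta <= 0:
            raise ValueError(f"prefilter_beta must be positive, got {self.prefilter_beta}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.sim_window > self.search_window:
            raise ValueError("sim_window must not exceed search_window")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults <- YAML file <- keyword overrides.

    Unknown keys, in the file or in the overrides, are rejected.
    Override values of None mean "not supplied" and are ignored, so CLI
    flags can pass through unset options.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        values.update(loaded)
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config overrides: {sorted(unknown)}")
    for key, val in overrides.items():
        if val is None:
            continue
        values[key] = val
    return RunConfig(**values)
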