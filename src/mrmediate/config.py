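"""Run configuration: analysis thresholds, seeds, YAML round-trip.

Defaults reproduce the conventional thresholds of the screening design:
suggestive instrument p < 1e-5, clumping at r² < 0.001 within 10,000 kb,
weak-instrument cutoff F < 10, forward-screen tiers at p < 0.05 / 0.01,
reverse-causality clearance at p > 0.05 and Bayesian confirmation at
p < 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    p_instrument: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_min: float = 10.0
    tier_suggestive: float = 0.05
    tier_significant: float = 0.01
    reverse_clear_p: float = 0.05
    bayes_confirm_p: float = 0.05
    palindrome_eaf_window: float = 0.08
    n_boot: int = 1000
    seeds: dict[str, int] = field(default_factory=lambda: {
        "simulate": 1, "estimators": 2, "bootstrap": 3})

    def __post_init__(self) -> None:
        for name in ("p_instrument", "tier_suggestive", "tier_significant",
                     "reverse_clear_p", "bayes_confirm_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} must lie in (0,1)")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigError(f"clump_r2={self.clump_r2} must lie in [0,1]")
        if self.tier_significant > self.tier_suggestive:
            raise ConfigError("tier_significant must not exceed tier_suggestive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
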