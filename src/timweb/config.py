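"""Run configuration: YAML round-trip with validated, complete defaults.

Defaults reproduce the comparison protocol (Test 1): 35-species niche
webs at connectance 0.14, retention at 18 persisting species, TIM rate
0.05 with alpha ~ U(-4,4), sigma ~ U(0.1,4), tau ~ U(-1,1), one
modifier per interaction, targeted mortality m = 1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import IntegrationConfig
from .experiments import TIMExperimentConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class CommunityConfig:
    S: int = 35
    C: float = 0.14
    n_communities: int = 20
    retention_min: int = 18
    B_init: float = 10.0

    def validate(self) -> None:
        if self.S < 2:
            raise ValueError("community.S must be >= 2")
        if not (0.0 < self.C < 0.5):
            raise ValueError("community.C must be in (0, 0.5)")
        if self.retention_min < 1 or self.retention_min > self.S:
            raise ValueError("community.retention_min must be in [1, S]")
        if self.B_init <= 0:
            raise ValueError("community.B_init must be > 0")


@dataclass
class ExperimentConfig:
    modes: tuple[str, ...] = ("none", "full", "pairwise")
    target_mortality: float = 1.0

    def validate(self) -> None:
        from .dynamics import MODES
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown experiment modes: {sorted(bad)}")


@dataclass
class RunConfig:
    """Complete, serializable settings for one simulation run."""

    community: CommunityConfig = field(default_factory=CommunityConfig)
    dynamics: IntegrationConfig = field(default_factory=IntegrationConfig)
    tim: TIMExperimentConfig = field(default_factory=TIMExperimentConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.community.validate()
        self.experiment.validate()
        if not (0.0 <= self.tim.rate <= 1.0):
            raise ValueError("tim.rate must be in [0, 1]")
        if self.tim.sigma_range[0] <= 0:
            raise ValueError("tim.sigma_range must be positive")
        if self.dynamics.rel_tol <= 0 or self.dynamics.t_window <= 0:
            raise ValueError("dynamics tolerances must be positive")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["experiment"]["modes"] = list(self.experiment.modes)
        d["tim"]["modes"] = list(self.tim.modes)
        for key in ("alpha_range", "sigma_range", "tau_range"):
            d["tim"][key] = list(d["tim"][key])
        return d


_BLOCKS = {
    "community": CommunityConfig,
    "dynamics": IntegrationConfig,
    "tim": TIMExperimentConfig,
    "experiment": ExperimentConfig,
}
_TUPLE_KEYS = {"modes", "alpha_range", "sigma_range", "tau_range"}


def _build_block(cls, raw: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown keys in {cls.__name__}: {sorted(unknown)}"
        )
    kwargs = {
        k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
        for k, v in raw.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; missing blocks take defaults.

    Unknown top-level or block keys are rejected with a descriptive
    error; an empty file yields the full default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    kwargs = {
        name: _build_block(cls, raw.get(name, {}) or {})
        for name, cls in _BLOCKS.items()
    }
    kwargs["seed"] = int(raw.get("seed", 0))
    return RunConfig(**kwargs).validate()


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False)
    )
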