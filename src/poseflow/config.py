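"""Pipeline configuration: one diffable YAML file with per-stage sections.

Defaults are the protocol's standard parameters: 3 Å cluster cutoff, 10 ns
MSM lag, 1 Å grid at 300 K with a 1.0 kcal/mol reporting contour, 20 Å
unbound / 3 Å bound macrostate cutoffs, 50% pathway-flux fraction, and
10 μs convergence checkpoints.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "DataError", "PipelineConfig"]


class ConfigError(ValueError):
    """Invalid configuration value; message names the offending key."""


class DataError(RuntimeError):
    """Missing or inconsistent stage inputs."""


@dataclass
class PathsConfig:
    trajectories: list[str] = field(default_factory=list)
    topology: str = ""
    reference: str = ""
    frame_spacing_ns: float = 0.1


@dataclass
class ClusterConfig:
    cutoff: float = 3.0
    stride: int = 100
    kmedoid_iters: int = 3
    rng_seed: int = 0
    assign_stride: int = 0  # 0 -> same as stride


@dataclass
class MSMConfig:
    lag_ns: float = 10.0
    lag_scan_ns: list[float] = field(default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 20.0])
    mode: str = "reversible-mle"
    sliding: bool = True


@dataclass
class GridConfig:
    spacing: float = 1.0
    temperature: float = 300.0
    contour: float = 1.0


@dataclass
class TPTConfig:
    unbound_cutoff: float = 20.0
    bound_cutoff: float = 3.0
    pathway_fraction: float = 0.5


@dataclass
class ConvergenceConfig:
    interval_us: float = 10.0
    tolerance: float = 0.5


@dataclass
class SeedingConfig:
    policy: str = "inverse-counts"
    n_seeds: int = 10
    rng_seed: int = 0


@dataclass
class SimulateConfig:
    n_steps: int = 2000
    n_trajectories: int = 12
    seed: int = 2025
    frame_spacing_ns: float = 0.1


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    msm: MSMConfig = field(default_factory=MSMConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    tpt: TPTConfig = field(default_factory=TPTConfig)
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    _SECTIONS = {
        "paths": PathsConfig,
        "cluster": ClusterConfig,
        "msm": MSMConfig,
        "grid": GridConfig,
        "tpt": TPTConfig,
        "convergence": ConvergenceConfig,
        "seeding": SeedingConfig,
        "simulate": SimulateConfig,
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for section, typ in cls._SECTIONS.items():
            data = raw.get(section, {})
            if not isinstance(data, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            valid = {f for f in typ.__dataclass_fields__}
            for key in data:
                if key not in valid:
                    raise ConfigError(f"unknown config key {section}.{key}")
            kwargs[section] = typ(**data)
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate(self) -> None:
        checks = [
            ("cluster.cutoff", self.cluster.cutoff > 0),
            ("cluster.stride", self.cluster.stride >= 1),
            ("cluster.kmedoid_iters", self.cluster.kmedoid_iters >= 0),
            ("cluster.assign_stride", self.cluster.assign_stride >= 0),
            ("msm.lag_ns", self.msm.lag_ns > 0),
            ("msm.mode", self.msm.mode in ("naive", "reversible-mle")),
            ("grid.spacing", self.grid.spacing > 0),
            ("grid.temperature", self.grid.temperature > 0),
            ("tpt.unbound_cutoff", self.tpt.unbound_cutoff > 0),
            ("tpt.bound_cutoff", self.tpt.bound_cutoff > 0),
            ("tpt.pathway_fraction", 0 <= self.tpt.pathway_fraction <= 1),
            ("convergence.interval_us", self.convergence.interval_us > 0),
            ("convergence.tolerance", self.convergence.tolerance > 0),
            ("seeding.n_seeds", self.seeding.n_seeds >= 1),
            ("seeding.policy", self.seeding.policy in ("uniform-states", "inverse-counts")),
            ("simulate.n_steps", self.simulate.n_steps >= 1),
            ("simulate.n_trajectories", self.simulate.n_trajectories >= 1),
            ("paths.frame_spacing_ns", self.paths.frame_spacing_ns > 0),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for config key {key}")
        spacing = self.paths.frame_spacing_ns * (self.cluster.assign_stride or self.cluster.stride)
        ratio = self.msm.lag_ns / spacing
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigError(
                "invalid value for config key msm.lag_ns: must be a positive integer "
                f"multiple of the assigned-frame spacing ({spacing:g} ns)"
            )
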