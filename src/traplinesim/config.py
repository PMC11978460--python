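"""Configuration loading and validation.

A run configuration is a YAML file with nested sections ``environment``,
``bee``, ``simulation`` and ``sweep``. Every parameter has a documented
default and range; unknown keys and out-of-range values are rejected
before any simulation starts, with the offending dotted key named. The
effective (post-default) configuration can be echoed back to an output
directory for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .cognition import BeeParams
from .environment import ConfigurationError, PatchSpec

__all__ = ["RunConfig", "EnvironmentConfig", "SimulationSection",
           "SweepSection", "load_config", "echo_config"]

SCHEMA_VERSION = "1"


@dataclass
class EnvironmentConfig:
    layout: str = "uniform"
    n_sites: int = 25
    arena_side: float = 500.0
    density: float | None = None
    buffer: float | None = None
    patch_radius_formula: str = "sqrt_density"
    max_nectar: float = 20.0
    renewal_duration: float = 500.0


@dataclass
class BeeConfig:
    alpha: float = 0.5
    beta: float = 20.0
    wm_span: float = 30.0
    crop_capacity: float | None = None  # None: 5 * max_nectar
    speed: float = 3.0
    max_bout_distance: float = 3000.0
    nest_wait: float = 300.0
    value_from_collected: bool = False


@dataclass
class SimulationSection:
    n_bees: int = 1
    horizon: float = 25200.0
    dt: float = 1.0


@dataclass
class SweepSection:
    profile: str = "ci"  # "ci" (scaled-down) or "paper"
    kind: str = "renewal_memory"  # spatial | renewal_memory | competition | control
    n_environments: int | None = None  # None: from profile
    sims_per_environment: int | None = None
    horizon: float | None = None
    reporting_bout: int | None = None


PROFILES = {
    "ci": {"n_environments": 5, "sims_per_environment": 2, "horizon": 7200.0},
    "paper": {
        "n_environments": 25,
        "sims_per_environment": 2,
        "horizon": 25200.0,
    },
}


@dataclass
class RunConfig:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    bee: BeeConfig = field(default_factory=BeeConfig)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    sweep: SweepSection = field(default_factory=SweepSection)
    schema_version: str = SCHEMA_VERSION

    def bee_params(self) -> BeeParams:
        crop = self.bee.crop_capacity
        if crop is None:
            crop = 5.0 * self.environment.max_nectar
        return BeeParams(
            alpha=self.bee.alpha,
            beta=self.bee.beta,
            wm_span=self.bee.wm_span,
            crop_capacity=crop,
            speed=self.bee.speed,
            max_bout_distance=self.bee.max_bout_distance,
            nest_wait=self.bee.nest_wait,
            value_from_collected=self.bee.value_from_collected,
        )

    def patch_spec(self) -> PatchSpec:
        if self.environment.density is None:
            raise ConfigurationError(
                "environment.density is required for patch layout"
            )
        return PatchSpec(
            n_sites=self.environment.n_sites,
            density=self.environment.density,
            buffer=self.environment.buffer,
            radius_formula=self.environment.patch_radius_formula,  # type: ignore[arg-type]
        )

    def sweep_protocol(self) -> dict[str, Any]:
        """Replication protocol with profile defaults filled in."""
        if self.sweep.profile not in PROFILES:
            raise ConfigurationError(
                f"sweep.profile must be one of {sorted(PROFILES)}"
            )
        proto = dict(PROFILES[self.sweep.profile])
        for key in ("n_environments", "sims_per_environment", "horizon"):
            val = getattr(self.sweep, key)
            if val is not None:
                proto[key] = val
        proto["reporting_bout"] = self.sweep.reporting_bout
        return proto


_SECTIONS = {
    "environment": EnvironmentConfig,
    "bee": BeeConfig,
    "simulation": SimulationSection,
    "sweep": SweepSection,
}

_RANGES: dict[str, tuple[float, float]] = {
    "bee.alpha": (0.0, 1.0),
    "bee.beta": (0.0, float("inf")),
    "bee.wm_span": (0.0, float("inf")),
    "bee.speed": (1e-12, float("inf")),
    "bee.max_bout_distance": (1e-12, float("inf")),
    "bee.nest_wait": (1e-12, float("inf")),
    "environment.n_sites": (2, float("inf")),
    "environment.arena_side": (1e-12, float("inf")),
    "environment.max_nectar": (1e-12, float("inf")),
    "environment.renewal_duration": (1e-12, float("inf")),
    "simulation.n_bees": (1, float("inf")),
    "simulation.horizon": (1e-12, float("inf")),
    "simulation.dt": (1e-12, float("inf")),
}

_CHOICES: dict[str, tuple[str, ...]] = {
    "environment.layout": ("uniform", "patch"),
    "environment.patch_radius_formula": ("sqrt_density", "literal"),
    "sweep.profile": ("ci", "paper"),
    "sweep.kind": ("spatial", "renewal_memory", "competition", "control"),
}


def _build_section(name: str, cls, data: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigurationError(f"unknown key {name}.{key}")
    section = cls(**data)
    for f in fields(cls):
        dotted = f"{name}.{f.name}"
        val = getattr(section, f.name)
        if dotted in _RANGES and val is not None:
            lo, hi = _RANGES[dotted]
            if not (lo <= val <= hi):
                raise ConfigurationError(
                    f"{dotted} = {val} outside allowed range [{lo}, {hi}]"
                )
        if dotted in _CHOICES and val not in _CHOICES[dotted]:
            raise ConfigurationError(
                f"{dotted} = {val!r} not one of {_CHOICES[dotted]}"
            )
    return section


def config_from_mapping(data: dict[str, Any] | None) -> RunConfig:
    """Validate a parsed mapping into a :class:`RunConfig`."""
    data = dict(data or {})
    version = str(data.pop("schema_version", SCHEMA_VERSION))
    sections = {}
    for name, cls in _SECTIONS.items():
        raw = data.pop(name, {}) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"section {name!r} must be a mapping")
        sections[name] = _build_section(name, cls, raw)
    if data:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(data)}")
    cfg = RunConfig(schema_version=version, **sections)
    cfg.bee_params()  # triggers BeeParams range validation
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the all-defaults configuration. Round-trip
    stability: loading an echoed configuration reproduces the original
    effective configuration exactly.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigurationError(f"cannot parse {path}: {err}") from err
    if data is not None and not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_mapping(data)


def echo_config(cfg: RunConfig, directory: str | Path,
                name: str = "config.effective.yaml") -> Path:
    """Write the effective configuration to *directory* for provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / name
    out.write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return out
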