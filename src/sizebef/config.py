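"""Flat key/value configuration handling.

One YAML file with flat ``key: value`` pairs configures everything: the
allometric constants, the ecosystem process rates, the seasonal forcing
shape and the experiment design.  Keys are routed to the owning
parameter class by name; unknown keys are rejected (no silent typos) and
invariant violations are reported with the key, value and constraint.
An empty file yields the full default configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import yaml

from .allometry import AllometricParams
from .ecosystem import DiversityControls, EcosystemParams
from .experiments import ExperimentConfig
from .forcing import Forcing

__all__ = ["ConfigError", "FullConfig", "load_config", "save_config", "config_template"]

log = logging.getLogger("sizebef")


class ConfigError(ValueError):
    """Invalid or unknown configuration input."""


#: Forcing fields settable from a config file.  The seasonal nutrient
#: amplitude is owned by the experiment section ('low'/'high' selector or
#: a float), so it is excluded here.
_FORCING_KEYS = tuple(
    f.name for f in fields(Forcing) if f.name != "amplitude"
)
_ALLOMETRY_KEYS = tuple(f.name for f in fields(AllometricParams))
_ECOSYSTEM_KEYS = tuple(f.name for f in fields(EcosystemParams))
_EXPERIMENT_KEYS = tuple(f.name for f in fields(ExperimentConfig))


@dataclass
class FullConfig:
    """Validated full model configuration."""

    allometry: AllometricParams = field(default_factory=AllometricParams)
    ecosystem: EcosystemParams = field(default_factory=EcosystemParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    forcing_overrides: dict = field(default_factory=dict)

    def forcing(self) -> Forcing:
        """Seasonal forcing implied by the experiment amplitude and overrides."""
        return Forcing(amplitude=self.experiment.amplitude_value, **self.forcing_overrides)

    def controls(self) -> DiversityControls:
        return DiversityControls(u=self.experiment.u, a_g=self.experiment.a_g)

    def to_flat_dict(self) -> dict:
        out = {}
        for section, keys in (
            (self.allometry, _ALLOMETRY_KEYS),
            (self.ecosystem, _ECOSYSTEM_KEYS),
            (self.experiment, _EXPERIMENT_KEYS),
        ):
            for k in keys:
                v = getattr(section, k)
                out[k] = list(v) if isinstance(v, tuple) else v
        forcing = self.forcing()
        for k in _FORCING_KEYS:
            out[k] = getattr(forcing, k)
        return out


def load_config(path) -> FullConfig:
    """Read and validate a flat YAML config; defaults fill missing keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping of key: value pairs, got {type(raw).__name__}")
    return from_dict(raw)


def from_dict(raw: dict) -> FullConfig:
    """Build a validated FullConfig from a flat mapping."""
    buckets = {"allometry": {}, "ecosystem": {}, "experiment": {}, "forcing": {}}
    for key, value in raw.items():
        if key in _ALLOMETRY_KEYS:
            buckets["allometry"][key] = value
        elif key in _ECOSYSTEM_KEYS:
            buckets["ecosystem"][key] = value
        elif key in _EXPERIMENT_KEYS:
            if key == "levels" and isinstance(value, list):
                value = tuple(value)
            buckets["experiment"][key] = value
        elif key in _FORCING_KEYS:
            buckets["forcing"][key] = value
        else:
            raise ConfigError(f"unknown configuration key {key!r}")

    def build(cls, kwargs, section):
        try:
            return cls(**kwargs)
        except ValueError as exc:
            offending = {k: v for k, v in kwargs.items()}
            raise ConfigError(f"invalid {section} configuration {offending}: {exc}") from exc

    cfg = FullConfig(
        allometry=build(AllometricParams, buckets["allometry"], "allometry"),
        ecosystem=build(EcosystemParams, buckets["ecosystem"], "ecosystem"),
        experiment=build(ExperimentConfig, buckets["experiment"], "experiment"),
        forcing_overrides=buckets["forcing"],
    )
    try:
        cfg.forcing()
    except ValueError as exc:
        raise ConfigError(f"invalid forcing configuration: {exc}") from exc
    log.info("configuration loaded: %s", cfg.to_flat_dict())
    return cfg


def save_config(cfg: FullConfig, path) -> None:
    """Write the full (defaults-filled) flat config; load/save round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_flat_dict(), fh, sort_keys=True)


def config_template() -> str:
    """Commented template listing every key with its default and units."""
    cfg = FullConfig()
    lines = [
        "# sizebef configuration (flat key: value); all keys optional.",
        "# Units: rates d^-1; N pools mmol N m^-3; iron umol Fe m^-3;",
        "# sizes ln um^3; variance (ln um^3)^2; light W m^-2.",
    ]
    for k, v in sorted(cfg.to_flat_dict().items()):
        lines.append(f"{k}: {v}")
    return "\n".join(lines) + "\n"
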