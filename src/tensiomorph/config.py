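"""Run configuration: one YAML file per run, CLI flags override.

All pipeline defaults live here in one place.  The density difference
``delta_rho`` intentionally has no default: the tissue density is an
external physical input that must be supplied per experiment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .adsa import FitConfig
from .plate import PushbackConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A required parameter is missing or out of range."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    delta_rho: float | None = None  # kg/m^3; REQUIRED for any ADSA stage
    g: float = 9.80665
    pixel_scale: float | None = None  # m/pixel for image stages
    qc_circularity_min: float = 0.6
    qc_convexity_deficiency_max: float = 0.15
    fit: FitConfig = field(default_factory=FitConfig)
    pushback: PushbackConfig = field(default_factory=PushbackConfig)
    seed: int = 0
    output_dir: str = "tensiomorph_out"

    def require_delta_rho(self) -> float:
        if self.delta_rho is None:
            raise ConfigError(
                "delta_rho is required for ADSA stages and has no default; "
                "supply the tissue-medium density difference (kg/m^3)"
            )
        if not (self.delta_rho > 0):
            raise ConfigError(f"delta_rho must be > 0, got {self.delta_rho}")
        return self.delta_rho

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fit = FitConfig(**raw.pop("fit", {}))
    pb = PushbackConfig(**raw.pop("pushback", {}))
    return RunConfig(fit=fit, pushback=pb, **raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
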