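"""Run configuration (YAML) with strict validation.

Unknown keys are rejected so a typo in a config file fails loudly rather
than silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .errors import InvalidInputError


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: str = "mscCG"
    protocol: str = "triangle"
    peak: float = -100.0
    duration: float = 20.0
    sampling_hz: float = 5000.0
    lead: float = 0.5
    voltage: float = 30.0
    noise_sd: float = 0.5
    curvature_um: float = 0.9
    filter_hz: Optional[float] = 2000.0


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    unitary_hint: Optional[float] = None
    deadband: float = 0.15
    min_dwell: int = 2


class MechanicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fit_intercept: bool = True
    method: str = "inverse"


class MdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    exclude: int = 0
    fit_intercept: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    simulation: SimulationConfig = SimulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    mechanics: MechanicsConfig = MechanicsConfig()
    md: MdConfig = MdConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise InvalidInputError(f"config root must be a mapping, got {type(data)}")
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError
        raise InvalidInputError(f"invalid config {path}: {exc}") from exc
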