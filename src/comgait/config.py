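"""Run configuration: YAML-backed, schema-validated via pydantic."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    """Raised for configuration schema violations (CLI exit code 3)."""


class SlipOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    m: float = 72.0
    h: float = 1.69
    dimensionless_k: float = 9.0
    R: float = 0.3
    d: float = 0.05


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    accel_noise_sd: float = Field(0.03, ge=0)
    bias: float = 0.01
    bias_drift_rate: float = 0.005


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hs_cutoff_hz: float = Field(40.0, gt=0)
    to_cutoff_hz: float = Field(10.0, gt=0)
    apex_cutoff_hz: float = Field(10.0, gt=0)


class ResampleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    points: int = Field(200, ge=2)


class TrainingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float = Field(1e-3, gt=0)
    epochs: int = Field(300, ge=1)
    batch_size: int = Field(512, ge=1)
    hidden_dim: int = Field(20, ge=1)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = Field(7, ge=2)
    n_steps: int = Field(31, ge=3)
    subject_jitter: float = Field(0.10, ge=0, le=0.5)
    speed_jitter: float = Field(0.10, ge=0, le=0.5)
    segments_per_trial: int = Field(30, ge=1)
    noise: bool = False


class LooOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    train_speeds: list[str] | None = None
    drop_displacement_inputs: bool = False


class RunConfig(BaseModel):
    """Top-level configuration shared by all CLI stages."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    slip: SlipOverrides = SlipOverrides()
    noise: NoiseConfig = NoiseConfig()
    filter: FilterConfig = FilterConfig()
    resample: ResampleConfig = ResampleConfig()
    train: TrainingConfig = TrainingConfig()
    cohort: CohortConfig = CohortConfig()
    loo: LooOptions = LooOptions()
    speed: float = 1.42
    n_steps: int = 31

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
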