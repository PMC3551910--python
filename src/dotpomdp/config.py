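"""Structured run configuration: one documented schema for every numeric
default in the pipeline, loadable from YAML/JSON with full validation
(unknown keys rejected, errors reported with their key paths)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .belief import PriorParams
from .lip_model import LIPParams
from .observation import MTParams
from .policy import RewardParams

__all__ = ["RunConfig", "load_config"]

DEFAULT_COHERENCES = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)


class _MTConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    base_rate: float = Field(40.0, gt=0, description="spikes/s at zero coherence")
    drive_pref: float = Field(1.0, ge=0)
    drive_null: float = Field(0.5, ge=0, lt=1)
    spikes_per_step: int = Field(1, ge=1)


class _PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha0: float = Field(1.0, gt=0)
    beta0: float = Field(1.0, gt=0)


class _RewardConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_cost: float = Field(-1.0, lt=0, description="per MT spike observed")
    reward_correct: float = Field(450.0, gt=0)
    reward_error: float = Field(0.0, le=0)


class _LIPConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bound_rate: float = Field(60.0, gt=0)
    gain: float = Field(50.0, ge=0)
    floor: float = Field(0.0, ge=0)
    buildup_window: int = Field(20, ge=2)


class RunConfig(BaseModel):
    """Validated configuration for the solve/predict/simulate/lip pipeline."""

    model_config = ConfigDict(extra="forbid")

    mt: _MTConfig = _MTConfig()
    prior: _PriorConfig = _PriorConfig()
    rewards: _RewardConfig = _RewardConfig()
    lip: _LIPConfig = _LIPConfig()
    horizon: int = Field(400, ge=1)
    coherences: tuple[float, ...] = DEFAULT_COHERENCES
    base_seed: int = Field(0, ge=0)
    n_trials: int = Field(10000, ge=1)

    @model_validator(mode="after")
    def _check_ranges(self) -> "RunConfig":
        if any(not 0.0 <= c <= 1.0 for c in self.coherences):
            raise ValueError("coherences: every entry must lie in [0, 1]")
        return self

    # ---- converters to the domain parameter objects -----------------
    def mt_params(self) -> MTParams:
        return MTParams(**self.mt.model_dump())

    def prior_params(self) -> PriorParams:
        return PriorParams(**self.prior.model_dump())

    def reward_params(self) -> RewardParams:
        return RewardParams(**self.rewards.model_dump())

    def lip_params(self) -> LIPParams:
        return LIPParams(**self.lip.model_dump())

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the fully-resolved configuration."""
        payload = json.dumps(
            json.loads(self.model_dump_json()), sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML (or JSON) config file; ``None`` gives the
    documented defaults.  All validation errors are reported together with
    their key paths (pydantic)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    return RunConfig.model_validate(data)
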