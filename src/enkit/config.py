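"""YAML pipeline configuration with schema validation and defaults.

One file drives the whole pipeline (simulate → paired train → evaluate
→ Grad-CAM).  An empty file is valid and yields the fully defaulted
protocol (learning rate 0.001, patience 20, max 200 training epochs,
60/20/20 stratified split).  Validation collects *all* errors with
their field paths before reporting, rather than stopping at the first.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "ConfigValidationError", "validate_config"]


class ConfigValidationError(ConfigurationError):
    """Carries every schema violation found, each with its field path."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnKSettings(_Base):
    l: int = Field(1, ge=1)
    m: int = Field(7, ge=1)
    shared_affine: bool = True

    @field_validator("m")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("artifact kernel time width m must be odd")
        return v


class DatasetConfig(_Base):
    preset: Literal["p300_like", "conflict_like", "mi_like", "mrcp_like"] = "p300_like"
    n_epochs_per_class: int = Field(200, ge=2)
    n_channels: int = Field(8, ge=1)
    n_samples: int = Field(128, ge=1)


class ModelConfig(_Base):
    architecture: Literal["eegnet", "shallowconvnet", "deepconvnet", "rcnn"] = "eegnet"
    scale: float = Field(1.0, gt=0)
    enk: EnKSettings = Field(default_factory=EnKSettings)


class TrainSettings(_Base):
    max_epochs: int = Field(200, ge=1)
    batch_size: int = Field(16, ge=2, le=16)
    dropout: float = Field(0.25, ge=0.15, le=0.75)
    learning_rate: float = Field(0.001, gt=0)
    patience: int = Field(20, ge=1)
    split: tuple[float, float, float] = (0.60, 0.20, 0.20)

    @field_validator("split")
    @classmethod
    def _sums_to_one(cls, v: tuple[float, float, float]):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"split {list(v)} must sum to 1")
        if any(f <= 0 for f in v):
            raise ValueError(f"split fractions must be positive: {list(v)}")
        return v

    @pydantic.model_validator(mode="after")
    def _patience_lt_epochs(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        return self


class GradCamConfig(_Base):
    target_class: int = Field(1, ge=0)
    epoch_index: Optional[int] = None  # None = first test epoch of target class


class PipelineConfig(_Base):
    seed: int = Field(7, ge=0)
    out: str = "runs/run"
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainSettings = Field(default_factory=TrainSettings)
    gradcam: GradCamConfig = Field(default_factory=GradCamConfig)


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Parse and validate a YAML config file (or an explicit dict),
    filling defaults; raises :class:`ConfigValidationError` listing every
    violation with its field path."""
    if data is None:
        path = Path(path)
        if not path.exists():
            raise IOError(f"config file {path} does not exist")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as err:
            raise IOError(f"cannot parse {path}: {err}") from err
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigValidationError(
                [f"(root): expected a mapping, got {type(data).__name__}"])
    try:
        return PipelineConfig(**data)
    except pydantic.ValidationError as err:
        msgs = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"]) or "(root)"
            msgs.append(f"{loc}: {e['msg']}")
        raise ConfigValidationError(msgs) from err
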