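"""Run configuration: a single JSON file validated against a schema.

A flags-only CLI is hard to reproduce; the whole pipeline is driven by
one schema-validated JSON document (every field optional, defaults being
the reference study conditions), plus a ``--seed`` override.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .classify import ThresholdRule
from .synthetic import CohortParams, PhantomParams

__all__ = ["RunConfig", "RoiConfig", "load_config", "config_hash"]


class PhantomConfig(BaseModel):
    image_shape: tuple[int, int] = (128, 128)
    background_rate: float = 50.0
    bone_rate: float = 60.0
    cardiac_rate: float | None = None
    heart_center: tuple[float, float] = (50.0, 40.0)
    heart_radius: float = 12.0
    midline_col: float = 63.5

    def to_params(self) -> PhantomParams:
        return PhantomParams(**self.model_dump())


class CohortConfig(BaseModel):
    n_per_grade: tuple[int, int, int, int] = (77, 19, 7, 67)
    hcl_mean_per_grade: tuple[float, float, float, float] = (0.98, 1.32, 1.54, 2.40)
    hcl_sd_per_grade: tuple[float, float, float, float] = (0.11, 0.40, 0.35, 0.76)
    diagnosis_mix_per_grade: tuple[
        tuple[float, float, float], ...
    ] | None = None
    hcl_floor: float = 0.5

    def to_params(self) -> CohortParams:
        data = self.model_dump()
        if data["diagnosis_mix_per_grade"] is None:
            data.pop("diagnosis_mix_per_grade")
        return CohortParams(**data)


class RoiConfig(BaseModel):
    center_row: float = 50.0
    center_col: float = 40.0
    radius: float = 12.0
    midline_col: float = 63.5


class RuleConfig(BaseModel):
    name: str
    cutoff: float
    mode: str = "two_category"
    inconclusive_floor: float | None = None

    def to_rule(self) -> ThresholdRule:
        return ThresholdRule(
            cutoff=self.cutoff, mode=self.mode,
            inconclusive_floor=self.inconclusive_floor,
        )


def _default_rules() -> list[RuleConfig]:
    return [
        RuleConfig(name="cutoff_1.5", cutoff=1.5, mode="three_category",
                   inconclusive_floor=1.0),
        RuleConfig(name="cutoff_1.3", cutoff=1.3, mode="two_category"),
        RuleConfig(name="cutoff_1.3_band", cutoff=1.3, mode="three_category",
                   inconclusive_floor=1.0),
    ]


class EvaluationConfig(BaseModel):
    reference_specificity: float | None = None  # None: hold the 1.5-rule's value
    rounding: str = "integer"  # integer | one_decimal

    @field_validator("rounding")
    @classmethod
    def _check_rounding(cls, v: str) -> str:
        if v not in ("integer", "one_decimal"):
            raise ValueError("rounding must be integer or one_decimal")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    roi: RoiConfig = Field(default_factory=RoiConfig)
    rules: list[RuleConfig] = Field(default_factory=_default_rules)
    use_asnc: bool = True
    reclassification_variant: str = "nearest_mean"
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    output_dir: str = "hclquant_out"

    @field_validator("reclassification_variant")
    @classmethod
    def _check_variant(cls, v: str) -> str:
        if v not in ("nearest_mean", "standardized"):
            raise ValueError("variant must be nearest_mean or standardized")
        return v


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from JSON; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    return RunConfig.model_validate(json.loads(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
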