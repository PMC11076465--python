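"""Pipeline configuration (pydantic models, YAML loading)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class AdjustmentOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    covariates: tuple[str, ...] = ("age_decade", "sex", "education_band")
    rank_offset: float = 0.375  # Blom
    fit_population: str = "pooled"  # or "controls"


class ContrastOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_group: str = "control"
    anova_type: str = "II"


class FactorOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    extraction: str = "paf"
    rotation: str = "varimax"
    score_method: str = "regression"


class SelectionOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    disc_min: float = Field(0.5, ge=0)
    dev_max: float = Field(0.2, ge=0)
    discreteness_min: float = Field(0.1, ge=0)


class CvOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scheme: str = "kfold"
    folds: int = Field(25, ge=2)
    seed: int = 0


class PipelineConfig(BaseModel):
    """Everything `run_pipeline` needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohort_csv: str
    normative_csv: str
    catalog_csv: str | None = None  # packaged default when omitted
    output_dir: str = "cogbattery_out"
    seed: int = 0
    adjustment: AdjustmentOptions = AdjustmentOptions()
    contrasts: ContrastOptions = ContrastOptions()
    factors: FactorOptions = FactorOptions()
    selection: SelectionOptions = SelectionOptions()
    cv: CvOptions = CvOptions()
    benchmark_scales: tuple[str, ...] = ("moca", "mmse")

    @field_validator("adjustment")
    @classmethod
    def _check_fit_population(cls, v: AdjustmentOptions) -> AdjustmentOptions:
        if v.fit_population not in ("pooled", "controls"):
            raise ValueError("fit_population must be 'pooled' or 'controls'")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
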