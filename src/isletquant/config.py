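"""Run configuration: a validated schema for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "MorphometryParams",
    "PerifusionParams",
    "StatsParams",
    "SynthParams",
    "RunConfig",
    "load_config",
]


class MorphometryParams(BaseModel):
    threshold_method: Literal["auto", "manual"] = "auto"
    manual_threshold: Optional[float] = None
    n_erode: int = Field(2, ge=0)
    n_dilate: int = Field(2, ge=0)
    selem_radius: int = Field(1, ge=1)
    circ_min: float = Field(0.5, ge=0.0, le=1.0)
    circ_max: float = Field(1.0, ge=0.0, le=1.0)
    max_area_fraction: float = Field(0.18, gt=0.0, le=1.0)
    pixel_size_um: Optional[float] = Field(None, gt=0.0)

    @model_validator(mode="after")
    def _check(self):
        if self.threshold_method == "manual" and self.manual_threshold is None:
            raise ValueError("manual threshold method requires manual_threshold")
        if self.circ_min > self.circ_max:
            raise ValueError("circ_min must be <= circ_max")
        return self


class PerifusionParams(BaseModel):
    normalize_mode: Literal["fold_over_basal", "percent_total"] = "fold_over_basal"
    run_length_min: float = Field(70.0, ge=58.0)
    flow_rate_ul_min: float = Field(120.0, gt=0.0)


class StatsParams(BaseModel):
    alpha: float = Field(0.05, gt=0.0, lt=1.0)


class SynthParams(BaseModel):
    n_phantoms_per_group: int = Field(6, ge=2)
    n_donors_per_group: int = Field(9, ge=2)
    trace_noise_cv: float = Field(0.1, ge=0.0)
    phantom_noise_sd: float = Field(50.0, ge=0.0)
    n_debris: int = Field(4, ge=0)
    # field large enough that typical islets stay under the 18% area gate
    image_shape: Tuple[int, int, int] = (9, 768, 768)
    qpcr_n_samples: int = Field(6, ge=1)


class RunConfig(BaseModel):
    """Everything one pipeline run needs; validated before any stage runs."""

    seed: int = 0
    out_dir: Path = Path("isletquant_out")
    input_dir: Optional[Path] = None  # raw TIFFs/CSVs; None -> synthesize
    morphometry: MorphometryParams = Field(default_factory=MorphometryParams)
    perifusion: PerifusionParams = Field(default_factory=PerifusionParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    synth: SynthParams = Field(default_factory=SynthParams)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file (if given) and apply keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig.model_validate(data)
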