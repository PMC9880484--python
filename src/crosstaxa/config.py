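"""Run configuration: one YAML/JSON document with a section per stage.

Unknown keys are rejected so typos fail loudly; every tunable of the
simulator, metrics, prediction engine and moving-frame analysis is exposed
here with its default.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Section):
    n_plots: int = Field(135, ge=2)
    n_bact: int = Field(4986, ge=1)
    n_fungi: int = Field(5701, ge=1)
    n_plant: int = Field(99, ge=1)
    coupling: float = Field(1.0, ge=0)
    niche_width: float = Field(0.15, gt=0)
    depth_logmean: float = 9.2
    depth_logsd: float = Field(0.5, ge=0)
    env_noise_sd: float = Field(0.15, ge=0)
    nb_size: float = Field(5.0, gt=0)
    n_partners: int = Field(3, ge=1)
    plant_cover_noise_sd: float = Field(0.4, ge=0)
    n_missing_bacteria: int = Field(0, ge=0)
    n_missing_fungi: int = Field(0, ge=0)
    n_missing_plants: int = Field(0, ge=0)


class DataPaths(_Section):
    """Optional paths to existing tables; unset tables are simulated."""

    environment: str | None = None
    plants: str | None = None
    bacteria: str | None = None
    fungi: str | None = None
    traits: str | None = None
    tree: str | None = None
    bacteria_functions: str | None = None
    fungi_functions: str | None = None


class MetricsConfig(_Section):
    # a float in (0,1), or "adaptive" for the instability-criterion quantile
    css_quantile: float | str = 0.5
    rarefaction_repeats: int = Field(999, ge=1)
    fdis_correction: str = "sqrt"
    pd_include_root: bool = True

    @field_validator("fdis_correction")
    @classmethod
    def _check_correction(cls, v: str) -> str:
        if v not in {"sqrt", "cailliez", "none"}:
            raise ValueError("fdis_correction must be sqrt|cailliez|none")
        return v

    @field_validator("css_quantile")
    @classmethod
    def _check_quantile(cls, v):
        if isinstance(v, str):
            if v != "adaptive":
                raise ValueError('css_quantile must be in (0,1) or "adaptive"')
            return v
        if not 0 < v < 1:
            raise ValueError("css_quantile must lie in (0, 1)")
        return v


class PredictionConfig(_Section):
    repeats: int = Field(10, ge=1)
    train_frac: float = Field(0.8, gt=0, lt=1)
    n_trees: int = Field(500, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    strict_folds: bool = False


class FramesConfig(_Section):
    window: int = Field(45, ge=1)
    min_frame_plots: int = Field(10, ge=10)
    even_rule: str | None = None


class RunConfig(_Section):
    seed: int = 0
    output_dir: str = "results"
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    data: DataPaths = Field(default_factory=DataPaths)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    prediction: PredictionConfig = Field(default_factory=PredictionConfig)
    frames: FramesConfig = Field(default_factory=FramesConfig)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse ({exc})") from exc
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
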