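"""Schema-validated pipeline configuration (YAML-backed).

Every knob of the end-to-end workflow lives here: cohort simulation,
preprocessing, statistics and classification. Unknown keys are rejected and
a serialized copy of the validated config is stored beside every pipeline
output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .core import ConfigError, WavenumberAxis
from .synthgen import (
    BaselineParams,
    LayoutParams,
    PeakSpec,
    default_peak_library,
)

__all__ = [
    "AxisConfig",
    "LayoutConfig",
    "BaselineConfig",
    "PeakLibraryConfig",
    "CohortConfig",
    "PreprocessConfig",
    "StatsConfig",
    "ClassifyConfig",
    "PipelineConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AxisConfig(_Strict):
    start: float = 250.0
    stop: float = 1800.0
    step: float = 2.0

    def build(self) -> WavenumberAxis:
        return WavenumberAxis(self.start, self.stop, self.step)


class LayoutConfig(_Strict):
    nest_fraction: float = 0.20
    adipose_fraction: float = 0.15
    normal_fraction: float = 0.05
    stroma_fraction: float = 0.60

    def build(self) -> LayoutParams:
        return LayoutParams(
            nest_fraction=self.nest_fraction,
            adipose_fraction=self.adipose_fraction,
            normal_fraction=self.normal_fraction,
            stroma_fraction=self.stroma_fraction,
        )


class BaselineConfig(_Strict):
    poly_coeffs: tuple[float, float, float, float] = (120.0, -60.0, 90.0, -40.0)
    hump_amplitude: float = 150.0
    hump_center: float = 1100.0
    hump_width: float = 220.0
    patient_cv: float = 0.10
    pixel_cv: float = 0.05

    def build(self) -> BaselineParams:
        return BaselineParams(
            poly_coeffs=self.poly_coeffs,
            hump_amplitude=self.hump_amplitude,
            hump_center=self.hump_center,
            hump_width=self.hump_width,
            patient_cv=self.patient_cv,
            pixel_cv=self.pixel_cv,
        )


class PeakLibraryConfig(_Strict):
    """Parameters of the shipped differential marker-band library."""

    low: float = 100.0
    high: float = 150.0
    width: float = 4.0
    amplitude_cv: float = 0.12

    def build(self) -> list[PeakSpec]:
        return default_peak_library(
            low=self.low, high=self.high, width=self.width,
            amplitude_cv=self.amplitude_cv,
        )


class CohortConfig(_Strict):
    """Synthetic cohort: sizes mirror the study (14 DCIS vs 32 invasive)."""

    seed: int
    n_dcis: int = 14
    n_ibc: int = 32
    image_shape: tuple[int, int] = (16, 16)
    axis: AxisConfig = Field(default_factory=AxisConfig)
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    baseline: BaselineConfig = Field(default_factory=BaselineConfig)
    peaks: PeakLibraryConfig = Field(default_factory=PeakLibraryConfig)
    noise_sd: float = 10.0
    hotspot_cv: float = 0.25
    calibration_shift: float = 0.0

    def model_post_init(self, __context) -> None:
        if self.n_dcis < 1 or self.n_ibc < 1:
            raise ValueError("cohort needs at least one patient per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class PreprocessConfig(_Strict):
    bin_factor: int = 4
    baseline_lam: float = 30.0
    baseline_method: str = "asls"
    baseline_clip_k: float = 2.0
    baseline_p: float = 1e-4
    baseline_max_iter: int = 50
    baseline_tol: float = 1e-6
    imaging_halfwidth: float = 5.0
    feature_halfwidth: float = 10.0


class StatsConfig(_Strict):
    alpha: float = 0.05
    annotation_filter: str = "stroma"
    correction: Optional[str] = None
    merge_distance: float = 20.0
    peak_separation: float = 10.0
    min_channels: int = 3
    min_effect: float = 1.5


class ClassifyConfig(_Strict):
    algorithms: list[str] = Field(
        default_factory=lambda: ["l1", "svm", "rf", "xgb", "knn", "nb"]
    )
    n_sets: int = 4
    k_folds: int = 3
    wavenumbers: Optional[list[float]] = None  # default: the 27 marker bands
    feature_halfwidth: float = 10.0
    importance_repeats: int = 5


class PipelineConfig(_Strict):
    cohort: CohortConfig
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    outdir: str = "scratch/run"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return PipelineConfig.from_dict(data)
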