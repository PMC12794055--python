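"""Tunable pipeline parameters and their serialization.

Every threshold, size filter and scale used anywhere in the pipeline lives
in :class:`AssayConfig` so a full run is reproducible from (config, seed)
alone.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """A parameter is outside its documented range."""


@dataclass
class NoiseModel:
    """Additive Gaussian read noise plus intensity-scaled Poisson shot noise.

    ``gaussian_sd`` is on the normalized [0, 1] intensity scale.
    ``poisson_scaling`` is the normalized intensity corresponding to one
    photoelectron; 0 disables the Poisson term.
    """

    gaussian_sd: float = 0.01
    poisson_scaling: float = 0.002

    def validate(self) -> None:
        if self.gaussian_sd < 0:
            raise ConfigError("gaussian_sd must be >= 0")
        if self.poisson_scaling < 0:
            raise ConfigError("poisson_scaling must be >= 0")


@dataclass
class SynthParams:
    """Parameters of the synthetic two-channel cardiac-culture field.

    Defaults emulate the assay's mixed neonatal culture: ~44% of cells are
    cardiomyocytes (CMs, alpha-actinin positive, mono- or binucleated), the
    rest are alpha-actinin-negative cells visible only through their nuclei.
    Hypertrophy is simulated multiplicatively through ``effect_area``
    (CM body area), ``effect_nuc_area`` (CM nuclear area) and
    ``effect_intensity`` (alpha-actinin amplitude); 1.0 everywhere means
    vehicle-control conditions.
    """

    field_shape: tuple[int, int] = (256, 256)
    cells_per_field: int = 50
    cm_fraction: float = 0.44
    binucleated_cm_fraction: float = 0.30

    # Object geometry (px^2 areas, drawn from truncated normals).
    cm_area_px_mean: float = 450.0
    cm_area_px_sd: float = 90.0
    noncm_nucleus_area_px_mean: float = 80.0
    noncm_nucleus_area_px_sd: float = 16.0
    cm_nucleus_area_px_mean: float = 110.0
    cm_nucleus_area_px_sd: float = 22.0
    cm_aspect_max: float = 2.0
    binucleate_min_sep_px: float = 9.0

    # Intensities on the normalized [0, 1] scale.
    actinin_intensity_mean: float = 0.35
    actinin_intensity_sd: float = 0.05
    dapi_intensity_mean: float = 0.55
    dapi_intensity_sd: float = 0.08
    dapi_background: float = 0.03
    actinin_background: float = 0.04
    striation_period_px: float = 6.0
    striation_depth: float = 0.2

    # Hypertrophy effect multipliers (1.0 = vehicle).
    effect_area: float = 1.0
    effect_nuc_area: float = 1.0
    effect_intensity: float = 1.0

    illumination_gradient_amplitude: float = 0.15
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.cm_fraction <= 1.0):
            raise ConfigError("cm_fraction must be in [0, 1]")
        if not (0.0 <= self.binucleated_cm_fraction <= 1.0):
            raise ConfigError("binucleated_cm_fraction must be in [0, 1]")
        if self.cells_per_field < 0:
            raise ConfigError("cells_per_field must be >= 0")
        for name in (
            "cm_area_px_mean",
            "noncm_nucleus_area_px_mean",
            "cm_nucleus_area_px_mean",
            "actinin_intensity_mean",
            "striation_period_px",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("effect_area", "effect_nuc_area", "effect_intensity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0.0 <= self.illumination_gradient_amplitude < 1.0):
            raise ConfigError("illumination_gradient_amplitude must be in [0, 1)")
        self.noise_model.validate()

    def with_effects(
        self, area: float, nuc_area: float, intensity: float
    ) -> "SynthParams":
        return dataclasses.replace(
            self,
            effect_area=area,
            effect_nuc_area=nuc_area,
            effect_intensity=intensity,
        )


@dataclass
class AssayConfig:
    """All tunable analysis-pipeline parameters.

    The segmentation section mirrors the stages of the pipeline:
    illumination correction of the alpha-actinin channel, nucleus
    segmentation on DAPI, nucleus classification by alpha-actinin
    colocalization, and seeded-watershed CM segmentation with the
    merged-basin rule that keeps binucleated CMs as single cells.
    """

    pixel_size_um: float = 0.65
    fields_per_well: int = 4
    seed: int = 0

    # Illumination correction.
    surface_order: int = 2
    robust_fraction: float = 0.1
    illum_grid_blocks: int = 8

    # Nucleus segmentation.
    nucleus_threshold_method: str = "otsu"  # otsu | percentile | fixed
    nucleus_threshold_value: float = 0.5  # percentile (0-100) or fixed level
    nucleus_min_area_px: int = 30
    nucleus_smooth_sigma: float = 1.0
    declump: bool = True
    declump_min_distance_px: int = 5

    # CM segmentation / classification.
    actinin_threshold_method: str = "otsu"
    actinin_threshold_value: float = 0.5
    cell_min_area_px: int = 200
    overlap_fraction: float = 0.5
    ridge_fraction: float = 0.6

    # Texture.
    texture_offsets_px: tuple[int, ...] = (1, 4)
    texture_gray_levels: int = 8
    texture_min_area_px: int = 25

    # Scoring.
    toxicity_threshold_fraction: float = 0.7

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.fields_per_well < 1:
            raise ConfigError("fields_per_well must be >= 1")
        if self.surface_order < 0 or self.surface_order > 4:
            raise ConfigError("surface_order must be in [0, 4]")
        if not (0.0 < self.robust_fraction <= 1.0):
            raise ConfigError("robust_fraction must be in (0, 1]")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ConfigError("overlap_fraction must be in (0, 1]")
        if not (0.0 < self.ridge_fraction <= 1.0):
            raise ConfigError("ridge_fraction must be in (0, 1]")
        if not (0.0 < self.toxicity_threshold_fraction <= 1.0):
            raise ConfigError("toxicity_threshold_fraction must be in (0, 1]")
        if self.nucleus_min_area_px < 0 or self.cell_min_area_px < 0:
            raise ConfigError("minimum areas must be >= 0")
        for m in (self.nucleus_threshold_method, self.actinin_threshold_method):
            if m not in ("otsu", "percentile", "fixed"):
                raise ConfigError(f"unknown threshold method {m!r}")
        if self.texture_gray_levels < 2:
            raise ConfigError("texture_gray_levels must be >= 2")
        if any(o < 1 for o in self.texture_offsets_px):
            raise ConfigError("texture offsets must be >= 1")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def _coerce(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "noise_model" and isinstance(v, dict):
            v = NoiseModel(**v)
        elif f.name in ("field_shape", "texture_offsets_px") and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cls(**kwargs)


def to_yaml(obj: AssayConfig | SynthParams, path: str | Path | None = None) -> str:
    """Serialize a config dataclass to YAML; optionally write it to *path*."""
    text = yaml.safe_dump(_to_plain(obj), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def assay_config_from_yaml(source: str | Path) -> AssayConfig:
    cfg = _coerce(AssayConfig, _load_yaml(source))
    cfg.validate()
    return cfg


def synth_params_from_yaml(source: str | Path) -> SynthParams:
    params = _coerce(SynthParams, _load_yaml(source))
    params.validate()
    return params


def _load_yaml(source: str | Path) -> dict[str, Any]:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config YAML must map parameter names to values")
    return data
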