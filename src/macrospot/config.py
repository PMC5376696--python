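"""Pipeline configuration: validated parameter blocks and a flat
``section.key = value`` config-file format."""

from __future__ import annotations

from pathlib import Path
from typing import Any

from pydantic import BaseModel, Field, model_validator

from .errors import FormatError


class GeometryConfig(BaseModel):
    block_pitch: float = Field(36.0, gt=0)
    spot_pitch: float = Field(12.0, gt=0)
    spot_radius: float = Field(4.0, gt=0)
    guide_dot_radius: float = Field(6.0, gt=0)
    margin: float = Field(24.0, gt=0)

    @model_validator(mode="after")
    def _no_overlap(self) -> "GeometryConfig":
        if self.spot_radius >= self.spot_pitch / 2:
            raise ValueError("spot_radius must be < spot_pitch/2")
        return self


class RegistrationConfig(BaseModel):
    threshold_k: float = Field(5.0, gt=0)
    area_low: float = Field(0.5, gt=0)
    area_high: float = Field(2.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "RegistrationConfig":
        if self.area_high <= self.area_low:
            raise ValueError("area_high must exceed area_low")
        return self


class QuantificationConfig(BaseModel):
    annulus_inner_pad: float = Field(2.0, ge=0)
    annulus_outer_pad: float = Field(6.0, gt=0)
    spread_floor: float = Field(1e-6, gt=0)
    saturation_fraction: float = Field(0.10, gt=0, le=1)
    min_annulus_pixels: int = Field(20, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "QuantificationConfig":
        if self.annulus_outer_pad <= self.annulus_inner_pad:
            raise ValueError("annulus_outer_pad must exceed annulus_inner_pad")
        return self


class CallingConfig(BaseModel):
    z_min: float = Field(3.0, gt=0)
    require_duplicate: bool = True


class IOConfig(BaseModel):
    seed: int = 0


class PipelineConfig(BaseModel):
    """All tunables of the scan-to-hit-list pipeline, grouped by stage."""

    geometry: GeometryConfig = GeometryConfig()
    registration: RegistrationConfig = RegistrationConfig()
    quantification: QuantificationConfig = QuantificationConfig()
    calling: CallingConfig = CallingConfig()
    io: IOConfig = IOConfig()


def _parse_scalar(text: str) -> Any:
    text = text.strip()
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key=value config; keys are ``section.field``, ``#`` starts
    a comment, unknown keys are an error."""
    nested: dict[str, dict[str, Any]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'section.key = value'")
        key, value = line.split("=", 1)
        key = key.strip()
        if "." not in key:
            raise FormatError(f"{path}:{lineno}: key {key!r} lacks a section")
        section, field_name = key.split(".", 1)
        nested.setdefault(section, {})[field_name] = _parse_scalar(value)
    try:
        return PipelineConfig.model_validate(nested)
    except Exception as exc:  # pydantic ValidationError
        raise FormatError(f"invalid config {path}: {exc}") from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for section, block in config.model_dump().items():
        for field_name, value in block.items():
            lines.append(f"{section}.{field_name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
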