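"""Pipeline configuration (shared by the JSON config file and CLI flags)."""

from __future__ import annotations

import json
import os
from typing import List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config"]

_MODES = (
    "simulate-ftir",
    "simulate-2dir",
    "analyze-ftir",
    "analyze-2dir",
    "order-parameter",
    "depth",
)


class ProbeBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    base_frequency: float = 2096.0
    dark_state_offset: float = 40.0
    theta_slope: float = 5.0
    bright_slope: float = 2.0
    fermi_coupling: float = 30.0
    theta_equilibrium: float = 116.0
    theta_kt_span: float = 11.0
    restriction: float = 1.0
    homogeneous_fwhm: float = 8.0


class TemperatureSeriesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    transition_temperature: float = 41.0
    transition_width: float = 1.0
    width_below: float = 14.0
    width_above: float = 28.0
    homogeneous_ref_fwhm: float = 8.0
    reference_temperature: float = 25.0
    temperatures: List[float] = Field(
        default_factory=lambda: [float(t) for t in range(22, 46)]
    )
    noise_sd: float = 0.0


class FFCFBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    components: List[Tuple[float, float]] = Field(default_factory=list)
    static_amplitude: float = 0.0
    pure_dephasing_time: float = 2.0
    lifetime: float = 3.0
    center: float = 2096.0
    anharmonicity: float = 25.0
    waiting_times: List[float] = Field(
        default_factory=lambda: [0.2, 0.5, 1.0, 2.0, 4.0, 7.5, 12.0, 18.0, 25.0]
    )
    kind: str = "absorptive"


class OrderParameterBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width_max: float = 31.0
    width_min: float = 14.0


class DepthBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cc_bond_length: float = 1.54
    ccc_angle: float = 113.3
    anchor_depth: Optional[float] = None
    n_ref: int = 1
    chain_lengths: List[int] = Field(default_factory=lambda: [6, 8, 11, 13, 15])
    coordinates_path: Optional[str] = None
    midplane_z: float = 0.0


class PipelineConfig(BaseModel):
    """Validated configuration for :func:`azospec.cli.run_pipeline`.

    Construction raises :class:`ConfigError` listing every violation.
    """

    model_config = ConfigDict(extra="forbid")

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from None

    mode: str
    inputs: List[str] = Field(default_factory=list)
    manifest: Optional[str] = None
    out_dir: str = "."
    seed: Optional[int] = None
    verbosity: int = 1
    band_window: Tuple[float, float] = (2060.0, 2135.0)
    poly_order: int = 1
    smooth_window: int = 5
    probe: ProbeBlock = Field(default_factory=ProbeBlock)
    temperature_series: TemperatureSeriesBlock = Field(
        default_factory=TemperatureSeriesBlock
    )
    ffcf: FFCFBlock = Field(default_factory=FFCFBlock)
    order_parameter: OrderParameterBlock = Field(default_factory=OrderParameterBlock)
    depth: DepthBlock = Field(default_factory=DepthBlock)

    @model_validator(mode="after")
    def _check(self):
        problems = []
        if self.mode not in _MODES:
            problems.append(f"unknown mode {self.mode!r}; choose one of {_MODES}")
        if self.mode == "simulate-ftir" and self.temperature_series.noise_sd > 0 and (
            self.seed is None
        ):
            problems.append("seed is mandatory when noise_sd > 0")
        if self.mode in ("analyze-ftir",):
            if not self.inputs:
                problems.append("analyze-ftir requires input spectrum files")
            problems.extend(
                f"input path does not exist: {p}" for p in self.inputs
                if not os.path.exists(p)
            )
        if self.mode == "analyze-2dir":
            if self.manifest is None:
                problems.append("analyze-2dir requires a manifest path")
            elif not os.path.exists(self.manifest):
                problems.append(f"manifest does not exist: {self.manifest}")
        if problems:
            raise ConfigError("; ".join(problems))
        return self


def load_config(path, **overrides) -> PipelineConfig:
    """Read a JSON config; keyword overrides (CLI flags) win over the file."""
    with open(path) as fh:
        data = json.load(fh)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from None
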