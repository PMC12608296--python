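"""Validated run configuration (YAML-backed).

One :class:`RunConfig` gathers calibration, thresholds, weights and the
backend selection, with the domain defaults filled in: urgency weights
gamma = (0.2, 0.2, 0.25, 0.35), delay weights alpha = (0.5, 0.25, 0.25),
reach window 1 s. Weight vectors must lie on the simplex; violations
raise a descriptive validation error naming the field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .anomaly import DetectionConfig
from .motion import CalibrationSpec
from .triage import DelayWeights, TriageParams

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def _check_simplex(name: str, values: tuple[float, ...]) -> tuple[float, ...]:
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ValueError(f"{name} components must lie in [0, 1], got {values}")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {sum(values)!r}")
    return values


class CalibrationSection(BaseModel):
    frame_rate: float = Field(5.0, gt=0, description="frames per second")
    scale: float = Field(0.01, gt=0, description="metres per pixel")


class ThresholdSection(BaseModel):
    theta_u: float = Field(0.2, ge=0, le=1)
    reach_window: float = Field(1.0, gt=0, description="Delta-t of the reach rule, seconds")
    stand_up_time: float = Field(3.0, gt=0)
    nurse_speed: float = Field(1.2, ge=0, description="nominal walking speed, m/s")
    t_ack: float = Field(30.0, gt=0, description="acknowledgment horizon, seconds")
    delay_scale: float = Field(10.0, ge=0, description="seconds per unit of normalised delay")
    tau_mode: Literal["mad", "absolute"] = "mad"
    k: float = Field(3.0, gt=0, description="MAD multiplier for tau_A")
    tau_abs: float = Field(5.0, gt=0)
    window_length: int = Field(25, ge=2)
    horizon: int | None = None


class WeightSection(BaseModel):
    gamma: tuple[float, float, float, float] = (0.2, 0.2, 0.25, 0.35)
    alpha: tuple[float, float, float] = (0.5, 0.25, 0.25)
    surrogate: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    tau: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.2)

    @field_validator("gamma")
    @classmethod
    def _gamma_simplex(cls, v):
        return _check_simplex("urgency weights gamma", v)

    @field_validator("alpha")
    @classmethod
    def _alpha_simplex(cls, v):
        return _check_simplex("delay weights alpha", v)


class RunConfig(BaseModel):
    calibration: CalibrationSection = Field(default_factory=CalibrationSection)
    thresholds: ThresholdSection = Field(default_factory=ThresholdSection)
    weights: WeightSection = Field(default_factory=WeightSection)
    backend: Literal["surrogate", "llm"] = "surrogate"
    llm: dict = Field(default_factory=dict, description="model/endpoint when backend=llm")
    scenario: dict = Field(default_factory=dict, description="ward simulator overrides")
    seed: int = 0
    strategy: Literal["baseline", "rsd", "rsdv", "proposed"] = "proposed"
    stream: str | None = None
    residents: str | None = None
    nurses: str | None = None

    @model_validator(mode="after")
    def _paths_exist(self):
        for name in ("stream", "residents", "nurses"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")
        return self

    # -- adapters into the library's dataclasses ---------------------------

    def triage_params(self) -> TriageParams:
        t, w = self.thresholds, self.weights
        return TriageParams(
            theta_u=t.theta_u,
            reach_window=t.reach_window,
            stand_up_time=t.stand_up_time,
            nurse_speed=t.nurse_speed,
            t_ack=t.t_ack,
            delay_scale=t.delay_scale,
            delay_weights=DelayWeights(*w.alpha),
            surrogate_weights=w.surrogate,
            tau_params=w.tau,
        )

    def detection_config(self) -> DetectionConfig:
        t = self.thresholds
        return DetectionConfig(
            window_length=t.window_length,
            horizon=t.horizon,
            tau_mode=t.tau_mode,
            k=t.k,
            tau_abs=t.tau_abs,
        )

    def calibration_spec(self) -> CalibrationSpec:
        return CalibrationSpec(
            frame_rate=self.calibration.frame_rate, scale=self.calibration.scale
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty or absent file means
    all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
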