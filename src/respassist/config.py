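"""Run-configuration schema (YAML or JSON) with validated bounds.

The schema mirrors the domain objects; every gain carries the published
range as a hard bound, so a config violating them fails before any
simulation starts, with the offending field path in the error.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .cohort import (
    ParameterRanges,
    VirtualSubject,
    sample_cohort,
    subject_from_table,
)
from .controller import ControllerConfig
from .lung import BreathPattern, LungParams
from .pneumatics import PneumaticParams
from .transmission import TransmissionModel

__all__ = ["RunConfig", "load_config"]


class SubjectSpec(BaseModel):
    kind: Literal["sampled", "table", "explicit"] = "sampled"
    count: int = Field(1, ge=1, description="cohort size (sampled kind)")
    table_id: Optional[str] = None
    # explicit parameters
    alpha_t: Optional[float] = Field(None, gt=0)
    mu: Optional[float] = Field(None, ge=0)
    delta: float = Field(0.05, gt=0)
    delta_unit: Literal["cmH2O/N", "kPa/N"] = "cmH2O/N"
    R: float = Field(2.7, ge=1.5, le=5.0)
    E: float = Field(4.8, ge=2.0, le=10.0)
    Q0: float = Field(0.4, gt=0)
    flow_noise_sd: float = Field(0.01, ge=0)
    fint_noise_sd: float = Field(1.0, ge=0)
    pmus_jitter_cv: float = Field(0.05, ge=0)

    @model_validator(mode="after")
    def _check_kind(self):
        if self.kind == "table" and self.table_id is None:
            raise ValueError("subject.kind='table' requires subject.table_id")
        if self.kind == "explicit" and (self.alpha_t is None or self.mu is None):
            raise ValueError("subject.kind='explicit' requires alpha_t and mu")
        return self

    def build(self, seed: int) -> list[VirtualSubject]:
        noise = dict(
            flow_noise_sd=self.flow_noise_sd,
            fint_noise_sd=self.fint_noise_sd,
            pmus_jitter_cv=self.pmus_jitter_cv,
        )
        if self.kind == "sampled":
            return sample_cohort(
                self.count, seed, delta_unit=self.delta_unit, **noise
            )
        if self.kind == "table":
            return [
                subject_from_table(
                    self.table_id,
                    delta=self.delta,
                    delta_unit=self.delta_unit,
                    breath=BreathPattern(Q0=self.Q0, rate=12.0),
                    **noise,
                )
            ]
        tm = TransmissionModel(
            alpha_t=self.alpha_t, mu=self.mu, delta=self.delta, delta_unit=self.delta_unit
        )
        return [
            VirtualSubject(
                id="explicit",
                tm=tm,
                lung=LungParams(R=self.R, E=self.E),
                breath=BreathPattern(Q0=self.Q0, rate=12.0),
                **noise,
            )
        ]


class ControllerSpec(BaseModel):
    assist_gain: float = Field(1.0, ge=0.0, le=1.0)
    B: float = Field(0.5, ge=0.1, le=10.0)
    K: float = Field(0.5, ge=0.1, le=5.0)
    kP: float = Field(2.6, gt=1.0, le=10.0)
    kD: float = Field(0.5, gt=0.0, le=1.0)
    Fmax: float = Field(400.0, gt=0.0, le=400.0)
    Psup_max: float = Field(20.0, gt=0.0, le=20.0)
    Pairway_max: float = Field(30.0, gt=0.0)

    def build(self) -> ControllerConfig:
        return ControllerConfig(**self.model_dump())


class PneumaticSpec(BaseModel):
    Pin: float = Field(16.0, gt=0.0, le=20.0)
    k1: float = Field(1.0, gt=0.0)
    Cf: float = Field(1.0, gt=0.0)
    Cv: Optional[float] = Field(None, gt=0.0)
    tau_fill: float = Field(0.030, gt=0.0)
    delay: float = Field(0.200, ge=0.0)

    def build(self) -> PneumaticParams:
        return PneumaticParams(**self.model_dump())


class SessionSpecModel(BaseModel):
    mode: Literal["natural", "assisted"] = "assisted"
    rate: float = Field(12.0, ge=1.0, le=80.0)
    duration: float = Field(180.0, gt=0.0)


class RunConfig(BaseModel):
    seed: int = 0
    subject: SubjectSpec = SubjectSpec()
    controller: ControllerSpec = ControllerSpec()
    pneumatics: PneumaticSpec = PneumaticSpec()
    sessions: list[SessionSpecModel] = [SessionSpecModel()]
    rates: list[float] = [12.0, 20.0, 30.0, 40.0]
    reps: int = Field(3, ge=1)
    duration: float = Field(180.0, gt=0.0)
    output_dir: str = "runs"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.model_validate(data)
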