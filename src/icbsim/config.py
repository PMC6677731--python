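"""Configuration loading, validation and run manifests.

YAML in, validated objects out.  Unknown keys are rejected, every value is
range-checked against the documented bounds, defaults are filled in, and
the fully resolved configuration is echoed back to a file so a run can be
reproduced bit-for-bit.  Every run directory receives a manifest with the
configuration hash, the seed and the package/library versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .engine import SolverSettings
from .params import ModelParams, PatientParameters
from .pbpk import Regimen, expand_schedule

__all__ = [
    "PatientConfig",
    "DoseConfig",
    "RegimenConfig",
    "SolverConfig",
    "RunConfig",
    "load_config",
    "load_regimen",
    "write_resolved_config",
    "write_manifest",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PatientConfig(_Strict):
    tumor_diameter_start: float = Field(47.5, ge=15.0, le=80.0,
                                        description="mm, longest diameter")
    antigen_strength: float = Field(0.9, ge=0.8, le=1.0)
    t_clonality: float = Field(70.0, ge=10.0, le=130.0)
    treg_ln_frac: float = Field(0.20, ge=0.05, le=0.35)
    treg_tumor_frac: float = Field(0.00125, ge=0.0, le=0.0025)
    mdsc_multiplier: float = Field(3.0, ge=2.0, le=4.0)
    pdl1_frac: float = Field(0.65, ge=0.40, le=0.90)
    antigen_per_cell: float = Field(100.0, gt=0)
    chemokine_factor: float = Field(200.0, ge=50.0, le=500.0)
    body_weight: float = Field(75.0, gt=0)

    def to_patient(self) -> PatientParameters:
        return PatientParameters(**self.model_dump())


class DoseConfig(_Strict):
    drug: str
    dose: float = Field(ge=0.0, description="mg per kg body weight")
    interval_days: float = Field(14.0, gt=0)
    n_doses: int = Field(1, ge=0)
    start_day: float = 0.0
    infusion_hours: float = Field(1.0, gt=0)

    @field_validator("drug")
    @classmethod
    def _known_drug(cls, v: str) -> str:
        if v not in ("antiPD1", "antiPDL1", "antiCTLA4"):
            raise ValueError(f"unknown drug {v!r}")
        return v


class RegimenConfig(_Strict):
    label: str = ""
    blocks: list[DoseConfig]

    def to_regimen(self) -> Regimen:
        events = []
        for b in self.blocks:
            events.extend(
                expand_schedule(b.drug, b.dose, b.interval_days, b.n_doses,
                                b.start_day, b.infusion_hours).events
            )
        return Regimen(events=events, label=self.label)


class SolverConfig(_Strict):
    abs_tol: float = Field(1e-9, gt=0)
    rel_tol: float = Field(1e-8, gt=0)
    method: str = "BDF"
    max_step: float = Field(7.0, gt=0)

    def to_settings(self) -> SolverSettings:
        return SolverSettings(**self.model_dump())


class RunConfig(_Strict):
    patient: PatientConfig = Field(default_factory=PatientConfig)
    regimen: RegimenConfig | None = None
    solver: SolverConfig = Field(default_factory=SolverConfig)
    horizon: float = Field(365.0, gt=0)
    seed: int | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def to_model_params(self) -> ModelParams:
        return ModelParams(patient=self.patient.to_patient())


def _read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def load_config(
    patient_path: str | Path | None = None,
    regimen_path: str | Path | None = None,
    **overrides,
) -> RunConfig:
    """Build a fully validated run configuration from YAML files.

    Out-of-range values raise a validation error citing the documented
    range; unknown keys are rejected.
    """
    data: dict = {}
    if patient_path is not None:
        data["patient"] = _read_yaml(patient_path)
    if regimen_path is not None:
        data["regimen"] = _read_yaml(regimen_path)
    data.update(overrides)
    return RunConfig(**data)


def load_regimen(path: str | Path) -> Regimen:
    return RegimenConfig(**_read_yaml(path)).to_regimen()


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_resolved_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the defaults-filled configuration; reloading it reproduces the
    identical object."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


def write_manifest(cfg: RunConfig, path: str | Path) -> dict:
    import numpy
    import scipy

    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "icbsim": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
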