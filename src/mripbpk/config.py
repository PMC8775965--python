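"""Run configuration: schema-validated structured-text (YAML) config,
manifest writing and config hashing for reproducible pipeline runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .covariate import CovariateModel, FitSettings
from .dce import AcquisitionProtocol
from .pbpk import PlasmaPKParams, TumorPBPKParams
from .synthetic import GroupPhenotype, NoiseModel, default_groups

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "write_manifest"]


class ProtocolConfig(BaseModel):
    frame_interval_s: float = 17.0
    n_frames: int = Field(default=70, ge=3)
    injection_time_min: float = 2.0
    tr_ms: float = 10.0
    flip_angle_deg: float = Field(default=20.0, gt=0.0, lt=90.0)
    r1_relaxivity: float = Field(default=3.3, gt=0.0)
    sr_recovery_times_ms: list[float] = [200.0, 400.0, 800.0, 1500.0, 3000.0, 5000.0]

    def build(self) -> AcquisitionProtocol:
        d = self.model_dump()
        d["sr_recovery_times_ms"] = tuple(d["sr_recovery_times_ms"])
        return AcquisitionProtocol(**d)


class GroupConfig(BaseModel):
    name: str
    n_subjects: int = Field(ge=1)
    ktrans_logmean: float
    ktrans_logsd: float = Field(ge=0.0)
    vp_mean: float
    vp_sd: float = Field(ge=0.0)
    egfr_conc: float = Field(default=0.0, ge=0.0)
    vp_zero_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    t10_mean_ms: float = 2000.0
    t10_sd_ms: float = 150.0

    def build(self) -> GroupPhenotype:
        return GroupPhenotype(**self.model_dump())


class NoiseConfig(BaseModel):
    dce_signal_cv: float = Field(default=0.05, ge=0.0)
    obs_cv: float = Field(default=0.20, ge=0.0)
    aif_variability: float = Field(default=0.10, ge=0.0)

    def build(self) -> NoiseModel:
        return NoiseModel(**self.model_dump())


class TumorParamsConfig(BaseModel):
    """Table of tumor PBPK parameters; defaults are the tabulated base values."""

    model_config = {"extra": "forbid"}

    q_tu: float = 1e-4
    l_tu: float = 4e-6
    clup_tu: float = 8.18e-9
    sigma_v: float = Field(default=0.734, ge=0.0, le=1.0)
    sigma_l: float = Field(default=0.2, ge=0.0, le=1.0)
    cl_tu: float = 8.96e-9
    kd_fcrn: float = 7.5e-7
    c_fcrn: float = 1.64e-5
    fr: float = Field(default=0.715, ge=0.0, le=1.0)
    kgrowth: float = 8.08e-5
    vi_tu: float = 1.38e-4
    ve_tu: float = 1.25e-6
    vv_tu: float = 1.75e-5
    kd_egfr: float = 1.5e-10
    kint: float = 1.38e-3
    c_egfr: float = 0.0

    def build(self) -> TumorPBPKParams:
        return TumorPBPKParams(**self.model_dump())


class PlasmaConfig(BaseModel):
    dose_mg_per_kg: float = Field(default=1.0, gt=0.0)
    bodyweight_kg: float = 0.025
    molecular_weight: float = 1.5e5
    coef_a: float = 333.3
    rate_alpha: float = 0.0011552453009332421
    coef_b: float = 500.0
    rate_beta: float = 8.022536811897515e-05

    def build(self) -> PlasmaPKParams:
        return PlasmaPKParams(**self.model_dump())


class TruthConfig(BaseModel):
    structure: Literal["base", "population", "ktrans", "vp", "ktrans+vp"] = "ktrans"
    theta_q: list[float] = [0.02]
    theta_sigma: list[float] = [50.0]

    def build(self) -> CovariateModel:
        return CovariateModel(structure=self.structure,
                              theta_q=tuple(self.theta_q),
                              theta_sigma=tuple(self.theta_sigma))


class FitConfig(BaseModel):
    sim_rtol: float = 1e-6
    xatol: float = 1e-5
    fatol: float = 1e-9
    maxfev: int = 400
    n_grid: int = 5
    n_starts: int = 2
    grid_span: float = 30.0

    def build(self, seed: int = 0) -> FitSettings:
        return FitSettings(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Everything a pipeline run needs; YAML-serialisable and hashable."""

    seed: int = 0
    output_dir: str = "runs/default"
    protocol: ProtocolConfig = ProtocolConfig()
    groups_nonbinding: list[GroupConfig] | None = None
    groups_binding: list[GroupConfig] | None = None
    noise: NoiseConfig = NoiseConfig()
    tumor: TumorParamsConfig = TumorParamsConfig()
    plasma: PlasmaConfig = PlasmaConfig()
    truth: TruthConfig = TruthConfig()
    structures: list[Literal["base", "population", "ktrans", "vp", "ktrans+vp"]] = [
        "base", "population", "ktrans",
    ]
    fit: FitConfig = FitConfig()
    use_fitted_mri_params: bool = True   # fit DCE curves; False = use true values

    @field_validator("structures")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("at least one candidate structure is required")
        return v

    def groups(self, antibody: str) -> list[GroupPhenotype]:
        cfgs = (self.groups_nonbinding if antibody == "non-binding"
                else self.groups_binding)
        if cfgs is None:
            return default_groups(antibody)
        return [g.build() for g in cfgs]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, outdir: Path, stages: list[str]) -> Path:
    """Record config hash, seed and software version so any numeric output is
    traceable and re-runnable."""
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
        "config": config.model_dump(),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
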