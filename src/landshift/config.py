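"""Validated run configuration and its YAML round trip.

The shipped defaults are the published global calibration: non-barren land
T = 11.26e9 ha, conversion fractions alpha = 0.4 / zeta = 0.9, abandonment
split gamma = 0.4, recovery rates beta = 0.01 / delta = 1.0 per year, urban
footprint s = 0.06 ha/person, and the three logistic drivers

    population   p: x0 = 310e6,  K = 10.5e9, r = 0.032, tI = 1998.3
    consumption  c: x0 = 571,    K = 1940,   r = 0.019, tI = 1995.8
    yield        y: x0 = 150,    K = 3391,   r = 0.039, tI = 1995.7

Unknown keys are rejected on load; omitted keys fall back to these
defaults.  ``load_config`` / ``save_config`` round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import ModelParams
from .drivers import DriverSet, LogisticDriver

__all__ = [
    "DriverConfig",
    "DriversConfig",
    "LandParamsConfig",
    "NumericsConfig",
    "ScanConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "default_config_path",
    "build_driver_set",
    "build_model_params",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DriverConfig(_Strict):
    """One translated logistic driver (floor, gain, rate, inflection year)."""

    x0: float = Field(ge=0)
    K: float = Field(gt=0)
    r: float = Field(gt=0)
    tI: float


class DriversConfig(_Strict):
    p: DriverConfig = Field(
        default_factory=lambda: DriverConfig(x0=310e6, K=10.5e9, r=0.032, tI=1998.3)
    )
    c: DriverConfig = Field(
        default_factory=lambda: DriverConfig(x0=571.0, K=1940.0, r=0.019, tI=1995.8)
    )
    y: DriverConfig = Field(
        default_factory=lambda: DriverConfig(x0=150.0, K=3391.0, r=0.039, tI=1995.7)
    )
    s: float = Field(default=0.06, gt=0, description="urban area per person, ha")


class LandParamsConfig(_Strict):
    T: float = Field(default=11.26e9, gt=0, description="non-barren land, ha")
    alpha: float = Field(default=0.4, ge=0, le=1)
    zeta: float = Field(default=0.9, ge=0, le=1)
    gamma: float = Field(default=0.4, ge=0, le=1)
    beta: float = Field(default=0.01, ge=0)
    delta: float = Field(default=1.0, ge=0)
    # None -> T / 0.85 (roughly 15% of global land is arid/barren)
    total_land_with_barren: float | None = Field(default=None, gt=0)
    preag_forest_frac: float = Field(default=0.575, ge=0, le=1)

    @model_validator(mode="after")
    def _fill_total(self) -> "LandParamsConfig":
        if self.total_land_with_barren is None:
            object.__setattr__(self, "total_land_with_barren", self.T / 0.85)
        if self.total_land_with_barren < self.T:
            raise ValueError("total_land_with_barren must be >= T")
        return self


class NumericsConfig(_Strict):
    t_start: float = 1000.0
    dt: float = Field(default=0.1, gt=0)
    horizon_cap: float = Field(default=2000.0, ge=500)
    record_every: float = Field(default=1.0, gt=0)
    reexpand_from_abandoned: bool = False


class ScanConfig(_Strict):
    n_ky: int = Field(default=30, ge=2)
    n_kc: int = Field(default=30, ge=2)
    t_e: float = 2009.0
    lo_factor: float = Field(default=1.02, gt=1.0)
    hi_factor: float = Field(default=3.0, gt=1.0)


class RunConfig(_Strict):
    """Everything a run needs: parameters, drivers, numerics, scan, seed."""

    params: LandParamsConfig = Field(default_factory=LandParamsConfig)
    drivers: DriversConfig = Field(default_factory=DriversConfig)
    numerics: NumericsConfig = Field(default_factory=NumericsConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    seed: int = 0
    output_dir: str | None = None


def build_driver_set(cfg: RunConfig) -> DriverSet:
    """Instantiate the logistic drivers from a config."""
    d = cfg.drivers
    return DriverSet(
        p=LogisticDriver(**d.p.model_dump()),
        c=LogisticDriver(**d.c.model_dump()),
        y=LogisticDriver(**d.y.model_dump()),
        s=d.s,
    )


def build_model_params(cfg: RunConfig) -> ModelParams:
    p = cfg.params
    return ModelParams(
        T=p.T,
        alpha=p.alpha,
        zeta=p.zeta,
        gamma=p.gamma,
        beta=p.beta,
        delta=p.delta,
        total_land_with_barren=p.total_land_with_barren,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config as YAML such that ``load_config`` restores it exactly."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def default_config_path() -> Path:
    """Path of the YAML file shipping the default calibration."""
    return Path(str(resources.files("landshift").joinpath("data/default_config.yaml")))
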