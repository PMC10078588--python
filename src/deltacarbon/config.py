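"""Run configuration schema and builders.

A run is fully described by one structured-text (YAML) document with
geometry, kinetic-parameter, photochemistry, optics, forcing, scenario and
output blocks plus a seed.  Every field has a default (the calibrated
parameter table where one exists), unknown keys are rejected, and the
resolved configuration is serialized alongside every output so a run can be
reproduced from its output directory alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .carbon_kinetics import KineticParams
from .column_chain import ChainGeometry, ChainModel
from .forcing_synth import ForcingSeries, default_forcing
from .photochem import AQYSpectrum, PhotoTransferMatrix
from .spectral_optics import IOPLibrary

__all__ = ["RunConfig", "load_config", "dump_config", "build_model",
           "build_forcing"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    names: list[str] = ["pilot", "delta", "mouth", "plume", "ocean"]
    areas_m2: list[float] = [1.0e9, 1.25e9, 1.0e9, 4.0e9, 8.0e9]
    depths_m: list[float] = [10.0, 8.0, 10.0, 10.0, 20.0]
    n_layers: int = 10
    branch_weights: dict[str, dict[str, float]] = Field(default_factory=dict)

    def build(self) -> ChainGeometry:
        return ChainGeometry(names=tuple(self.names),
                             areas=np.asarray(self.areas_m2),
                             depths=np.asarray(self.depths_m),
                             n_layers=self.n_layers,
                             branch_weights=self.branch_weights)


class ParamsConfig(_Block):
    """Kinetic parameters, keyed by their standard symbols."""

    kappa_b: float = 0.2
    kappa_c: tuple[float, float, float] = (0.025, 0.01, 0.001)
    kappa_p: tuple[float, float] = (0.03, 0.006)
    kappa_fmax: float = 0.0
    s_max: float = 1.0
    kappa_c1: float = 5.0
    kappa_c2: float = 0.25
    nu_b: float = 1.5
    f_b: tuple[float, float] = (0.1, 0.5)
    w_p: tuple[float, float] = (1.0, 0.4)
    w_max: float = 2.0
    k_iss: float = 51.0
    tau_crit: float = 0.005
    m_tau: float = 1.0e-5
    kt_c: float = 0.069
    kt_p: float = 0.069
    kt_b: float = 0.069
    t_ref: float = 20.0
    mu_max: float = 2.0
    e_k: float = 15.0
    k_n: float = 0.025
    c_to_chl: tuple[float, float] = (40.0, 28.6)

    def build(self) -> KineticParams:
        return KineticParams(**self.model_dump())


class PhotochemConfig(_Block):
    phi0: dict[str, float] = {"cdoc_w": 5e-5, "cdoc_ss": 5e-5, "cdoc_m": 5e-6}
    slope: float = 0.02
    scale: float = 1.0
    transfer: dict[str, tuple[float, float, float]] = {
        "cdoc_w": (0.30, 0.69, 0.01),
        "cdoc_ss": (0.30, 0.69, 0.01),
        "cdoc_m": (0.00, 0.99, 0.01),
    }

    def build(self) -> tuple[AQYSpectrum, PhotoTransferMatrix]:
        return (AQYSpectrum(phi0=self.phi0, slope=self.slope, scale=self.scale),
                PhotoTransferMatrix(rows=self.transfer))


class OpticsConfig(_Block):
    iop_csv: str | None = None    # override the built-in IOP library

    def build(self) -> IOPLibrary:
        if self.iop_csv:
            return IOPLibrary.from_csv(self.iop_csv)
        return IOPLibrary.default()


class ForcingConfig(_Block):
    n_days: int = 183
    noise_sigma: float = 0.0
    salinity: list[float] = [0.0, 0.0, 0.5, 5.0, 25.0]

    def build(self, seed: int) -> ForcingSeries:
        return default_forcing(seed=seed, n_days=self.n_days,
                               salinity=np.asarray(self.salinity),
                               noise_sigma=self.noise_sigma)


class OutputConfig(_Block):
    cadence_days: int = 1


class RunConfig(_Block):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    photochem: PhotochemConfig = Field(default_factory=PhotochemConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    forcing: ForcingConfig = Field(default_factory=ForcingConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    scenario: str = "Base"
    seed: int = 0
    dt: float = 0.005
    spinup_days: int = 45


def load_config(path: str | Path | None) -> RunConfig:
    """Load and schema-validate a YAML run configuration.

    An empty or missing document resolves to the full-default
    configuration; unknown keys or type mismatches raise a validation
    error naming the offending key paths.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("run configuration must be a mapping")
    return RunConfig(**data)


def dump_config(config: RunConfig) -> str:
    """Serialize the fully resolved configuration as YAML."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def build_forcing(config: RunConfig, seed: int | None = None) -> ForcingSeries:
    return config.forcing.build(seed=config.seed if seed is None else seed)


def build_model(config: RunConfig, forcing: ForcingSeries | None = None,
                seed: int | None = None) -> ChainModel:
    """Assemble a simulator from a resolved configuration."""
    from .scenario_engine import SCENARIOS

    if config.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {config.scenario!r}; valid names: "
                         f"{sorted(SCENARIOS)}")
    scen = SCENARIOS[config.scenario]
    params = scen.apply(config.params.build())
    aqy, transfer = config.photochem.build()
    aqy = AQYSpectrum(phi0=aqy.phi0, slope=aqy.slope,
                      scale=aqy.scale * scen.aqy_scale,
                      ref_wavelength=aqy.ref_wavelength)
    forcing = forcing if forcing is not None else build_forcing(config, seed)
    return ChainModel(config.geometry.build(), params, forcing,
                      iops=config.optics.build(), aqy=aqy, transfer=transfer,
                      dt=config.dt, spinup_days=config.spinup_days)
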