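import numpy as np
import pytest

from deltacarbon.carbon_kinetics import KineticParams
from deltacarbon.column_chain import ChainGeometry, ChainModel
from deltacarbon.forcing_synth import ForcingSeries, default_forcing
from deltacarbon.spectral_optics import IOPLibrary, SpectralGrid

import pandas as pd


@pytest.fixture(scope="session")
def grid() -> SpectralGrid:
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def iops(grid) -> IOPLibrary:
    return IOPLibrary.default(grid)


@pytest.fixture
def params() -> KineticParams:
    return KineticParams()


def make_quiet_forcing(n_days: int = 10, n_boxes: int = 5, discharge: float = 0.0,
                       shortwave: float = 0.0, temperature: float = 20.0,
                       current: float = 0.0, salinity=None,
                       boundary=None) -> ForcingSeries:
    """Minimal forcing: constants everywhere, zero lake input."""
    dates = pd.date_range("2019-04-01", periods=n_days, freq="D")
    sal = np.zeros(n_boxes) if salinity is None else np.asarray(salinity, float)
    bnd = {k: np.full(n_days, float(v)) for k, v in (boundary or {}).items()}
    return ForcingSeries(
        dates=dates,
        discharge=np.full(n_days, float(discharge)),
        temperature=np.full(n_days, float(temperature)),
        shortwave=np.full(n_days, float(shortwave)),
        current_speed=np.full(n_days, float(current)),
        salinity=sal,
        boundary=bnd,
        lake_volume=np.zeros(n_days),
    )


def single_box_geometry(depth: float = 10.0, area: float = 1e6,
                        n_layers: int = 10) -> ChainGeometry:
    return ChainGeometry(names=("box",), areas=np.array([area]),
                         depths=np.array([depth]), n_layers=n_layers)


def closed_params(**overrides) -> KineticParams:
    """All transformation processes switched off."""
    base = dict(kappa_c=(0.0, 0.0, 0.0), kappa_p=(0.0, 0.0), kappa_fmax=0.0,
                nu_b=0.0, mu_max=0.0, w_p=(0.0, 0.0), w_max=0.0, m_tau=0.0)
    base.update(overrides)
    return KineticParams(**base)


@pytest.fixture
def quiet_model(params) -> ChainModel:
    """Five default boxes, null forcing, all processes off."""
    f = make_quiet_forcing()
    return ChainModel(ChainGeometry.default(), closed_params(), f,
                      dt=0.01, spinup_days=0)
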