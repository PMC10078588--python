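"""The box-chain simulator.

A short chain of well-mixed boxes (river inflow box, delta, mouth, plume,
ocean), each split into equal-thickness vertical layers, is advanced with
explicit Euler time stepping through an operator sequence of

    advection -> optics -> photochemistry -> kinetics -> settling/resuspension

Advection is first-order upwind along the chain driven by the daily
discharge (plus a small delta-lake side input); salinity and temperature
are prescribed forcing.  Every mass transfer is written into a budget
ledger so a full carbon accounting (boundary inflow, net primary
production, export, deposition, resuspension, microbial/photochemical/
respiratory CO2) closes over any run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import carbon_kinetics as ck
from .carbon_kinetics import (CARBON_VARS, STATE_VARS, KineticParams,
                              N_TO_C_MASS, flocculation_rate,
                              iss_settling_velocity, resuspension_flux,
                              temp_factor)
from .forcing_synth import ForcingSeries
from .photochem import (AQYSpectrum, CARBON_MOLAR_MASS, PhotoTransferMatrix,
                        PHOTO_SOURCES)
from .spectral_optics import (IOPLibrary, SpectralGrid, build_surface_spectrum,
                              kd_spectrum, total_absorption)

__all__ = [
    "ChainGeometry",
    "BudgetLedger",
    "ChainModel",
    "RunOutput",
    "advect_step",
    "VAR_INDEX",
    "MARINE_BACKGROUND",
]

VAR_INDEX = {v: i for i, v in enumerate(STATE_VARS)}
_CARBON_IDX = np.array([VAR_INDEX[v] for v in CARBON_VARS])
_SETTLING_VARS = ("iss", "lpoc", "rpoc")

#: constant offshore background used to initialise the salty end of the chain
MARINE_BACKGROUND = {
    "cdoc_m": 0.30, "cdoc_w": 0.0, "cdoc_ss": 0.0,
    "ncdoc1": 0.030 * 0.48, "ncdoc2": 0.097 * 0.48, "ncdoc3": 0.873 * 0.48,
    "lpoc": 0.02, "rpoc": 0.05, "iss": 1.77, "b1": 0.02, "b2": 0.02,
    "din": 0.05,
}

_H2O_DENSITY = 1000.0  # kg m-3, for bottom stress tau = c_d rho u^2


@dataclass(frozen=True)
class ChainGeometry:
    """Ordered boxes with plan area (m2), depth (m) and shared layer count."""

    names: tuple[str, ...]
    areas: np.ndarray
    depths: np.ndarray
    n_layers: int = 10
    #: optional named branch weights for one interface (flux accounting only)
    branch_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "depths", depths)
        if len(self.names) != areas.size or areas.size != depths.size:
            raise ValueError("names, areas and depths must align")
        if np.any(areas <= 0) or np.any(depths <= 0) or self.n_layers < 1:
            raise ValueError("areas, depths and layer count must be positive")
        for iface, weights in self.branch_weights.items():
            if iface not in self.interfaces:
                raise ValueError(f"branch weights reference unknown interface "
                                 f"{iface!r}")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"branch weights on {iface!r} must sum to 1")

    @classmethod
    def default(cls) -> "ChainGeometry":
        """Five boxes: river inflow, delta, mouth, plume (10 m isobath), ocean."""
        return cls(
            names=("pilot", "delta", "mouth", "plume", "ocean"),
            areas=np.array([1.0e9, 1.25e9, 1.0e9, 4.0e9, 8.0e9]),
            depths=np.array([10.0, 8.0, 10.0, 10.0, 20.0]),
        )

    @classmethod
    def four_mouth_preset(cls) -> "ChainGeometry":
        """Default chain with the delta outflow split over four named mouths."""
        geo = cls.default()
        return cls(names=geo.names, areas=geo.areas, depths=geo.depths,
                   n_layers=geo.n_layers,
                   branch_weights={"delta->mouth": {
                       "SM": 0.79, "EMK": 0.07, "MM": 0.07, "NM": 0.07}})

    @property
    def n_boxes(self) -> int:
        return len(self.names)

    @property
    def volumes(self) -> np.ndarray:
        return self.areas * self.depths

    @property
    def dz(self) -> np.ndarray:
        """Layer thickness per box (equal layers)."""
        return self.depths / self.n_layers

    @property
    def layer_volumes(self) -> np.ndarray:
        return self.volumes / self.n_layers

    @property
    def interfaces(self) -> tuple[str, ...]:
        between = tuple(f"{a}->{b}" for a, b in zip(self.names[:-1],
                                                    self.names[1:]))
        return ("inflow",) + between + ("export",)


@dataclass
class BudgetLedger:
    """Cumulative mass bookkeeping (g) for the conservation audit.

    Carbon closure: initial stock + boundary inflow + net primary production
    = current stock (water column + benthic) + export + CO2 sinks.
    Deposition and resuspension are internal transfers between the water
    column and the benthic pool and are tallied for diagnostics.
    """

    inflow: dict[str, float] = field(default_factory=lambda: {v: 0.0 for v in STATE_VARS})
    outflow: dict[str, float] = field(default_factory=lambda: {v: 0.0 for v in STATE_VARS})
    deposition: dict[str, float] = field(default_factory=lambda: {v: 0.0 for v in _SETTLING_VARS})
    resuspension: dict[str, float] = field(default_factory=lambda: {v: 0.0 for v in _SETTLING_VARS})
    microbial_co2: float = 0.0
    photo_co2: float = 0.0
    respiration_co2: float = 0.0
    npp: float = 0.0
    initial_carbon: float = 0.0

    @property
    def co2_total(self) -> float:
        return self.microbial_co2 + self.photo_co2 + self.respiration_co2

    def carbon_inflow(self) -> float:
        return sum(self.inflow[v] for v in CARBON_VARS)

    def carbon_outflow(self) -> float:
        return sum(self.outflow[v] for v in CARBON_VARS)

    def closure_residual(self, current_carbon: float) -> float:
        """Relative carbon-audit residual for a current total stock (g C)."""
        expected = (self.initial_carbon + self.carbon_inflow() + self.npp
                    - self.carbon_outflow() - self.co2_total)
        scale = max(abs(expected), abs(current_carbon), 1.0)
        return (current_carbon - expected) / scale

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": f"inflow_{v}", "mass_g": m} for v, m in self.inflow.items()]
        rows += [{"term": f"outflow_{v}", "mass_g": m} for v, m in self.outflow.items()]
        rows += [{"term": f"deposition_{v}", "mass_g": m} for v, m in self.deposition.items()]
        rows += [{"term": f"resuspension_{v}", "mass_g": m} for v, m in self.resuspension.items()]
        rows += [{"term": "microbial_co2", "mass_g": self.microbial_co2},
                 {"term": "photo_co2", "mass_g": self.photo_co2},
                 {"term": "respiration_co2", "mass_g": self.respiration_co2},
                 {"term": "npp", "mass_g": self.npp},
                 {"term": "initial_carbon", "mass_g": self.initial_carbon}]
        return pd.DataFrame(rows)


@dataclass
class RunOutput:
    """Time series, flux ledger, budget and provenance from one run."""

    dataset: xr.Dataset
    fluxes: xr.DataArray            # g per day, dims (time, interface, constituent)
    budget: BudgetLedger
    closure: float                  # final relative carbon-audit residual
    config: dict
    spinup_days: int

    @property
    def post_spinup(self) -> xr.Dataset:
        return self.dataset.isel(time=slice(self.spinup_days, None))


def advect_step(conc: np.ndarray, geometry: ChainGeometry, discharge: float,
                boundary_conc: np.ndarray, dt_days: float,
                lake_discharge: float = 0.0, lake_box: int = 1,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One first-order upwind advection step along the chain.

    ``conc`` has shape (n_vars, n_boxes, n_layers); ``boundary_conc``
    (n_vars,) is the river inflow concentration.  The optional lake side
    input enters ``lake_box`` with the same boundary concentrations.
    Returns (new concentrations, interface masses (n_interfaces, n_vars) in
    g for this step, inflow masses (n_vars,)).
    """
    if discharge < 0 or lake_discharge < 0:
        raise ValueError("discharge must be nonnegative")
    dt_s = dt_days * 86400.0
    nb, nl = geometry.n_boxes, geometry.n_layers
    lake_box = min(lake_box, nb - 1)   # short chains: side input joins the end
    vols = geometry.volumes
    q_out = np.where(np.arange(nb) >= lake_box, discharge + lake_discharge,
                     discharge)
    courant = q_out * dt_s / vols
    if np.any(courant >= 1.0):
        i = int(np.argmax(courant))
        raise RuntimeError(
            f"advective CFL violation in box {geometry.names[i]!r}: "
            f"Q dt = {q_out[i] * dt_s:.3e} m3 exceeds volume {vols[i]:.3e} m3; "
            "reduce dt or enlarge the box")

    # per-layer masses leaving each box (equal split over sigma layers)
    mass_out = q_out[None, :, None] * dt_s * conc / nl       # (nv, nb, nl)
    mass_in = np.zeros_like(conc)
    mass_in[:, 1:, :] = mass_out[:, :-1, :]
    river_in = discharge * dt_s * boundary_conc              # (nv,)
    mass_in[:, 0, :] += river_in[:, None] / nl
    lake_in = lake_discharge * dt_s * boundary_conc
    mass_in[:, lake_box, :] += lake_in[:, None] / nl

    new = conc + (mass_in - mass_out) / (vols[None, :, None] / nl)

    iface_mass = np.empty((nb + 1, conc.shape[0]))
    iface_mass[0] = river_in
    iface_mass[1:] = mass_out.sum(axis=2).T                  # box i -> i+1, last = export
    return new, iface_mass, river_in + lake_in


class ChainModel:
    """Stateful simulator binding geometry, parameters, optics and forcing."""

    def __init__(self, geometry: ChainGeometry, params: KineticParams,
                 forcing: ForcingSeries, iops: IOPLibrary | None = None,
                 aqy: AQYSpectrum | None = None,
                 transfer: PhotoTransferMatrix | None = None,
                 dt: float = 0.005, drag_coefficient: float = 0.0025,
                 lake_box: int = 1, spinup_days: int = 45,
                 initial: np.ndarray | None = None):
        self.geometry = geometry
        self.params = params
        self.forcing = forcing
        self.iops = iops or IOPLibrary.default()
        self.grid: SpectralGrid = self.iops.grid
        self.aqy = aqy or AQYSpectrum()
        self.transfer = transfer or PhotoTransferMatrix()
        if dt <= 0 or abs(round(1.0 / dt) - 1.0 / dt) > 1e-9:
            raise ValueError("dt must be a positive divisor of one day")
        self.dt = float(dt)
        self.steps_per_day = int(round(1.0 / dt))
        self.drag_coefficient = drag_coefficient
        self.lake_box = min(int(lake_box), geometry.n_boxes - 1)
        self.spinup_days = int(spinup_days)
        if forcing.salinity.shape != (geometry.n_boxes,):
            raise ValueError("forcing salinity must provide one value per box")

        nb, nl = geometry.n_boxes, geometry.n_layers
        self.conc = (initial.copy() if initial is not None
                     else self._initial_state())
        if self.conc.shape != (len(STATE_VARS), nb, nl):
            raise ValueError("initial state has wrong shape")
        # benthic pools (g m-2): iss, lpoc, rpoc
        split = params.resusp_iss_fraction
        poc_each = (1.0 - split) / 2.0
        self.benthic = np.outer([split, poc_each, poc_each],
                                np.full(nb, params.benthic_init))
        self.ledger = BudgetLedger()
        self.ledger.initial_carbon = self.total_carbon()
        self.time_days = 0.0
        # precomputed spectra
        self._aqy_bands = {c: self.aqy.evaluate(c, self.grid.wavelengths)
                           for c in PHOTO_SOURCES}
        self._photon_conv = (self.grid.wavelengths * 1e-9 * self.grid.band_width
                             / (6.62607015e-34 * 2.99792458e8 * 6.02214076e23))
        self._kappa_doc = np.array(
            [params.kappa_c[params.doc_lability[v]] for v in ck.DOC_VARS])
        self._last_optics: dict | None = None
        # hot-path caches: daily boundary matrix, static flocculation rates
        self._boundary = np.array(
            [forcing.boundary.get(v, np.zeros(forcing.n_days))
             for v in STATE_VARS])                           # (nv, n_days)
        self._doc_idx = np.array([VAR_INDEX[v] for v in ck.DOC_VARS])
        kf = flocculation_rate(forcing.salinity, params)     # (nb,)
        self._kf_doc = np.zeros((len(ck.DOC_VARS), nb, 1))
        for j, v in enumerate(ck.DOC_VARS):
            if v in ("cdoc_w", "cdoc_ss"):
                self._kf_doc[j] = kf[:, None]
        self._ed0_day: tuple[int, np.ndarray] | None = None

    # -- state helpers -----------------------------------------------------

    def _initial_state(self) -> np.ndarray:
        """Blend river (day-0 boundary) and marine backgrounds by salinity."""
        nb, nl = self.geometry.n_boxes, self.geometry.n_layers
        sal = self.forcing.salinity
        w = sal / max(sal.max(), 1e-12) if sal.max() > 0 else np.zeros(nb)
        conc = np.zeros((len(STATE_VARS), nb, nl))
        for v, i in VAR_INDEX.items():
            river = self.forcing.boundary.get(v, np.zeros(1))[0]
            marine = MARINE_BACKGROUND.get(v, 0.0)
            conc[i] = ((1.0 - w) * river + w * marine)[:, None]
        return conc

    def total_carbon(self) -> float:
        """Total organic carbon stock (g C): water column plus benthic POC."""
        water = (self.conc[_CARBON_IDX]
                 * self.geometry.layer_volumes[None, :, None]).sum()
        benthic = ((self.benthic[1] + self.benthic[2])
                   * self.geometry.areas).sum()
        return float(water + benthic)

    def state_frame(self) -> pd.DataFrame:
        """Flat snapshot of the current state (diagnostics / abort dumps)."""
        nb, nl = self.geometry.n_boxes, self.geometry.n_layers
        idx = pd.MultiIndex.from_product(
            [self.geometry.names, range(nl)], names=["box", "layer"])
        return pd.DataFrame(self.conc.reshape(len(STATE_VARS), -1).T,
                            index=idx, columns=list(STATE_VARS))

    # -- operators ---------------------------------------------------------

    def _advect(self, day: int) -> np.ndarray:
        f = self.forcing
        lake_q = f.lake_volume[day] / 86400.0
        self.conc, iface_mass, in_mass = advect_step(
            self.conc, self.geometry, float(f.discharge[day]),
            self._boundary[:, day], self.dt, lake_discharge=lake_q,
            lake_box=self.lake_box)
        for v, i in VAR_INDEX.items():
            self.ledger.inflow[v] += float(in_mass[i])
            self.ledger.outflow[v] += float(iface_mass[-1, i])
        return iface_mass

    def _optics(self, day: int) -> dict:
        p = self.params
        C = self.conc
        chl = 1000.0 * (C[VAR_INDEX["b1"]] / p.c_to_chl[0]
                        + C[VAR_INDEX["b2"]] / p.c_to_chl[1])
        spm = (C[VAR_INDEX["iss"]] + C[VAR_INDEX["lpoc"]]
               + C[VAR_INDEX["rpoc"]])
        conc = {"cdoc_w": C[VAR_INDEX["cdoc_w"]],
                "cdoc_ss": C[VAR_INDEX["cdoc_ss"]],
                "cdoc_m": C[VAR_INDEX["cdoc_m"]],
                "chl": chl, "spm": spm}
        a_t = total_absorption(conc, self.iops)              # (nb, nl, nband)
        b_b = self.iops.bb_w + self.iops.bb_star_spm * spm[..., None]
        kd = kd_spectrum(a_t, b_b, self.forcing.solar_zenith)
        dz = self.geometry.dz[:, None, None]
        if self._ed0_day is None or self._ed0_day[0] != day:
            self._ed0_day = (day, build_surface_spectrum(
                float(self.forcing.shortwave[day]), self.grid))
        ed0 = self._ed0_day[1]
        trans = np.exp(-kd * dz)
        nb, nl = self.geometry.n_boxes, self.geometry.n_layers
        ed_if = np.empty((nb, nl + 1, self.grid.n_bands))
        ed_if[:, 0] = ed0
        ed_if[:, 1:] = ed0 * np.cumprod(trans, axis=1)
        ed_mid = ed_if[:, :-1] * np.exp(-0.5 * kd * dz)
        par_mask = self.grid.par_mask()
        bw = self.grid.band_width
        par_mid = ed_mid[..., par_mask].sum(axis=-1) * bw
        par_if = ed_if[..., par_mask].sum(axis=-1) * bw
        with np.errstate(divide="ignore", invalid="ignore"):
            kd_par = np.where(
                par_if[:, :-1] > 0,
                -np.log(np.maximum(par_if[:, 1:], 1e-300)
                        / np.maximum(par_if[:, :-1], 1e-300)) / self.geometry.dz[:, None],
                0.0)
        optics = {"a_t": a_t, "ed_if": ed_if, "ed_mid": ed_mid,
                  "par_mid": par_mid, "kd_par": kd_par, "kd": kd}
        self._last_optics = optics
        return optics

    def _photochem(self, optics: dict) -> None:
        if self.aqy.scale == 0.0:
            return
        dt_s = self.dt * 86400.0
        dz = self.geometry.dz[:, None, None]
        pf = optics["ed_if"] * self._photon_conv                 # mol m-2 s-1
        absorbed = (pf[:, :-1] - pf[:, 1:]) / dz                 # mol m-3 s-1
        a_t = optics["a_t"]
        safe_at = np.where(a_t > 0, a_t, 1.0)
        cell_v = self.geometry.layer_volumes[:, None]
        gains_m = np.zeros_like(self.conc[0])
        for src in PHOTO_SOURCES:                                # m processed last
            i = VAR_INDEX[src]
            a_c = getattr(self.iops, f"a_star_{src}") * self.conc[i][..., None]
            photons = absorbed * np.where(a_t > 0, a_c / safe_at, 0.0)
            rate = (photons * self._aqy_bands[src]).sum(axis=-1) \
                * CARBON_MOLAR_MASS                              # g C m-3 s-1
            loss = rate * dt_s
            avail = self.conc[i] + (gains_m if src == "cdoc_m" else 0.0)
            loss = np.minimum(loss, np.maximum(avail, 0.0))
            if src == "cdoc_m":
                self.conc[i] += gains_m - loss
            else:
                self.conc[i] -= loss
                gains_m += self.transfer.fraction(src, "cdoc_m") * loss
            self.conc[VAR_INDEX["ncdoc3"]] += \
                self.transfer.fraction(src, "ncdoc3") * loss
            self.ledger.photo_co2 += float(
                (self.transfer.fraction(src, "dic") * loss * cell_v).sum())

    def _kinetics(self, day: int, optics: dict) -> None:
        p = self.params
        dt = self.dt
        C = self.conc
        t = float(self.forcing.temperature[day])
        theta_c = float(temp_factor(t, p.kt_c, p.t_ref))
        theta_p = float(temp_factor(t, p.kt_p, p.t_ref))
        cell_v = self.geometry.layer_volumes[:, None]

        # DOC pools: microbial loss everywhere, flocculation on riverine CDOC
        doc = C[self._doc_idx]                                  # (6, nb, nl)
        micro = self._kappa_doc[:, None, None] * theta_c * doc * dt
        floc = self._kf_doc * doc * dt
        total = micro + floc
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(total > 0,
                              np.minimum(1.0, doc / np.where(total > 0, total,
                                                             1.0)), 0.0)
        micro *= factor
        floc *= factor
        C[self._doc_idx] = doc - micro - floc
        C[VAR_INDEX["rpoc"]] += floc.sum(axis=0)
        self.ledger.microbial_co2 += float((micro.sum(axis=0) * cell_v).sum())

        # POC hydrolysis to non-chromophoric DOC
        for j, v in enumerate(ck.POC_VARS):
            i = VAR_INDEX[v]
            loss = np.minimum(p.kappa_p[j] * theta_p * C[i] * dt, C[i])
            C[i] -= loss
            C[VAR_INDEX[p.hydrolysis_target[j]]] += loss

        # phytoplankton growth / exudation / predation, DIN-coupled
        par = optics["par_mid"]
        din_i = VAR_INDEX["din"]
        theta_b = float(temp_factor(t, p.kt_b, p.t_ref))
        n_lim = C[din_i] / (C[din_i] + p.k_n)
        growth = []
        for g, bv in enumerate(("b1", "b2")):
            b = C[VAR_INDEX[bv]]
            light_lim = par / (par + p.e_k)
            growth.append(p.mu_max * theta_b
                          * np.minimum(light_lim, n_lim) * b * dt)
        uptake = N_TO_C_MASS * (growth[0] + growth[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            din_factor = np.where(uptake > 0, np.minimum(
                1.0, C[din_i] / np.where(uptake > 0, uptake, 1.0)), 1.0)
        for g, bv in enumerate(("b1", "b2")):
            i = VAR_INDEX[bv]
            gr = growth[g] * din_factor
            pred = np.minimum(p.nu_b * theta_b * C[i] ** 2 * dt, C[i])
            C[i] += (1.0 - p.kappa_b) * gr - pred
            C[VAR_INDEX["cdoc_m"]] += p.kappa_b * gr
            C[VAR_INDEX["lpoc"]] += p.f_b[0] * pred
            C[VAR_INDEX["rpoc"]] += p.f_b[1] * pred
            C[VAR_INDEX["ncdoc1"]] += p.predation_to_ncdoc1 * pred
            resp = p.predation_to_co2 * pred
            C[din_i] += N_TO_C_MASS * resp - N_TO_C_MASS * gr
            self.ledger.npp += float((gr * cell_v).sum())
            self.ledger.respiration_co2 += float((resp * cell_v).sum())
        np.maximum(C[din_i], 0.0, out=C[din_i])   # guard rounding at exhaustion

    def _settling_resuspension(self, day: int) -> None:
        p = self.params
        dt = self.dt
        dz = self.geometry.dz[:, None]
        areas = self.geometry.areas
        pools = {"iss": None, "lpoc": p.w_p[0], "rpoc": p.w_p[1]}
        for k, (var, w_const) in enumerate(pools.items()):
            i = VAR_INDEX[var]
            C = self.conc[i]
            w = (iss_settling_velocity(C, p) if w_const is None
                 else np.full_like(C, w_const))
            flux = w * C                                   # g m-2 d-1, downward
            delta = np.empty_like(C)
            delta[:, 0] = -flux[:, 0]
            delta[:, 1:] = flux[:, :-1] - flux[:, 1:]
            self.conc[i] = C + delta * dt / dz
            dep = flux[:, -1] * dt                         # g m-2 to the bed
            self.benthic[k] += dep
            self.ledger.deposition[var] += float((dep * areas).sum())

        u = float(self.forcing.current_speed[day])
        tau = self.drag_coefficient * _H2O_DENSITY * u ** 2
        r = float(resuspension_flux(tau, p))               # g m-2 s-1
        if r > 0.0:
            demand = r * dt * 86400.0                      # g m-2 this step
            total = self.benthic.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                comp = np.where(total > 0, self.benthic / np.where(
                    total > 0, total, 1.0), 0.0)
            lift = comp * np.minimum(demand, total)
            self.benthic -= lift
            dz_bot = self.geometry.dz
            for k, var in enumerate(_SETTLING_VARS):
                self.conc[VAR_INDEX[var]][:, -1] += lift[k] / dz_bot
                self.ledger.resuspension[var] += float((lift[k] * areas).sum())

    # -- time stepping -----------------------------------------------------

    def step(self, day: int) -> np.ndarray:
        """Advance one dt: advect -> optics -> photochem -> kinetics -> settle."""
        iface_mass = self._advect(day)
        optics = self._optics(day)
        self._photochem(optics)
        self._kinetics(day, optics)
        self._settling_resuspension(day)
        self.time_days += self.dt
        if not np.all(np.isfinite(self.conc)) or np.any(self.conc < -1e-9):
            bad = self.state_frame()
            raise RuntimeError(
                "state became invalid (NaN or negative) at t = "
                f"{self.time_days:.3f} d; state dump:\n{bad.describe()}")
        np.maximum(self.conc, 0.0, out=self.conc)
        return iface_mass

    def run(self, progress: bool = False) -> RunOutput:
        """Integrate over the full forcing window, recording daily output."""
        geo = self.geometry
        n_days = self.forcing.n_days
        nv, nb, nl = len(STATE_VARS), geo.n_boxes, geo.n_layers
        out_state = np.empty((n_days, nv, nb, nl))
        out_kdpar = np.empty((n_days, nb, nl))
        out_par = np.empty((n_days, nb, nl))
        ifaces = geo.interfaces
        flux_daily = np.zeros((n_days, len(ifaces), nv))
        for day in range(n_days):
            for _ in range(self.steps_per_day):
                iface_mass = self.step(day)
                flux_daily[day] += iface_mass
            out_state[day] = self.conc
            out_kdpar[day] = self._last_optics["kd_par"]
            out_par[day] = self._last_optics["par_mid"]

        coords = {"time": self.forcing.dates, "box": list(geo.names),
                  "layer": np.arange(nl)}
        data = {v: (("time", "box", "layer"), out_state[:, i])
                for v, i in VAR_INDEX.items()}
        data["kd_par"] = (("time", "box", "layer"), out_kdpar)
        data["par"] = (("time", "box", "layer"), out_par)
        ds = xr.Dataset(data, coords=coords,
                        attrs={"dt_days": self.dt,
                               "spinup_days": self.spinup_days})
        fluxes = xr.DataArray(
            flux_daily, dims=("time", "interface", "constituent"),
            coords={"time": self.forcing.dates, "interface": list(ifaces),
                    "constituent": list(STATE_VARS)},
            name="interface_mass", attrs={"units": "g per day"})
        closure = self.ledger.closure_residual(self.total_carbon())
        return RunOutput(dataset=ds, fluxes=fluxes, budget=self.ledger,
                         closure=float(closure), config={},
                         spinup_days=self.spinup_days)
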