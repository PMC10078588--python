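"""Local (per-box, per-layer) biogeochemical reaction rates.

Every non-photochemical reaction in the dissolved/particulate organic carbon,
inorganic suspended sediment, and phytoplankton equations is expressed here
as a pure function of local state, temperature, salinity and light:

* first-order microbial degradation of six DOC reactivity classes,
* first-order hydrolysis of two POC classes back to DOC,
* a salinity bell curve for DOC-to-POC flocculation,
* Michaelis-Menten concentration-dependent sediment settling,
* critical-shear-stress resuspension,
* light/nitrogen co-limited phytoplankton growth with exudation and an
  implicit second-order predation closure.

Rate constants default to the calibrated estuarine parameter set carried in
:class:`KineticParams`; temperature modulation uses exponential theta
functions with a Q10 of roughly 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BoxState",
    "KineticParams",
    "STATE_VARS",
    "CARBON_VARS",
    "DOC_VARS",
    "POC_VARS",
    "temp_factor",
    "microbial_degradation_rate",
    "hydrolysis_rate",
    "flocculation_rate",
    "iss_settling_velocity",
    "settling_flux",
    "resuspension_flux",
    "phyto_rates",
]

#: transported state variables, in canonical order
STATE_VARS = ("cdoc_m", "cdoc_w", "cdoc_ss", "ncdoc1", "ncdoc2", "ncdoc3",
              "lpoc", "rpoc", "iss", "b1", "b2", "din")
DOC_VARS = ("cdoc_m", "cdoc_w", "cdoc_ss", "ncdoc1", "ncdoc2", "ncdoc3")
POC_VARS = ("lpoc", "rpoc")
#: variables measured in g C m-3 (everything except sediment and nitrogen)
CARBON_VARS = DOC_VARS + POC_VARS + ("b1", "b2")

#: molar C:N (Redfield) converted to a g N per g C mass ratio
N_TO_C_MASS = (16.0 * 14.007) / (106.0 * 12.011)


@dataclass
class BoxState:
    """Concentrations in one layer of one box (g m-3; din as g N m-3)."""

    cdoc_m: float = 0.0
    cdoc_w: float = 0.0
    cdoc_ss: float = 0.0
    ncdoc1: float = 0.0
    ncdoc2: float = 0.0
    ncdoc3: float = 0.0
    lpoc: float = 0.0
    rpoc: float = 0.0
    iss: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    din: float = 0.0
    temperature: float = 10.0
    salinity: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration for {name!r}")
        if self.salinity < 0:
            raise ValueError("salinity must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS])


@dataclass
class KineticParams:
    """Rate constants and stoichiometric parameters (defaults = Table set).

    ``kappa_c`` maps lability order (labile, semi-labile, refractory);
    ``kappa_p``, ``f_b`` and ``w_p`` map (labile POC, refractory POC).
    """

    kappa_b: float = 0.2                                  # exuded growth fraction
    kappa_c: tuple[float, float, float] = (0.025, 0.01, 0.001)   # d-1
    kappa_p: tuple[float, float] = (0.03, 0.006)          # d-1
    kappa_fmax: float = 0.0                               # d-1 (0.1 in Floc runs)
    s_max: float = 1.0                                    # salinity of peak floc
    kappa_c1: float = 5.0                                 # sub-optimal shape
    kappa_c2: float = 0.25                                # super-optimal shape
    nu_b: float = 1.5                                     # m3 (g C)-1 predation
    f_b: tuple[float, float] = (0.1, 0.5)                 # predation -> POC split
    w_p: tuple[float, float] = (1.0, 0.4)                 # m d-1 POC sinking
    w_max: float = 2.0                                    # m d-1 max ISS sinking
    k_iss: float = 51.0                                   # g m-3 half saturation
    tau_crit: float = 0.005                               # Pa
    m_tau: float = 1.0e-5                                 # g m-2 s-1 Pa-1
    kt_c: float = 0.069                                   # degC-1 (Q10 ~ 2)
    kt_p: float = 0.069
    kt_b: float = 0.069
    t_ref: float = 20.0                                   # degC
    mu_max: float = 2.0                                   # d-1
    e_k: float = 15.0                                     # W m-2 PAR half sat
    k_n: float = 0.025                                    # g N m-3 half sat
    c_to_chl: tuple[float, float] = (40.0, 28.6)          # g C (g chl)-1
    # lability class (0=labile, 1=semi-labile, 2=refractory) per DOC pool:
    # marine CDOC degrades fastest, winter riverine CDOC slowest
    doc_lability: dict = field(default_factory=lambda: {
        "ncdoc1": 0, "cdoc_m": 0,
        "ncdoc2": 1, "cdoc_ss": 1,
        "ncdoc3": 2, "cdoc_w": 2,
    })
    # hydrolysis products: labile POC -> labile NCDOC, refractory POC ->
    # refractory NCDOC (hydrolysate assumed non-chromophoric)
    hydrolysis_target: tuple[str, str] = ("ncdoc1", "ncdoc3")
    # predation remainder (1 - sum f_b): DOC release vs respired CO2
    predation_to_ncdoc1: float = 0.2
    predation_to_co2: float = 0.2
    resusp_iss_fraction: float = 0.95
    benthic_init: float = 10_000.0                        # g m-2 ISS-equivalent

    def __post_init__(self) -> None:
        if sum(self.f_b) > 1.0 + 1e-12:
            raise ValueError("POC fractions of predation must sum to <= 1")
        for name in ("kappa_b", "kappa_fmax", "nu_b", "w_max", "k_iss",
                     "tau_crit", "m_tau", "mu_max", "e_k", "k_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative")
        if any(k < 0 for k in self.kappa_c) or any(k < 0 for k in self.kappa_p):
            raise ValueError("rate constants must be nonnegative")
        residual = 1.0 - sum(self.f_b)
        routed = self.predation_to_ncdoc1 + self.predation_to_co2
        if abs(routed - residual) > 1e-9:
            raise ValueError("predation remainder routing does not close: "
                             f"1 - sum(f_b) = {residual} but routed {routed}")

    def with_overrides(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


def temp_factor(t, kt: float, t_ref: float = 20.0):
    """Exponential temperature modulation theta = exp(kt (T - T_ref))."""
    return np.exp(kt * (np.asarray(t, dtype=float) - t_ref))


def microbial_degradation_rate(doc_class_conc, class_index: int, t,
                               params: KineticParams):
    """First-order microbial loss (g C m-3 d-1) for one DOC lability class."""
    if class_index not in (0, 1, 2):
        raise KeyError(f"unknown DOC lability class index {class_index}")
    conc = np.asarray(doc_class_conc, dtype=float)
    return params.kappa_c[class_index] * temp_factor(t, params.kt_c, params.t_ref) * conc


def hydrolysis_rate(poc_conc, class_index: int, t, params: KineticParams):
    """First-order POC hydrolysis to DOC (g C m-3 d-1)."""
    if class_index not in (0, 1):
        raise KeyError(f"unknown POC class index {class_index}")
    conc = np.asarray(poc_conc, dtype=float)
    return params.kappa_p[class_index] * temp_factor(t, params.kt_p, params.t_ref) * conc


def flocculation_rate(s, params: KineticParams):
    """Salinity-dependent flocculation rate kappa_f (d-1).

    A bell curve peaking at ``kappa_fmax`` for salinity ``s_max``, with a
    steep sub-optimal rise (shape ``kappa_c1``) and a gentler super-optimal
    decline (shape ``kappa_c2``).  Applies to the two riverine chromophoric
    DOC classes; flocculated mass becomes refractory POC.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("salinity must be nonnegative")
    below = params.kappa_fmax * np.exp(-params.kappa_c1 * (s - params.s_max) ** 2)
    above = params.kappa_fmax * np.exp(-params.kappa_c2 * (params.s_max - s) ** 2)
    return np.where(s < params.s_max, below, above)


def iss_settling_velocity(iss_conc, params: KineticParams):
    """Saturating (Michaelis-Menten style) sediment settling velocity (m d-1)."""
    conc = np.asarray(iss_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    return params.w_max * conc / (conc + params.k_iss)


def settling_flux(conc_above, conc_here, w, dz):
    """Layer tendency (g m-3 d-1) from settling through a layer of thickness dz.

    Upwind in the vertical: w (C_above - C_here) / dz; the top layer takes
    C_above = 0 and the bottom-layer export w C_bottom is the deposition
    flux recorded by the caller.
    """
    dz = np.asarray(dz, dtype=float)
    if np.any(dz <= 0):
        raise ValueError("layer thickness must be positive")
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("settling velocity must be nonnegative")
    return w * (np.asarray(conc_above, float) - np.asarray(conc_here, float)) / dz


def resuspension_flux(tau, params: KineticParams):
    """Excess-shear resuspension mass flux (g m-2 s-1).

    Zero at or below the critical stress, linear in the excess above it.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("bottom stress must be nonnegative")
    return np.where(tau > params.tau_crit,
                    params.m_tau * (tau - params.tau_crit), 0.0)


def phyto_rates(b, din, par, t, group: int, params: KineticParams) -> dict:
    """Phytoplankton source/sink terms (all g C m-3 d-1).

    Growth is Liebig-limited by light and inorganic nitrogen saturation
    terms; a fraction ``kappa_b`` of gross growth is exuded as marine
    chromophoric DOC.  Predation is an implicit second-order closure
    nu_b * theta * b**2 split into POC production (``f_b``), labile
    non-chromophoric DOC, and respired CO2.
    """
    if group not in (0, 1):
        raise KeyError(f"unknown phytoplankton group {group}")
    b = np.asarray(b, dtype=float)
    din = np.asarray(din, dtype=float)
    par = np.asarray(par, dtype=float)
    theta = temp_factor(t, params.kt_b, params.t_ref)
    light_lim = par / (par + params.e_k)
    n_lim = din / (din + params.k_n)
    growth = params.mu_max * theta * np.minimum(light_lim, n_lim) * b
    predation = params.nu_b * theta * b ** 2
    return {
        "growth": growth,
        "exudation": params.kappa_b * growth,
        "predation": predation,
        "poc_production": tuple(f * predation for f in params.f_b),
        "predation_to_ncdoc1": params.predation_to_ncdoc1 * predation,
        "predation_to_co2": params.predation_to_co2 * predation,
        "din_uptake": N_TO_C_MASS * growth,
    }
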