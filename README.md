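# deltacarbon

A desk-scale mechanistic simulator of organic-carbon transformation along a
river–delta–ocean continuum, built for biogeochemists who want to explore how
photodegradation, microbial degradation, flocculation, settling/resuspension
and phytoplankton production reshape the composition and export of dissolved
and particulate organic carbon (DOC, POC) between a high-latitude river mouth
and the coastal ocean — without running a 3-D hydrodynamic model.

The water body is a short chain of well-mixed boxes (river inflow → delta →
mouth → plume → ocean), each with 10 vertical layers, advected by a synthetic
double-pulse freshet hydrograph and advanced by explicit time stepping with a
conservative carbon-budget audit.

## The model

Twelve state variables are transported: three chromophoric DOC classes
(marine CDOC_M, winter-riverine CDOC_W, spring/summer-riverine CDOC_SS),
three non-chromophoric DOC classes split by biological lability
(NCDOC₁/₂/₃), labile and refractory POC, inorganic suspended sediment (ISS),
two phytoplankton groups and dissolved inorganic nitrogen. The DOC balance in
each cell is

    dDOC/dt = transport + κ_b µB − κ_c θ_c [DOC] + κ_p θ_p [POC]
              + pdDOC − κ_f(S) [DOC]

with phytoplankton exudation (κ_b = 0.2), first-order microbial degradation
(κ_c = 0.025 / 0.01 / 0.001 d⁻¹ by lability class, temperature-modulated by
θ = e^{kT(T−20)}), POC hydrolysis to DOC (κ_p = 0.03 / 0.006 d⁻¹, half-lives
23 and 116 days), spectral photodegradation `pdDOC`, and salinity-dependent
flocculation of riverine CDOC into refractory POC,

    κ_f = κ_fmax · exp(−κ_c1 (S − S_max)²)   for S < S_max
    κ_f = κ_fmax · exp(−κ_c2 (S_max − S)²)   for S ≥ S_max

a bell curve peaking at κ_fmax (0.1 d⁻¹ in the flocculation scenario) at
S_max = 1. POC sinks at constant velocities (1.0 / 0.4 m d⁻¹); ISS settles
with a saturating Michaelis–Menten velocity w = w_max [ISS]/([ISS] + κ_ISS)
and both resuspend when bottom shear stress exceeds τ_crit = 0.005 Pa.
Phytoplankton grow under Liebig light/nitrogen limitation and are closed by
an implicit second-order predation term ν_B B².

Light is resolved hyperspectrally (285–700 nm at 5 nm): broadband shortwave
is scaled by 0.43 to its UV-visible fraction, distributed by a 5778 K
black-body spectrum, converted to a diffuse attenuation coefficient via the
semi-analytical form K_d = (1 + m₀θ_s)·a_t + m₁(1 − m₂ e^{−m₃ a_t})·b_b, and
propagated with Beer–Lambert exponentials. Photons absorbed by each CDOC
class drive apparent-quantum-yield (AQY) mass transfers toward CDOC_M,
refractory NCDOC and a small direct CO₂ (photomineralization) sink.

A companion fractionation module estimates non-chromophoric DOC as the
intercept of an ordinary-least-squares regression of DOC on CDOM absorption
at 300 nm, forms seasonal mass-specific absorption spectra, and unmixes
measured CDOM spectra into class concentrations by nonnegative least squares
(a_CDOM(λ) = Σ_c a*_c(λ)·[CDOC_c]), finishing with a 3 % / 9.7 % / 87.3 %
lability split of the non-chromophoric remainder.

## Worked example

Run the Base, no-photodegradation (NoPD) and flocculation (Floc) scenarios on
a shared 60-day seeded synthetic freshet and integrate the organic-carbon
flux crossing the plume interface after a 15-day spin-up:

```python
from deltacarbon import run_suite
from deltacarbon.forcing_synth import default_forcing
from deltacarbon.scenario_engine import (integrate_flux, composition_fractions,
                                         DOC_CLASSES, POC_CLASSES, RIVERINE_CDOC)

forcing = default_forcing(seed=1, n_days=60)
runs = run_suite(["Base", "NoPD", "Floc"], seed=1, forcing=forcing,
                 spinup_days=15)
iface = "plume->ocean"
for name, out in runs.items():
    doc = integrate_flux(out.fluxes, iface, 15, 60, DOC_CLASSES)
    poc = integrate_flux(out.fluxes, iface, 15, 60, POC_CLASSES)
    rc = integrate_flux(out.fluxes, iface, 15, 60, RIVERINE_CDOC)
    print(f"{name:12s} {doc:8.2f}  {poc:7.2f}  {rc:13.2f}   {out.closure:.1e}")
```

which prints

```
scenario           DOC      POC  riverine CDOC   audit
Base           192.72     7.47         109.74   1.0e-15
NoPD           192.72     7.47         109.85   1.2e-15
Floc           174.12    13.05          90.43   6.3e-15
```

Each row is the time-integrated flux in Gg C (1 Gg = 10⁹ g) past the
plume→ocean interface, plus the relative residual of the run's carbon-budget
audit (inflow + primary production = stock + export + CO₂ sinks), which
closes to machine precision. Switching photodegradation off (NoPD) leaves
slightly more riverine chromophoric DOC in the export (109.85 vs 109.74 Gg C
— light penetration is modest in this turbid 60-day window); enabling
flocculation moves carbon from the DOC column to the POC column (DOC falls by
19 Gg C, POC nearly doubles) as riverine CDOC is aggregated into refractory
POC during estuarine mixing. The composition of the Base export,

```python
composition_fractions({c: integrate_flux(runs["Base"].fluxes, iface, 15, 60, [c])
                       for c in DOC_CLASSES + POC_CLASSES})
# {'cdoc_m': 0.027, 'cdoc_w': 0.118, 'cdoc_ss': 0.43, 'ncdoc': 0.388,
#  'lpoc': 0.002, 'rpoc': 0.036}
```

shows the spring/summer riverine CDOC class dominating the exported carbon,
with POC largely lost to settling inshore of the plume interface.

The same experiment is available from the shell:

```sh
deltacarbon suite --seed 1 --out runs/
deltacarbon fluxes runs/Base --interface "plume->ocean"
deltacarbon compare runs/Base runs/Floc
```

## Layout

- `deltacarbon.spectral_optics` — wavelength grid, IOP library, surface
  spectrum, K_d, irradiance propagation
- `deltacarbon.carbon_kinetics` — all non-photochemical reaction rates
- `deltacarbon.photochem` — AQY spectra and photodegradation transfers
- `deltacarbon.column_chain` — the box-chain simulator and budget ledger
- `deltacarbon.cdoc_fractionation` — DOC↔CDOM fractionation (OLS + NNLS)
- `deltacarbon.forcing_synth` — seeded synthetic forcing and test datasets
- `deltacarbon.scenario_engine` — scenario suite, flux integration, comparison
- `deltacarbon.config` / `io_utils` / `cli` — configuration schema, outputs
  with manifests, command-line interface

See `docs/methods.md` for the full model description, parameter defaults and
known limitations.
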