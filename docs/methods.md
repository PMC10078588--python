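# Methods

## Scope and intent

`deltacarbon` is a desk-scale pool-and-flux simulator of organic-carbon
cycling between a large high-latitude river and its coastal ocean. It keeps
the full biogeochemical reaction network — multi-reactivity DOC and POC,
hyperspectral light, photodegradation, flocculation, settling/resuspension,
phytoplankton sources, nitrogen coupling by fixed stoichiometry — while
replacing 3-D hydrodynamics with a one-dimensional advective chain of
well-mixed boxes. It is a tool for studying process interactions and sign
structure, not for reproducing field-scale flux magnitudes: transport
through the chain is set by box volumes and the prescribed hydrograph, so
residence times are a modelling choice, not an emergent property.

## State variables

Twelve transported pools per box and layer (g m⁻³; nitrogen as g N m⁻³):

| pool | meaning |
|---|---|
| `cdoc_m` | marine chromophoric DOC (biolabile, weakly absorbing) |
| `cdoc_w` | winter "base-flow" riverine chromophoric DOC |
| `cdoc_ss` | spring/summer "high-flow" riverine chromophoric DOC |
| `ncdoc1..3` | non-chromophoric DOC: labile, semi-labile, refractory |
| `lpoc`, `rpoc` | labile and refractory particulate organic carbon |
| `iss` | inorganic suspended sediment |
| `b1`, `b2` | two phytoplankton groups (carbon units) |
| `din` | dissolved inorganic nitrogen (NH₄⁺ + NO₃⁻) |

Salinity and temperature are prescribed forcing (per-box ladder, daily
series); they are not prognostic. Each box also carries a benthic pool
(g m⁻²) of deposited ISS/LPOC/RPOC feeding resuspension.

## Kinetics

All rates are first-order except predation (second-order) and are modulated
by exponential temperature functions θ = exp(k_T (T − T_ref)). The defaults
are the calibrated estuarine parameter set:

- κ_b = 0.2 — fraction of gross phytoplankton growth exuded as CDOC_M.
- κ_c = (0.025, 0.01, 0.001) d⁻¹ — microbial degradation of labile,
  semi-labile, refractory DOC. The lability → pool mapping is
  labile = {NCDOC₁, CDOC_M}, semi-labile = {NCDOC₂, CDOC_SS},
  refractory = {NCDOC₃, CDOC_W}: winter riverine CDOC is treated as the
  most biologically refractory pool. The mapping is a configurable
  dictionary on `KineticParams`.
- κ_p = (0.03, 0.006) d⁻¹ — hydrolysis of LPOC and RPOC (half-lives 23 and
  116 days). Hydrolysate is assumed non-chromophoric: LPOC → NCDOC₁,
  RPOC → NCDOC₃ (configurable).
- Flocculation: κ_f(S) is the two-branch bell curve with κ_c1 = 5.0 below
  S_max = 1 and κ_c2 = 0.25 above; κ_fmax = 0 in the baseline and 0.1 d⁻¹
  in the flocculation scenario. It drains CDOC_W and CDOC_SS into RPOC.
- Predation: ν_B θ_B B² with ν_B = 1.5 m³ (g C)⁻¹; its products split 0.1 to
  LPOC, 0.5 to RPOC, 0.2 to NCDOC₁, and 0.2 respired to CO₂ (with the
  matching nitrogen returned to DIN). The 0.2/0.2 split of the remainder is
  a design choice that keeps the carbon audit closed; nothing in the
  underlying reaction network constrains it.
- Growth: µ_max θ_B min(PAR/(PAR+E_k), DIN/(DIN+K_N)) B with µ_max = 2 d⁻¹,
  E_k = 15 W m⁻² (PAR), K_N = 0.025 g N m⁻³ — literature-typical coastal
  values; the growth carbon is new fixation (ledgered as NPP) and consumes
  DIN at Redfield C:N (106:16 molar). Chlorophyll for optics derives from
  fixed C:chl ratios 40.0 and 28.6 g C (g chl)⁻¹.
- Settling: constant w_p = (1.0, 0.4) m d⁻¹ for POC; ISS uses the saturating
  form w = w_max [ISS]/([ISS] + κ_ISS) with w_max = 2 m d⁻¹,
  κ_ISS = 51 g m⁻³. Vertical transport is flux-form upwind, so mass
  telescopes exactly to the bed.
- Resuspension: M_τ (τ − τ_crit) with τ_crit = 0.005 Pa and
  M_τ = 10⁻⁵ g m⁻² s⁻¹ Pa⁻¹, active when the bottom stress
  τ = c_d ρ u² (c_d = 0.0025, u from the prescribed current series) exceeds
  the threshold. Resuspended mass is partitioned by the current benthic
  pool composition (initialised 95 % ISS, 2.5 % LPOC, 2.5 % RPOC at
  10 kg m⁻² total) and never exceeds the available pool.
- Temperature functions: k_T = 0.069 °C⁻¹ (Q₁₀ ≈ 2) and T_ref = 20 °C for
  all three θ functions, independently overridable. The original network
  names these functions without printing parameters; Q₁₀ ≈ 2 is the
  standard aquatic default.

## Optics and photochemistry

The wavelength grid is 285–700 nm at 5 nm (84 bands). Broadband shortwave is
scaled by 0.43 (UV-visible fraction) and distributed by a normalized Planck
spectrum at 5778 K. Total absorption is

a_t(λ) = a_w + Σ_c a*_c(λ)[CDOC_c] + a*_φ(λ)[chl] + a*_SPM(λ)[SPM],

with SPM = ISS + LPOC + RPOC. The built-in IOP library uses a compact
literature-shaped pure-water absorption table, exponential CDOC spectra
a*(λ) = a*₃₀₀ e^{−S(λ−300)} with slopes 0.018 (winter), 0.016
(spring/summer) and 0.022 nm⁻¹ (marine) and a*₃₀₀ of 3.5, 2.5 and
0.8 m² (g C)⁻¹ (riverine a₃₀₀/DOC in the 2–4 m² g⁻¹ range), a two-peak
Gaussian chlorophyll spectrum, an exponential non-algal particle spectrum,
and a spectrally flat particulate backscatter of 0.01 m² g⁻¹. Every
spectrum is overridable via CSV — the library defines the model structure,
not a site calibration.

K_d(λ) = (1 + m₀ θ_s) a_t + m₁ (1 − m₂ e^{−m₃ a_t}) b_b with
(m₀, m₁, m₂, m₃) = (0.005, 4.18, 0.52, 10.8) and a default solar zenith of
30°. Irradiance propagates layer-by-layer with Beer–Lambert exponentials;
rate calculations use mid-layer irradiance; PAR is the 400–700 nm integral.

Photochemistry converts the photon flux absorbed by each chromophoric class
(band-wise share a_c/a_t of the layer's absorbed photons) into carbon loss
through an apparent quantum yield AQY(λ) = scale · φ₀ e^{−0.02(λ−290)} with
φ₀ = 5×10⁻⁵ mol C (mol photons)⁻¹ for the riverine classes and one tenth of
that for CDOC_M. Lost mass is routed by a row-stochastic transfer matrix:
riverine classes → 30 % CDOC_M, 69 % NCDOC₃, 1 % CO₂; CDOC_M → 99 % NCDOC₃,
1 % CO₂ — keeping direct photomineralization far smaller than
photobleaching. The AQY magnitudes are an order-of-magnitude choice (the
underlying photodegradation literature spans 10⁻⁶–10⁻⁴ at UV wavelengths);
the NoPD (scale 0) and 2xPD (scale 2) scenario contrast is the robust,
structural prediction, not the absolute rates.

## Transport and time stepping

Boxes default to (river, delta, mouth, plume, ocean) with volumes 10, 10,
10, 40 and 160 km³, 10 equal sigma layers each, and prescribed salinities
(0, 0, 0.5, 5, 25). Advection is first-order upwind in box space, the daily
discharge applied equally across sigma layers, with an explicit CFL guard
(Q Δt < box volume, abort naming the limiting box). A small delta-lake side
input (0.647 km³ per season, distributed with discharge, carrying same-day
river concentrations) joins the delta box. An optional four-mouth preset
splits the delta→mouth interface flux over named branches
(0.79/0.07/0.07/0.07) for accounting.

The operator sequence per step is advect → optics → photochemistry →
kinetics → settling/resuspension, explicit Euler at dt = 0.005 d by default.
Every loss term is limited to the mass available in its source pool within
the step, and all transfers are written into the budget ledger at their
applied (post-limiting) values, so the global carbon audit —
initial stock + boundary inflow + NPP = stock (water + benthos) + export +
CO₂ sinks — closes to machine precision by construction; the stated
tolerance of 10⁻⁶ relative over a full run leaves headroom for accumulated
rounding in long integrations. Default runs are 183 days (April 1 –
September 30) with the first 45 days flagged as spin-up.

## Synthetic forcing

The generator emulates the drivers of a high-latitude river season:

- Hydrograph: 5000 m³ s⁻¹ base plus Gaussian pulses at day 65 (primary
  freshet, 11 000 m³ s⁻¹, 12 d width) and day 149 (secondary pulse,
  4 000 m³ s⁻¹, 16 d), multiplicatively rescaled to a 150.5 km³ seasonal
  volume; optional seeded lognormal noise.
- Concentration–discharge ratings ln C = a₀ + a₁ ln(Q/Q̄) + a₂ ln²(Q/Q̄) +
  a₃ sin 2πT + a₄ cos 2πT, with presets giving riverine DOC ≈ 6–11,
  POC ≈ 2–6 and ISS ≈ 80–250 g m⁻³ across the freshet. The fitting helper
  is plain OLS in log space with an exponential back-transform (no smearing
  correction; predictions are unbiased in log space and slightly low in
  linear space).
- Riverine DOC is split 50 % CDOC_SS, 12 % CDOC_W, 1 % CDOC_M and the
  non-chromophoric remainder 3 / 9.7 / 87.3 %; POC splits 20/80
  labile/refractory.
- Temperature 0 → 18 °C and shortwave 50 → 300 W m⁻² half-sinusoids peaking
  mid-July; constant 0.05 m s⁻¹ bottom current (τ just above critical, so
  resuspension is active but weak).
- A CDOM-spectrum generator forward-models the mass-specific mixture with
  multiplicative lognormal noise, returning a truth table for recovery
  scoring. Its default noise is one factor per record (spectrometer
  gain/dilution error); a per-band independent mode exists. Because the
  winter and spring/summer spectral slopes differ by only 0.002 nm⁻¹, the
  three-column unmixing design is nearly collinear, and per-band noise at
  the same sigma degrades class separation by an order of magnitude — a
  real limitation of slope-based CDOC class separation that the record-mode
  tests do not exercise.

What the generator does **not** emulate: tides and storm resuspension
events, sea ice, sediment-water dissolved fluxes, multi-year carryover,
spatial heterogeneity within boxes, and hysteresis in the
concentration–discharge relation. Passing tests therefore demonstrate
correct mechanics and sign structure under smooth seasonal forcing, not
field-scale realism.

## Scenarios

Six switch sets share identical forcing: Base; NoPD (AQY scale 0); 2xPD
(scale 2); NoSet (w_p = 0); Floc (κ_fmax = 0.1 d⁻¹); NoMicrobial (κ_c = 0).
The suite treats the no-microbial run as a first-class member. Interface
fluxes are accumulated exactly (mass per daily bin) and integrated over
windows in Gg C with pro-rata edge days; composition is reported over six
classes (CDOC_M, CDOC_W, CDOC_SS, aggregate NCDOC, LPOC, RPOC); time series
smoothing uses a centred 10-day moving mean with edge shrinkage. Scenario
comparisons are element-wise scenario − base.

The expected sign structure on the default seeded season — riverine-CDOC
export NoPD > Base > 2xPD; POC export NoSet > Base; Floc moving flux from
DOC to POC; NoMicrobial DOC stock ≥ Base throughout — is asserted by the
acceptance tests. The photodegradation contrast is small in absolute terms
because the default water column is turbid and box residence near the
surface is short; the ordering is nonetheless deterministic and strict.

## Fractionation

`ncdoc_intercept` regresses DOC on a₃₀₀ (the grid band nearest 300 nm, no
interpolation) and takes the intercept as the non-chromophoric
concentration, clipping a negative intercept to zero with a warning.
Seasonal mass-specific spectra average a_CDOM/CDOC within winter (Nov–Apr)
and spring+summer (May–Oct) groups, excluding records whose chromophoric DOC
is nonpositive. `decompose_spectrum` solves the nonnegative least-squares
problem with scipy's active-set `nnls`, raising on rank-deficient designs
and naming the collinear columns. The default pipeline is one regression
pass plus one NNLS pass; an optional mode iterates spectra ↔ concentrations
to a 10⁻⁶ fixed point. Closure is structural: per record,
CDOC_W + CDOC_SS + CDOC_M + NCDOC = DOC exactly (CDOC is rescaled in the
rare case the NNLS total exceeds DOC). Negative NNLS residual spectra are
reported, never clipped.

## Numerical choices and degenerate inputs

- Explicit Euler with per-process mass limiting was chosen over a stiff
  integrator for transparency and exact auditability of every transfer.
- dt must divide one day; the default 0.005 d keeps the settling Courant
  number w Δt/Δz ≤ 0.01 and first-order operator-splitting error below the
  0.5 % dt-refinement tolerance asserted in tests.
- Division guards: bands with a_t = 0 absorb nothing; empty benthic pools
  resuspend nothing; zero PAR gives zero growth; DIN uptake is scaled so
  nitrogen cannot go negative.
- NaN or negative concentrations after limiting abort the run with a state
  summary rather than propagating.
- Determinism: all randomness flows from explicit seeds through
  `numpy.random.default_rng`; identical configuration + seed reproduces
  bit-identical outputs and manifest hashes.

## Problem sizes used in the shipped experiments

The acceptance suite runs the full 183-day season for all six scenarios at
dt = 0.005 d on the 5-box × 10-layer chain (36 600 steps per run); unit and
property tests use shorter windows (3–90 days), single-box columns, and
coarser dt where only mechanics are under test. The fractionation recovery
experiment uses n = 50 records at 2 % noise with a fixed seed.

## Known limitations

- Flux magnitudes are not comparable to a 3-D simulation: box residence
  times (≈ 12 d for the river box at mean flow, ≈ 49 d for the plume box)
  exceed realistic transit times, so in-water losses are proportionally
  larger than any field estimate.
- No return (upstream) transport: the chain is strictly one-directional, so
  estuarine recirculation and the plume "bulge" retention are absent.
- Nitrogen is a single DIN pool coupled by fixed Redfield stoichiometry;
  there is no DON/PON dynamics and no oxygen.
- The optics library is shape-realistic but not site-calibrated; absolute
  K_d and photodegradation magnitudes should be treated as order-of-
  magnitude.
- The salinity–flocculation curve lacks turbulence dependence, and the
  benthic pool has no diagenesis — deposited carbon is inert until
  resuspended.
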