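# Methods

## Problem and model

A set of N implanted ^125I seeds with unknown air kerma strengths
a = (a_1..a_N) (U = µGy·m²·h⁻¹) irradiates dosimeters on and in a
phantom.  The measured dose at site s over the exposure is modelled as

    D_exp(s) = Σ_i a_i · D_ical(s) + ε_s,

with D_ical the calculated absorbed dose at s per unit strength of seed i
(Gy/U) and ε_s independent measurement noise.  Estimating a by (weighted)
linear least squares is exactly the superposition used in treatment
planning, so the fitted strengths feed straight back into the forward dose
calculation.  The package's claim of interest is operational: re-predicting
the interior dose with the fitted strengths is more accurate than assuming
the planned strengths when a seed falls short.

## Geometry

Water-filled PMMA cylinder, 18 cm diameter, 16 cm long, 2 mm wall, in air;
two model-6711 seeds at r = 1.5 cm, θ = 90°/270°, axes parallel to the
phantom axis; GRDs are 1.5 mm × 12 mm glass rods, axes parallel to the
phantom axis, in triplets (0.9° apart) at 8 surface azimuths (24 rods,
r = 9 cm) and singly at 18 interior points, all in the mid-plane z = 0.
The surface azimuth φ is measured from the direction of seed #1
(φ = 0 ↔ θ = 90°).  Choices the source description leaves open and the
defaults taken here:

- interior water, shell PMMA, exterior air; surface rods centred on the
  outer wall radius (their bodies straddle the wall);
- internal rods and seeds in the mid-plane; surface ring at mid-length;
- seed axes parallel to the phantom axis (symmetric default);
- a 2.8 mm casing at r = 9 cm subtends ≈1.8°, not the quoted 0.9°; the
  quoted 0.9° triplet spacing is used as stated.

Angles are degrees, lengths cm, site indexing by id string.

## Monte Carlo transport

Analog photon transport with two interactions: photoelectric absorption
and incoherent scattering sampled from the free-electron Klein–Nishina
cross section (rejection sampling in x = E'/E).  Coherent (Rayleigh)
scattering is excluded *and* excluded from µ_total, keeping transport
self-consistent; at 20–36 keV in low-Z media this mainly ignores a
small-angle redistribution and is a documented bias, not a hidden one.
Binding (incoherent scattering function) corrections are likewise
neglected.  The kerma approximation applies throughout: secondary
electrons (CSDA range < 30 µm at ≤ 35.5 keV) deposit locally, so absorbed
dose in a rod body is scored by the track-length estimator

    D = Σ_segments L · E · (µ_en/ρ)_glass(E) · 1.602e-13 / V   [Gy/photon].

Emission points are uniform on the silver-core surface (the iodine is
adsorbed on the silver), directions isotropic, line energies from the
packaged spectrum; self-absorption arises from transport through the
core/capsule rather than an analytic correction.  The capsule interior is
modelled as solid titanium between core and outer wall (a slightly
conservative encapsulation).  The non-emitting seed's body is present as
an attenuator by default (interseed attenuation); it can be removed per
run for sensitivity.

Numerics: energy cutoff 2 keV (residual deposited on the spot); all
coefficient lookups are log-log interpolations resampled onto a common
512-point grid; photons escape at a 30 cm world boundary; a photon that
finds no boundary raises a geometry-leak error.  Default 2×10⁶ histories
per seed resolve interior sites to roughly 3–15% and triplet-averaged
surface azimuths to roughly 10–20% MC standard error (batch-based, 20
batches).  The engine's inner loop is numba-compiled and single-threaded;
one master seed drives a sequential deterministic stream, so a fixed seed
and history count reproduce results bit-for-bit.  Validation uses an
infinite-medium point-source driver sharing the collision physics, with
thin spherical-shell track-length tallies: primary-only dose at 3 cm in
water matches E·µ_en·exp(−µr)/(4πr²) to ~0.1%, and vacuum mode exposes
pure inverse-square behaviour.

## Interaction data

No coefficient library is assumed at run time; the packaged 2–40 keV
tables for water, PMMA, air, GD-302M-type phosphate glass, titanium and
silver are generated by `scripts/build_material_tables.py` from
per-element photoelectric power laws anchored at 10 keV (anchor values
consistent with the standard compilations, slopes E^-3.1..-3.3 for low-Z,
silver carrying its 25.514 keV K edge) plus free-electron Klein–Nishina
incoherent cross sections; µ_en = µ_pe + µ_incoh · f_tr with f_tr the KN
mean energy-transfer fraction (photoelectric deposits locally,
fluorescence escape neglected).  Accuracy against reference data is at the
10–20% level, adequate here because every validation compares the engine
against closed forms *on the same tables*, and because the regression and
recovery claims are invariant to kernel scale.  The tables are editable
fixtures; regenerating them is one script run.

The ^125I(6711) spectrum fixture carries six lines (22.1, 25.2, 27.2,
27.5, 31.0, 35.5 keV — Te K X-rays plus silver fluorescence) with yields
rescaled so the total is exactly 1.5951 photons/disintegration, the
constant the unit-conversion chain uses.

## Unit conversions

Per-photon dose → Gy per U over exposure t (hours):

    d × 1.5951 × 3.7e7 × 3600 × t × 1.8 / 1.27.

The 1.8 apparent-activity normalization *multiplies* (one apparent mCi
represents more contained activity than a bare point source); since only
its provenance, not its direction, is documented, the constant lives in
`ConversionConstants` where either convention is a one-line change — note
that its value cancels identically in the fitted strengths' *ratio* and
in all agreement ranges.  Glass-to-water conversion uses the µ_en/ρ ratio
at a single effective energy of 28 keV (the fluence-weighted mean line
energy, rounded); a spectrum-weighted variant would shift the factor by a
few percent and cancels in the same way.  Source decay over the ~24 h
exposure (<1.2%/day) is ignored.

## Regression

Default inverse-variance weighting by the measurement sigmas (the source
description does not state its weighting; the unweighted option is kept).
The covariance is (XᵀWX)⁻¹ with the *provided* sigmas — not rescaled by
residuals — so simulation-based coverage statements are well defined.  No
non-negativity constraint: a negative fitted strength signals model
misfit and raises a warning instead of being hidden by a constraint.

Ratio reporting: the weak/strong ratio in percent, rounded half-away-from
zero to integers for table parity.  Two sigma conventions coexist
deliberately: the module-level `ratio_to_stronger` combines the two
relative errors in quadrature (all one can do with printed per-seed
values), while `SourceStrengthResults.ratio_to_stronger` propagates the
full fit covariance — the two estimates share the same data and are
negatively correlated, which widens the ratio sigma; simulation shows the
covariance form restores nominal ~95% two-sigma coverage where the
quadrature form gives ~88–90%.

## Synthetic data

The generator emulates the study conditions: four scenarios with true
strengths (0.253, 0.132), (0.090, 0.062), (0.046, 0.036), (0.030, 0.029) U
and the plan assuming both seeds at the stronger value; 10% relative,
independent, multiplicative truncated-normal noise applied per rod
(before triplet averaging, so the averaging's variance reduction is
exercised); recorded sigma = 10% of the noisy reading; 24 h exposure.
It does not model GRD fading, energy or angular response, correlated
calibration error, or seed/rod positioning error — so passing recovery
tests demonstrate the statistical machinery under the stated noise model,
not robustness to those systematic effects.  A rod whose forward dose is
exactly zero (possible only at very low MC statistics) is assigned a
detection-limit sigma and excluded from agreement ranges.

## Evaluation

Agreement is the min–max of per-site 100·calculated/measured over the
*interior* sites only (the surface rods are the regression's input, not
its scorecard), rounded to integer percent; the figure of merit is the
largest deviation from 100%.  The published-style min–max ranges for the
real experiments are not reproducible without the unpublished raw
readings; the corresponding check here is distributional: across 200
synthetic replicates of the worst-shortage scenario, the with-regression
maximum deviation is smaller than the without-regression one in ≥95% of
replicates (observed: ~100%).

## Problem sizes

Default kernels use 2×10⁶ histories/seed; the regression and recovery
test fixtures use 4×10⁵ (their truth is defined from the same kernel, so
kernel MC noise does not bias them); the acceptance script uses 10⁶ and
200 replicates per replicated statement.  These sizes are the package's
defaults and render every simulation in seconds on one core.

## Known limitations

- Interaction tables are constructed, not measured: absolute doses carry
  ~10–20% systematic uncertainty (ratios and recovery results do not).
- No coherent scattering, no binding corrections, no fluorescence
  transport (silver K fluorescence appears only as primary spectrum lines).
- Solid-titanium capsule fill slightly overestimates encapsulation
  attenuation.
- 1-D TG-43 backend (point-source g(r), φ_an(r)) rather than the 2-D
  anisotropy table; adequate with seed axes perpendicular to the
  measurement plane, and explicitly not valid near the phantom surface.
- Two-seed scenarios only are exercised; the formalism is N-seed generic
  but conditioning of the fit for many seeds is untested.
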