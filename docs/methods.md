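# Methods

## Physical model

The source is modeled as nested right circular cylinders about the z
axis, origin at the center of the active core: a metallic cobalt core
(radius 0.025 cm, half-length 0.175 cm, ρ = 8.9 g/cm³), a 0.01 cm air
gap around it radially and axially, a 0.015 cm AISI 316L steel capsule
(ρ = 7.8 g/cm³) with flat ends, and a solid 316L cable cylinder of
length 0.2 cm attached at negative z. Flat capsule ends stand in for the
rounded tip of the physical source; the difference matters only for the
near-axis longitudinal dose. The cable density and structure are not
published; solid 316L is assumed, which makes the −z axis slightly more
attenuating than +z (visible in the on-axis dose table rows, as it
should be).

Emission: one photon per history, 1.17 or 1.33 MeV with equal
probability, position uniform in the active core, direction isotropic.
The nuclide yields two photons per disintegration, so per-decay
quantities are scaled by 2 at tally finalization; line correlations are
irrelevant to mean kerma.

Transport is analog: exponential free paths from the total linear
attenuation coefficient of the enabled processes, and at each collision

* **photoelectric** — history terminated. Fluorescence is omitted: the
  K edges of every constituent element except molybdenum lie below the
  10 keV cutoff, and Mo is 2% of the capsule steel.
* **incoherent** — Klein–Nishina scattering on free stationary
  electrons, sampled exactly by Kahn's composition–rejection method.
  Binding and Doppler corrections are a sub-percent effect at these
  energies in low-Z media and are neglected; this is the model's main
  documented approximation below ~100 keV.
* **coherent** (disabled by default) — Thomson-law direction resampling
  at unchanged energy. At ⁶⁰Co energies coherent scattering is a
  ≤0.5% forward-peaked correction with negligible kerma effect.
* **pair production** (enabled by default, above 1.022 MeV) — the photon
  is replaced by two back-to-back 0.511 MeV annihilation photons at the
  collision site; positron range is ignored, consistent with the absence
  of electron transport. Pair events are ~10⁻⁴ of interactions here.

Photons below 10 keV are terminated without local deposition: the
quantity scored is collision kerma via fluence, not deposited energy.
Secondary electrons are not transported, so the scored collision kerma
approximates absorbed dose only where charged-particle equilibrium
holds — i.e. beyond roughly 1 cm from this source; values inside 0.5 cm
should be read as collision kerma, not dose.

## Interaction coefficients

Per-element mass attenuation coefficients (photoelectric, incoherent,
coherent, pair) are shipped as package data on a 10 keV–1.5 MeV grid and
evaluated by log-log interpolation; mixtures follow Bragg additivity.
The tables are constructed by `tools/build_xs_tables.py`:

* incoherent = Klein–Nishina × Z (free-electron);
* element totals for H, C, N, O and Fe anchored to the standard NIST
  compilations (the package reproduces the canonical water curve,
  e.g. μ/ρ = 0.0632 cm²/g at 1.25 MeV, to <0.1% across the grid);
* photoelectric for anchor elements by remainder, for other elements by
  per-atom Z^4.75 scaling from the nearest anchor;
* coherent from a Z³-scaled smooth curve; pair from a Z²-scaled curve.

The remainder bookkeeping folds the free-electron excess of the
Klein–Nishina incoherent term into the photoelectric column at low
energy, keeping compound totals exact while slightly over-absorbing
sub-100-keV photons; the Mo K edge at 20 keV is not modeled. Both
effects are far below the statistical resolution of the results. Mass
energy-absorption coefficients for air and water are the Hubbell–Seltzer
values, log-log interpolated.

## Tallies

Dose scoring uses ring cells: solids of revolution of 0.05 × 0.05 cm
rectangles centered on every (y, z) of the reported lattices — the 32
transverse radii 0.2–20 cm at z = 0, and the away–along grid
y ∈ {0, 0.5, …, 15} cm, z ∈ {0, ±0.25, …, ±15} cm. On-axis (y = 0)
points use 0.05 cm-radius disk cells, since a ring volume vanishes on
the axis; the three on-axis points nearest the source/cable have no cell,
matching the published tables. Fluence is track length over cell volume;
kerma weights each segment by E·(μ_en/ρ)_water at the exact photon
energy, so spectrum binning introduces no kerma bias. Kerma is always
"kerma to water", also inside the solid phantoms. Uncertainties are
history-by-history: per-cell sums and sums of squares of per-history
scores, reported as relative 1σ of the mean.

Air-kerma strength uses a next-event estimator: every source emission
(pdf 1/4π) and every collision (Klein–Nishina pdf toward the detector,
weighted by the scatter probability; pair events as two isotropic
0.511 MeV quanta) contributes exp(−τ)/d² fluence at four transverse
detectors y = 25, 50, 75, 100 cm in a 5 m air sphere, converted to air
kerma at the along-ray energy. S_K/A and the build-up slope b come from
the unweighted OLS fit of k(y)·y² against y, with the intercept variance
propagated from the per-detector statistics. In this model b comes out
slightly negative: at 1.25 MeV, primary attenuation in 1 m of air
(≈0.8%) outweighs scatter build-up. The intercept is insensitive to
this, and a vacuum-sphere run reproduces the same S_K within statistics.

Fluence spectra are scored in 20 keV bins with 2 keV bins bracketing the
two emission lines, normalized to total fluence per cell.

## TG-43 reduction

G_L(r,θ) = β/(L r sinθ) with L = 0.35 cm, continuous through the
long-axis limit 1/(r² − L²/4). Λ uses the ring cell centered at
(y = 1 cm, z = 0) directly — no interpolation, matching the cell-based
scoring. g_L is normalized to exactly 1 at r₀ = 1 cm and fitted with an
unweighted cubic over 0.2–20 cm (no inverse-variance weights: the
transverse-axis statistics are nearly uniform and the published fit is
unweighted by default reading). Ratios propagate relative 1σ in
quadrature, adequate below a few percent. Phantom comparisons report
100·(solid − water)/water per lattice point with combined σ and a 2σ
significance flag.

The power-law effective atomic number (Σ fᵢ Zᵢ^p)^(1/p) over electron
fractions uses the Mayneord exponent p = 2.94 by default (configurable).
It reproduces the conventional 7.416 for water; published Z_eff values
for composite phantoms vary with the (usually unstated) formula, so this
quantity is informational only.

## Synthetic fixtures

`brachymc.fixtures` generates tally archives with closed-form kerma
fields — inverse square, bare G_L, or G_L × exp(−μr) × polynomial
build-up — plus multiplicative lognormal noise of chosen relative σ
(defaulting to the 0.04–2% range of the real tallies), bit-reproducible
from a seed. They validate the analysis stage end to end: the bare-G_L
field must return g_L ≡ 1 to 1e-12, and the attenuated field a known
exponential. They emulate only the radial structure and noise of real
tallies — no spectral content, no scatter physics — so passing fixture
tests certifies the estimator algebra, not the transport.

## Numerical choices

* Log-log linear interpolation for all coefficient tables (standard for
  smooth photon cross sections away from edges).
* Boundary tracing steps to the nearest quadric crossing; points within
  10⁻⁹ cm of a surface are resolved by a nudge along the current
  direction, which prevents grazing-ray loops. Crossings of a quadric
  outside its bounding patch are harmless no-op steps.
* The compiled (numba) kernels implement exactly the physics of the
  readable Python path; the two are cross-checked statistically in the
  test suite, and fixed seeds make every run bit-reproducible.
* History counts: the shipped analyses use 10⁷ (water), 5×10⁶ (PMMA)
  and 2×10⁶ (air) histories, giving ~0.2% statistics at 1 cm and ~0.7%
  at 20 cm; the test suite uses 4×10⁶/2.5×10⁶/10⁶ with correspondingly
  wider assertion bands.

## Known limitations

* No secondary-electron transport: collision kerma only; near-source
  (<1 cm) values are not absorbed dose.
* Free-electron Compton and the remainder-based coefficient split bias
  the low-energy (<100 keV) scattered field at the percent level in ways
  that largely cancel in the TG-43 ratios.
* The 2D anisotropy function F(r,θ) is not computed.
* Capsule tip geometry and cable composition are approximations;
  on-axis values near the source carry that model uncertainty.
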