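# Methods

This note documents the models, conventions and numerical choices behind
`sfdphantom`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data experiments do and do not
demonstrate.

## Phantom model

A phantom is a gelatin/water/Intralipid-20% mixture specified in weight
percent (summing to 100), optionally carrying a hemoglobin additive.  Two
composition rules drive everything downstream:

* **Total water fraction.** Intralipid-20% is itself 80% water by mass, so
  the total water mass fraction is `(water_wt% + 0.8 * IL20_wt%) / 100`.
  The standard four-phantom ladder (89/1/10, 80/10/10, 60/30/10, 40/50/10)
  yields 0.97, 0.88, 0.68 and 0.48.
* **Concentration conversions.** All components are assigned density
  1.00 g/ml by default (overridable table), making mass and volume fractions
  interchangeable and keeping the arithmetic transparent; hemoglobin is
  expressed as micromolar **tetramer** (molar mass 64,500 g/mol), the
  convention used in every output header.  Whole blood is converted with a
  default hemoglobin content of 150 g/l.  The reference hemoglobin batch
  (40 mg powder in a 30.5 g phantom) gives 0.040 / 64500 / 0.0305 l ≈
  20.3 μM nominal.

The composition table mixes weight percent for the bulk components with a
parenthetical volume-percent gloss for Intralipid; the package follows the
weight-percent reading throughout.

Scattering is modeled as a Rayleigh+Mie power law scaled by the Intralipid
weight percent,

    mu_s'(λ) = (IL20_wt% / 10) · a · [ r (λ/λ0)^-4 + (1-r) (λ/λ0)^-b ],

with defaults a = 1.6 mm⁻¹ at λ0 = 700 nm, r = 0.05, b = 2.4.  The
amplitude is a configuration constant tuned so 2% Intralipid gives
mu_s' ≈ 0.7–3.7 mm⁻¹ across 450–1000 nm (the regime of skin-mimicking
phantoms); it is not a calibrated claim about any specific lot of
Intralipid.  Because the ladder holds Intralipid fixed, scattering is
decoupled from the water/gelatin ratio by design.

## Chromophore basis

The unmixing basis holds specific absorption spectra for HbO2, Hb, MetHb
(mm⁻¹ per μM tetramer), water (mm⁻¹ per volume fraction) and the two gelatin
types (mm⁻¹ per mass fraction), tabulated natively at 1 nm over 450–1000 nm
and linearly resampled (never extrapolated) onto any requested grid.

The bundled spectra are **synthetic stand-ins**: smooth Gaussian-band models
anchored at the canonical band positions (water 740/836/970 nm; HbO2 Q-bands
542/576 nm; Hb 556/758 nm; MetHb 500/630 nm; Soret tails below 480 nm) with
magnitudes on the scale of the usual molar extinction compilations.  They
reproduce the features the pipeline's logic depends on — the 970 nm water
peak, the diagnostic 630 nm MetHb band, non-negativity, mutual
distinguishability — but they are not literature data, and results obtained
with them apply to real measurements only after the bundled basis is replaced
by measured/tabulated spectra via the CSV basis-directory interface.

### Gelatin spectrum estimation

Gelatin absorption is estimated from a gelatin/water dilution series as the
non-negative residual left after removing the water contribution, divided by
the gelatin mass fraction and averaged (unweighted) across dilutions.  The
water contribution is removed using the **known recipe water fraction** by
default: the fractions are part of the dilution design, and using them makes
the estimator exactly unbiased (a free least-squares water coefficient
absorbs whatever part of the gelatin spectrum projects onto the water
spectrum, biasing the residual; that variant is available as
`water_mode="fitted"` for sensitivity analysis).  A joint per-wavelength
least-squares fit across all dilutions is available as `joint=True`; with
noiseless data all variants that use the known fractions agree to machine
precision, which is the recovery property the tests freeze at 1e-6 mm⁻¹.

## Forward model: SFD diffuse reflectance

Calibrated spatial-frequency-domain reflectance of a homogeneous
semi-infinite medium is computed with the diffusion-approximation closed
form

    mu_tr   = mu_a + mu_s',      a' = mu_s'/mu_tr,
    mu_eff' = sqrt(3 mu_a mu_tr + (2π fx)²),
    Rd(fx)  = 3 A a' / ((mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A)),

with A = (1 − R_eff)/(2(1 + R_eff)) and R_eff from the standard cubic-in-1/n
polynomial; n = 1.40 by default (water/gelatin/lipid media; the index is not
otherwise constrained).  Spatial frequencies are cycles per mm and the 2π
lives inside mu_eff' — a convention fixed once and verified by test.  The
default frequency set is five evenly spaced values spanning 0–0.2 mm⁻¹,
{0, 0.05, 0.10, 0.15, 0.20}, configurable.

Calibration divides the raw sample matrix by the raw reference matrix and
multiplies by the model prediction for the reference phantom, so instrument
gain and spectral throughput cancel; the calibrated result is invariant to
any common gain.

### Monte Carlo oracle

The diffusion form replaces a scaled-Monte-Carlo lookup solver; to quantify
that substitution the package bundles a photon-transport oracle: pencil-beam
random walks in a semi-infinite medium with Henyey–Greenstein scattering
(g = 0.8, mu_s = mu_s'/(1−g)), survival weighting, Russian roulette below
weight 1e-3 (survival 0.1), and a refractive-index-mismatched Fresnel
boundary.  Exit weights and radii are Hankel-transformed,
Rd(fx) = (1/N) Σ w_i J0(2π fx r_i), which at fx = 0 is identically the plain
diffuse-reflectance tally.  The roulette threshold matters here because the
phantoms are nearly conservative (single-event albedo ≈ 0.999); it bounds
the longest walks while remaining unbiased.  Standard errors are reported
per frequency and scale as photons^-1/2.

Validation over the optical-property pairs the ladder phantoms realize
(mu_s'/mu_a ≥ 20) finds the diffusion model within ~1–5% of transport at low
spatial frequencies, degrading to ~10–15% at fx = 0.15–0.2 mm⁻¹ where the
transport mean free path approaches the modulation period — the known
breakdown regime of the diffusion approximation.  The acceptance suite
checks this agreement at 10⁶ photons on three pairs taken from the most
absorbing ladder phantom at 550, 800 and 970 nm, spanning the low/mid/high
ends of the mu_s' range with the worst-agreement (lowest mu_s') point
included.  The band sits close to its 15% edge at that point; this is a
property of the diffusion approximation itself, not of the sampling.

## Inverse solver

Each wavelength is inverted independently — no spectral priors or smoothing,
so e.g. a single-wavelength absorption spike survives inversion unchanged
(tested).  The solver is two-stage:

1. **Lookup table.** The diffusion model is tabulated on log-spaced grids,
   by default 64×64 over mu_a ∈ [1e-4, 1] mm⁻¹ and mu_s' ∈ [0.1, 10] mm⁻¹
   (covering the phantom regime with margin); the nearest node in
   sum-of-squares over frequencies seeds the search, ties resolved toward
   smaller mu_a.
2. **Refinement.** Damped Gauss–Newton in log10(mu_a, mu_s'), all
   wavelengths advanced simultaneously as one vectorized batch; central
   finite-difference Jacobians (h = 1e-6 in log10 space), damping 1e-10,
   steps clipped to 0.25 decades, at most 40 iterations or a 1e-12 step.

Wavelengths whose optimum touches the table boundary are flagged
`at_bound`; wavelengths whose RMS reflectance misfit exceeds 5% of the mean
measured reflectance (e.g. physically inconsistent frequency dependence) are
flagged `poor_fit` rather than raising.  Noiseless forward–inverse round
trips recover both properties to better than 0.01% across the interior;
under 1% multiplicative reflectance noise the median error stays below 5%.

## Spectral unmixing

Absorption is decomposed as mu_a(λ) = Σ c_i ε_i(λ) by least squares:
non-negative (NNLS) for hemoglobin panels — where a species genuinely absent
is reported as exactly 0 with a finite uncertainty — and unconstrained for
water/gelatin fits, where estimates above 1 are allowed and diagnostic of
calibration or basis error.  One-sigma uncertainties use the residual-scaled
covariance σ_i = sqrt([(EᵀE)⁻¹]_ii · χ²/dof) with dof = n_wavelengths −
n_components; species pinned at zero by the non-negativity bound inherit the
unconstrained covariance.  Under i.i.d. additive noise this convention
matches the empirical replicate scatter within a few percent (checked at 500
replicates).  A condition-number guard (cond(EᵀE) > 1e10) refuses collinear
bases by naming the most correlated pair, rather than fitting silently
unstable coefficients.  Gelatin may be fitted freely (default) or held fixed
at the recipe value via the `fixed=` argument.  The default fit range is the
full 450–1000 nm grid.

## Study analyses

* **Water regression.** Estimated versus designed total water fraction, as
  ordinary least squares or constrained through the origin (slope
  Σxy/Σx²).  R² is reported against the grand-mean null in both modes —
  for constrained fits this can differ from conventions that use the
  zero-model, and can in principle go negative; it is stated explicitly so
  constrained and unconstrained values are comparable.
* **Stability.** A chromophore is stable through the latest timepoint t such
  that every timepoint up to and including t deviates from the initial
  estimate by at most the threshold (default 10%); replicate measurements at
  a timepoint are averaged before thresholding, the first timepoint is
  stable by definition, and recovery after an excursion does not re-open the
  window.  Stability is assessed on raw fitted concentrations, not on
  percentages of the nominal recipe.  No automatic outlier exclusion is
  performed; excluding e.g. a saturated phantom is a user action.

## Synthetic studies

The generator composes recipe → truth → forward model → noise so that every
analysis stage can be scored against known truth:

* **Design**: the four-recipe water ladder at fixed 10% Intralipid-20%,
  three batches, three spatial repeats, measured at 2 h, 4 h, 1 d, 2 d, 3 d,
  4 d; wavelengths 450–1000 nm at 0.5 nm by default.
* **Variability**: independent lognormal factors on the true concentrations
  per batch (5%) and per spatial repeat (3%) — the two error-bar families of
  a multi-batch, multi-site measurement — plus multiplicative Gaussian noise
  on Rd (1%, truncated at physical range).  Batches consume independent
  child streams of the root seed, so enlarging a study never perturbs
  existing batches, and identical (config, seed) regenerate bit-identical
  studies.
* **Drift**: water declines linearly by 8% to a plateau at day 2 and is
  stable afterwards; hemoglobin converts HbO2 → MetHb by first-order
  kinetics with conserved total heme, HbO2(t) = c₀e^(−kt).
* **Hemoglobin scenarios**: `ferrous_powder` starts at 3.2 μM total heme
  with 35% already oxidized to MetHb and converts fast (k = 1.0/day);
  `whole_blood` starts at 4.2 μM with 5% MetHb and converts slowly
  (k = 0.08/day).  These four numbers are tuning constants chosen once to
  reproduce the qualitative contrast between the two preparations
  (MetHb-contaminated and short-lived versus clean and stable for ~3 days)
  at realistic fitted magnitudes; they are not measurements.

What passing the synthetic suite shows: the computational pipeline is
self-consistent — compositions propagate to optical properties, the inverse
solver undoes the forward model, the unmixer undoes the mixing model, and
the analyses recover designed effects at the configured noise levels.  What
it does not show: correctness of the bundled stand-in spectra against real
compounds, validity of the diffusion model beyond the tested regime,
chemical realism of the drift forms, or any instrument effect (stray light,
wavelength miscalibration, spatial nonuniformity) not in the noise model.

## Problem sizes and runtime choices

Replicated analyses use reduced problem sizes chosen to keep the full suite
desk-scale while leaving conclusions unchanged: the noiseless end-to-end
regression runs on a 2 nm grid, replicate studies on a 10 nm grid (the
regression operates on band-integrated quantities and is insensitive to grid
density), uncertainty calibration uses 500 replicates on a 5 nm grid, and
Monte Carlo validation uses 10⁶ photons on three optical-property pairs.

## Known limitations

* The bundled chromophore spectra are parametric stand-ins (see above).
* The diffusion forward model is biased against transport by up to ~15% at
  the highest spatial frequency when mu_s' is low; inversions inherit that
  bias only when applied to real (transport-governed) data, not in the
  synthetic closed loop.
* Hemoglobin chemistry is reduced to a single first-order conversion; pH
  effects, gelatin-type-dependent breakdown and oxygen exchange with the
  environment are not modeled (gelatin type only switches the gelatin
  basis spectrum).
* The measurement model starts at calibrated reflectance; fringe projection
  and three-phase demodulation happen upstream of this package's inputs.
* Homogeneous, semi-infinite, single-layer media only.
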