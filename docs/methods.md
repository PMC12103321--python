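# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, and where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Carbon fractions and the material registry

Carbon mass fractions come from repeat-unit (or compound) empirical
formulas with IUPAC 2021 conventional atomic weights (5 significant
figures): w_C = 12.011·nC / M. `PolymerSpec` stores w_C at the
two-decimal-percent precision quoted on calibrant certificates and data
sheets (92.26 %C for PS, 47.05 %C for KHP, 11.33 %C for Na2CO3), because
that is the number practitioners plug into carbon↔mass conversions — a
1 + 1 mg/L PS spike then adds exactly 1.8452 mg C/L. The full-precision
value is always available via `carbon_mass_fraction()`; the difference is
below 3·10⁻⁵ for every registered material.

Modeling choices: PE as (CH₂)ₙ, PP as (C₃H₆)ₙ, PVC as (C₂H₃Cl)ₙ, PET as
(C₁₀H₈O₄)ₙ, cellulose as anhydroglucose (C₆H₁₀O₅)ₙ. Gold doping of
in-house polyolefin particles is ignored in the carbon math (the dopant
mass fraction is unknown); copolymers, additives and surfactant carbon
are out of scope. These are documented limitations, not parameters.

## Centrifugal sedimentation

Assumptions: rigid spheres in the Stokes regime, swing-bucket rotor at
full deflection (tube axis radial), no wall effects, no hindered
settling, no aggregation, fixed-viscosity fluid. Buoyant particles
(ρp ≤ ρf) get a negative settling speed and a zero pellet fraction;
flotation is not modeled further.

**Geometry reconstruction.** RCF ∝ r at fixed speed, so the radii spanned
by the liquid column follow from the RCF at its two ends and the column
height; ω comes from the RCF at the bottom. The reconstruction is its own
inverse (recomputing RCF at the derived radii returns the inputs
exactly), and the two bench set-points of the reference rotor
(2500 g / 3727 rpm and 4000 g / 4714 rpm) imply the same outer radius
(~161 mm) within 0.5 %, which is the internal-consistency check the test
suite runs.

**Two cutoffs, deliberately distinct.**

- *Nominal* (planning) cutoff: the RCF set on the instrument taken as
  uniform over the column, constant-speed traversal of the height H.
  This is how spin durations are chosen at the bench, so the planner is
  provided (`nominal_spin_time`, `nominal_cutoff_diameter`) and outputs
  are labeled nominal.
- *Effective* cutoff: the exponential trajectory integrated from
  meniscus to bottom under the actual g-force gradient,
  d_eff = sqrt(18µ·ln(r_b/r_t)/(Δρω²t)). `spin_time_for_cutoff` is its
  exact algebraic inverse (round trip to 1e-9 relative).

**Pellet fraction.** The initial particle distribution is uniform per
unit radial length along the column. With k = d²Δρω²/18µ, a particle
starting at r₀ reaches the bottom iff r₀·e^{kt} ≥ r_bottom, so
f = min(1, (r_bottom/H)(1 − e^{−kt})). The alternative constant-velocity
bookkeeping was considered and rejected: it does not reproduce the
pellet composition shares that the position-dependent model yields
consistently across both reference spins. An independent Monte-Carlo
oracle (10⁵ stratified-uniform initial positions propagated
exponentially; stratification keeps the marginal law uniform while
reducing the estimator error to O(1/n)) checks every closed-form pellet
fraction within 3 binomial standard errors in the tests and in the
acceptance script.

**Sequential fractionation bookkeeping.** Each spin applies to the
previous supernatant; unsettled components stay uniform over the
original column volume; pellet liquid volume (~0.5 mL in practice) and
sampling aliquots are *not* deducted. This matches the pellet
composition shares but is known not to match every published
supernatant-side number (the reference supernatant F3 values rest on
unstated volume bookkeeping); the model therefore reports supernatant
concentrations but makes no claim for them beyond mass conservation,
which holds exactly (1e-12 relative) per component across any chain.

Defaults: water at 20 °C with µ = 1.0016 mPa·s and ρ = 1.00 g/cm³; no
temperature→viscosity lookup (the workflow uses a single set value);
g = 9.81 m/s². PS density 1.05 g/cm³ where polystyrene is involved.

## TOC instrument reduction

- Replicate rule: two injections; if their CV exceeds 2 % a third is
  drawn and the mean of the closest pair is accepted, the remaining
  replicate rejected. CV is defined as sample standard deviation (n−1)
  over the mean — the instrument's own convention is unpublished, so
  this choice is documented and the threshold is a parameter. Tie-break
  when the third replicate is exactly equidistant from the first two:
  keep the first two (deterministic, documented).
- Injection plans are verbatim rows of the instrument's volume/range
  table; the modified TC plan (500 µL, 1.0–50.0 mg/L) applies strictly
  above 10 µm — 10 µm itself measures acceptably under both procedures,
  so the boundary stays with the standard plan. Out-of-range samples get
  a gravimetric dilution factor aiming at 5 mg C/L (standard) or
  25 mg C/L (modified), rounded up to one decimal.
- Expected injected counts are reported at full precision and rounded
  half-up only for display; the carbon targets are 5 mg C/L with 50 µL
  (standard) and 25 mg C/L with 500 µL (modified). The 25 mg C/L target
  follows the instrument-table footnote; some published count tables for
  1–10 µm imply a 20 mg C/L target instead, a discrepancy that cannot be
  resolved from the available description and is therefore not asserted.
- Injection counts are Poisson; the pmf is evaluated with scipy over an
  adaptive truncation capturing all but <1e-9 of the mass.

## Recovery arithmetic and uncertainty

All recoveries are 100·measured/expected. The default propagation is
first-order GUM: relative uncertainties in quadrature for ratios,
absolute in quadrature for differences; a linear (straight-addition)
rule is available and every result records which rule produced it. The
quadrature rule is verified in the tests against a 10⁵-draw Monte-Carlo
propagation oracle (within 5 % of the uncertainty for the bundled
spike-recovery cases). Note the published uncertainty of the
subtraction-based 200 nm recovery is reproducible by neither rule
exactly; only central values are asserted anywhere. Negative nets and
residuals are returned unclipped with a machine-readable warning — they
signal contamination or interference, not arithmetic to be hidden.
Display rounding is nearest-integer percent; full precision is retained
internally. AF4 recovery comes in absolute (vs injected mass — one
injection suffices) and relative (vs a no-crossflow reference run)
modes, with the ISO acceptability flag at ≥70 % (configurable).

## Synthetic data

The generator emulates the statistical structure the reduction assumes:

- TOC replicates: lognormal noise at a stated CV (defaults 7 % for
  TC/TIC, matching the between-replicate spread of the modeled
  experiments; lognormal keeps concentrations positive and is
  indistinguishable from normal noise at small CV).
- Unstirred vials: each component is attenuated by
  max(0, 1 − v_settle·t_dead/h_intake) with the gravitational Stokes
  speed, a 2 min syringe dead time and a 2 cm intake depth by default.
  This linear-depletion loss is deliberately illustrative — it
  reproduces the qualitative collapse of unstirred large-particle
  recoveries, but no quantitative loss model exists to calibrate it.
- Particle counting: components outside 250 nm – 5 µm are invisible;
  visible ones give Poisson counts (mean = number concentration ×
  analyzed volume) times a lognormal efficiency factor at the counter's
  CV (default 10 %), reported with the Poisson standard error.
- Dissolved-carbon backgrounds default to ultrapure-water level
  (0.03 mg C/L); river (~0.2) and lake (~0.87) levels are the other
  matrix presets used in the analyses.

All randomness flows from the single scenario seed; identical seeds give
bit-identical datasets. What passing synthetic tests shows: the
reduction pipeline is unbiased (<2 % mean bias over 100 seeds) and its
stated uncertainties cover the truth at 3σ in ≥95 % of 200 seeded
scenarios *under the generator's noise model*. What it does not show:
robustness to matrix interference, hetero-aggregation, filter fouling,
bacterial growth or incomplete combustion — none of which the generator
models.

## Problem sizes

The simulation studies are sized for desk-scale runs: 10⁵ Monte-Carlo
particles per sedimentation check, 10⁵ draws per propagation oracle, 200
seeded scenarios for coverage — each chosen so the statistical power of
the check (3σ bands, 5 % uncertainty agreement) is comfortably reached.

## Known limitations

- Fixed-angle rotors, non-radial tubes, wall effects, hindered settling
  and DLVO/aggregation kinetics are out of scope.
- Carbon fractions ignore dopants, additives, surfactants.
- The supernatant-side volume bookkeeping of real pellet harvesting
  (pellet liquid, aliquots) is not modeled; supernatant concentrations
  are theoretical.
- NPOC-mode measurement, detector physics, AF4 channel hydrodynamics and
  particle-counter optics are not modeled; fraction masses and number
  concentrations are inputs, not computed from raw signals.
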