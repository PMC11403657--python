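# Methods

## Scope and model

`memcurv` implements the analysis chain from bilayer lateral-stress
profiles to synthetic-cell division predictions. It does **not** run or
post-process molecular dynamics itself: the per-slab local stress tensor is
taken as input (the output of stress-decomposition tools), and the bending
rigidity κ is an input parameter, not estimated here.

The elastic model is the standard spontaneous-curvature description of an
asymmetric membrane. Its key relations, in the order the pipeline applies
them:

- **First moment.** 2κm = −∫ z·s(z) dz with s(z) = (σxx + σyy)/2 − σzz,
  z = 0 at the bilayer midplane and the exterior solution at positive z.
  The sign is chosen so that a bulky inclusion in the *upper* (exterior-
  facing) leaflet — which physically makes the membrane bulge away from
  the inclusion, i.e. toward the interior — yields negative m, and bulging
  toward the exterior yields positive m. Data recorded under the opposite
  convention can be handled either by `set_orientation(...,
  exterior_at_positive_z=False)` (grid reflection) or by the `moment_sign`
  switch on the estimator.
- **Coverage calibration.** 2κm(ϕ) = slope·ϕ with zero intercept: an
  uncovered membrane is symmetric and has no spontaneous curvature, so the
  fit is forced through the origin. m₀ = slope/(2κ) is the curvature per
  unit coverage; |1/m₀| the local curvature radius.
- **Adsorption.** Langmuir isotherm θ(c) = c/(c + K_d) with saturation
  coverage ϕ_sat = x_anchor·a_pep/a_lip (one peptide per anchor lipid).
  This is a dilute-regime model; `area_fraction` refuses ϕ ≥ 1, and
  `BindingModel` refuses configurations with ϕ_sat ≥ 1.
- **Dumbbell geometry.** A vesicle of membrane area A = 4πR_ves² and
  reduced volume v = V/((4π/3)R_ves³) in (1/√2, 1) has a unique two-sphere
  dumbbell: r₁² + r₂² = 1 and r₁³ + r₂³ = v in units of R_ves. With
  r₁ = √(1 − r₂²) the volume equation is strictly monotone in r₂ on
  (0, 1/√2], so the root is bracketed and unique. Neck curvature
  M_ne = (1/R₁ + 1/R₂)/2; the closed neck is stable for m ≥ M_ne, which
  defines the dumbbell threshold m\*.
- **Constriction force.** f = 8πκ(m − M_ne), reported in pN via kB·T.
  This closed form is isolated in `constriction_force` as the single place
  to change if a different neck-force expression is preferred.

## Parameters, units, defaults

| Parameter | Unit | Default | Meaning |
| --- | --- | --- | --- |
| stress s(z) | bar | input | lateral stress per slab |
| z grid | nm | input | uniform, ≥ 8 slabs; non-uniform grids are rejected, never resampled |
| T | K | 303.15 | temperature for kBT conversions (simulation temperature of the source data) |
| κ | kBT | 25.2 | bending rigidity (literature value for POPC-class bilayers) |
| K_d | nM | 18.5 | His-peptide / NTA-anchor dissociation constant |
| x_anchor | — | 0.03 | anchor-lipid mole fraction |
| a_lip | nm² | 0.64 | area per lipid |
| a_pep | nm² | π | bound-peptide footprint (disk of 1 nm radius) |
| v | — | 0.8 | reduced volume of the deflated vesicle |
| R_ves | μm | 0.5 / 10 | studied vesicle sizes (cell-sized) |
| f_target | pN | 20 | reference force for the fission-favored regime, the scale of observed spontaneous neck fission |
| tension tolerance | bar·nm | 1.0 | residual-tension warning threshold (warning, not error: finite sampling leaves residual tension) |

Unit conversions are computed from scipy.constants at run time:
1 bar·nm² = 1e−22 J/nm ≈ 0.023893 kBT/nm and 1 kBT/nm ≈ 4.185 pN at
303.15 K.

The peptide footprint in `area_fraction` is a disk of **diameter** equal to
the mean end-to-end distance (the anchored complex rotates freely, so the
covered area is circular); callers needing a different radius convention
can scale `ree` accordingly.

## Numerical choices

- **Quadrature:** trapezoidal rule on the native grid, no interpolation.
  For membrane-like profiles (features of width ≳ 0.5 nm resolved by
  ≲ 0.1 nm slabs, decaying well inside the box) this agrees with adaptive
  quadrature to better than 1e−6 relative; profiles whose features do not
  decay by the box edge incur ordinary boundary (Euler–Maclaurin) error.
- **Blocking plateau rule:** at each level k, s_k = √(var_k/(n_k − 1)) with
  one-sigma uncertainty s_k/√(2(n_k − 1)); the reported SEM is the first
  level whose estimate is within its own one sigma of the next level's.
  If no plateau occurs before fewer than 4 blocks remain, the maximum
  across levels is returned with `plateau_found=False` (a conservative
  upper estimate). Odd-length levels drop their last element before
  pairing.
- **Origin fit:** weights 1/sem² when every point has a positive SEM,
  uniform when all SEMs are zero; mixing is rejected rather than guessed.
  Weighted slope error is √(1/Σwx²) (exact under the stated noise model);
  the unweighted error uses the residual variance.
- **Root finding:** dumbbell radii and concentration thresholds use
  bracketed Brent iteration (deterministic; residuals < 1e−10 for the
  geometry, relative tolerance 1e−9 for concentrations). The threshold
  ratio across vesicle sizes is exact up to one ulp — the reduced geometry
  is solved once per v and only the 1/R_ves prefactor differs.
- **Degenerate inputs:** a calibration slope whose inner-leaflet curvature
  is non-positive everywhere yields a prediction with `status` explaining
  why no threshold exists, not an exception; all-zero coverages make the
  origin fit unidentifiable and raise; profiles must be centered and
  oriented before moments are taken (state errors otherwise).

## Synthetic data: what it does and does not emulate

`make_profile_ensemble` builds a mean profile from two repulsive headgroup
peaks (±2 nm, width 0.5 nm, ~100 bar) and a central attractive trough,
rebalanced on the discrete grid so the zeroth moment (tension) is exactly
zero, plus an antisymmetric component c·z·exp(−z²/(2w²)) scaled so the
first moment ∫z·s dz equals the requested value exactly on the grid.
Per-frame noise is white Gaussian per slab. This reproduces the *scales*
and the two planted invariants (tension, first moment) of real
coarse-grained bilayer profiles — which is what the estimator tests need —
but none of the molecular structure: no correlated noise across slabs, no
asymmetric ionic contributions, no peptide density profile. Passing tests
therefore demonstrate correctness of the estimators and calibrations, not
fidelity of any particular force field.

`make_ar1_series` provides stationary lag-1 autocorrelated series for the
blocking analysis (marginal sd exact by construction); real moment series
may mix several correlation times, for which blocking remains consistent
but plateaus later. `make_coverage_dataset` draws y = slope·ϕ + N(0, sem²)
with heteroscedastic sems, matching the weighted-fit noise model.

Problem sizes used by the test suite and the acceptance script (400-frame
ensembles, 100–500 replicate seeds, 4096/65536-sample series) are chosen so
each statistical check resolves its tolerance with comfortable margin while
the whole suite runs in seconds to minutes on one core.

## Known limitations

- Only the two-sphere closed-neck limit of vesicle shapes is modeled; no
  axisymmetric shape equations, energy landscapes, or prolate branches.
- κ is assumed composition-independent along a calibration series, though
  charged lipids are known to change rigidity; only the sign of m is
  robust to that caveat.
- The Langmuir model ignores peptide–peptide interactions (dilute regime)
  and pH-dependent charge/anchoring changes.
- Ionic-asymmetry contributions to the measured moment are not separated
  from the peptide contribution; the calibration slope absorbs both.
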