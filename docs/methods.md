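# Methods

## The mechanical model

At the instant of maximal deformation under an air puff, the cornea is
treated as a static, thin, homogeneous, isotropic spherical shell of radius
*R* and uniform thickness *t*, clamped at the limbus (the equator of the
hemisphere) and filled with an incompressible fluid at the intraocular
pressure *p*. Inertia is neglected: at peak deflection the apex velocity is
zero, so the frozen snapshot is an equilibrium problem. The deformed shape
is described by a small set of generalised coordinates (a Rayleigh–Ritz
ansatz) rather than a full field solution:

1. **Dimple inversion.** The apex cap inside polar angle α is mirror-imaged
   through the plane of the ridge circle. The apex travels
   Δ₁ = 2R(1 − cos α) and the enclosed volume changes by ΔV₁, equal to
   minus twice the spherical-cap volume of depth Δ₁/2; in closed form
   ΔV₁ = −πRΔ₁²(6 − Δ₁/R)/12.
2. **Membrane strain.** The inverted cap and the outer shell carry uniform
   equibiaxial strains w̄ᵢ and w̄ₒ (radial displacement over *R*). These
   move the apex by Δ₂ = R(w̄ᵢ(1 − cos α) − w̄ₒ cos α) and change the volume
   by ΔV₂ = −2πR²Δ₂(1 − cos α) (cap sweep) and ΔV₃ = 2πR³w̄ₒ cos α (outer
   swelling). The stretch energy is
   U_S = 2πEtR²/(1 − ν) · (w̄ᵢ²(1 − cos α) + w̄ₒ² cos α).
3. **Edge bending.** Narrow boundary-layer zones at the dimple ridge and at
   the clamped limbus store bending energy and add the apex travel
   Δ₄ = −R(λ√2/4)w̄ₒ², with ΔV₄ = −2πR²Δ₄(1 − cos α).

Equilibrium is the stationary point of
Π = U_S + U_B + U_P + U_pr, with U_P = −P(Δ₁ + Δ₂ + Δ₄) the puff-force work
and U_pr = −p·ΣΔVᵢ the pressure work.

## The edge-bending energy

U_B is built from the classical influence coefficients of a spherical-shell
edge. With the edge-zone parameter μ = (3(1 − ν²))^¼ √(R/t) (equivalently
μ² = λ/2, where λ = R/c and c = t/√(12(1 − ν²))), an edge at polar angle
φₑ loaded by a horizontal force H and meridional moment M (per unit length)
displaces by

    h   = (2μR sin²φₑ · H + 2μ² sin φₑ · M)/(Et),
    χ   = (2μ² sin φₑ · H + 4μ³/R · M)/(Et).

Inverting this compliance gives an edge stiffness. Two mismatches drive the
edges:

* at the **ridge**, the mirror inversion kinks the meridian by 2α and the
  strained cap/shell edges differ horizontally by R sin α (w̄ₒ − w̄ᵢ); the
  two edge zones (cap side at φₑ = α, shell side at φₑ = π − α) act as
  springs in series and share the mismatch equally;
* at the **limbus** (φₑ = π/2), the clamp suppresses the membrane edge
  displacement Rw̄ₒ.

Carrying this through gives, with Δw̄ = w̄ₒ − w̄ᵢ,

    U_B = (πEtR² sin α / 2) [ √(2/λ)·Δw̄² − (4α/λ)·Δw̄ + 2(2/λ)^{3/2}·α² ]
        +  πEtR² √(2/λ) · w̄ₒ² .

The constant term is the inversion-ridge energy (∝ t^{5/2}, the familiar
boundary-layer scaling); the linear term couples the kink to the strain
mismatch. U_B is exactly quadratic in the strains and linear in *E*. A
cross-check test differentiates an independent symbolic transcription of Π
and verifies it reproduces the assembled system — the √(2λ)/(1 − ν)
diagonal families, the −½ off-diagonal coupling, equal-and-opposite ridge
forcing in the two equations, and pressure forcing confined to the
outer-shell equation.

The sign convention of the ridge force/rotation pairing was fixed by
requiring the physical strain pattern (inverted cap compressed, outer shell
swollen) at clinical loads; the tests assert that pattern.

## Load models and the reduced equilibrium

**Default (`iop_normalized`).** The measured IOP enters as
p̄ = pR²/(Et²) and the puff force is tied to it by the small-deformation
force balance P̄ = 2π(1 − cos α)p̄ (P̄ = P/(Et²)). Under that tie, the load
work cancels exactly from the cap-strain equation, the quadratic Δ₄/ΔV₄
work terms cancel between U_P and U_pr, and stationarity of Π reduces to a
symmetric positive-definite linear 2×2 system

    [ ½ + G(1−cos α)/sin α      −½                      ] [w̄ᵢ]   [ −α/√(2λ) ]
    [ −½                        ½ + 1/sin α + G cot α   ] [w̄ₒ] = [ +α/√(2λ) + (t/c)·cot α·p̄/√(2λ) ]

with G = √(2λ)/(1 − ν). The solver is a damped Newton iteration (initial
strains zero, step halving on residual growth, scaled residual tolerance
10⁻¹⁰, 200-iteration cap); on this linear system it converges in one full
step, and the damping machinery serves the nonlinear variant below. All
normalised outputs depend only on (λ, α, ν, p̄), which a test verifies by
joint rescaling of (R, t).

**Volume-conserving variant.** For sensitivity studies the pressure can be
treated as unknown: the puff force is computed from the jet parameters
(60 mmHg peak over (2/3)² of the dimple chord area πR² sin²α) and
(w̄ᵢ, w̄ₒ, p̄) solve the two stationarity conditions plus exact conservation
of the enclosed fluid volume, which is nonlinear through the w̄ₒ² term of
ΔV₄. This variant is dominated by the requirement that the outer swelling
re-absorb the dimple volume; it is not the clinical default.

A 5×5 assembly of the equilibrium with the ridge rotation/translation
unknowns (y₃, y₄) kept symbolic is provided for inspection; its
edge-unknown rows are proportional to the force imbalance
P* = P̄/2π − (1 − cos α)p̄ and vanish under the tie, which is what makes
y₃ = y₄ = 0 self-consistent. The coupled 5-unknown solve is experimental
and not used on the estimation path.

## Monotonicity and the inverse problem

Increasing p̄ swells the outer shell; the ridge circle rides outward/upward
and the apex deflection Δ *decreases*. Conversely Δ is strictly increasing
in *E* at fixed IOP, approaching (from below) the E-independent
zero-pressure equilibrium just under Δ₁ — the ridge kink strains the shell
by pure geometry, so Δ₁ is a strict upper bound but not the stiff limit.
Strict monotonicity makes the inverse problem well-posed: the estimator
brackets the root of Δ(E) = δ in log E over [0.01, 10] MPa (Brent's
method, with a bounded SQP-style minimisation of |Δ − δ| as fallback). A
measured deflection outside the reachable range pins the estimate at the
nearer bound with `converged=False`. Convergence requires a residual below
10⁻⁴ mm, far under the 0.034 mm imaging floor.

The effective-modulus correction E′ = E + T with T = pR/(2t) accounts for
pressure-induced tension stiffening; at p = 15 mmHg, R = 0.7 cm,
t = 550 µm it contributes T ≈ 0.013 MPa.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| ν | 0.49 | – | nearly incompressible stroma |
| puff pressure | 60 | mmHg | device jet peak |
| area factor | (2/3)² | – | nonuniform jet over the chord disc |
| mmHg → Pa | 133.322 | Pa/mmHg | standard conversion |
| pixel | 0.017 | mm | Scheimpflug pixel pitch; 2 px = 0.034 mm floor |
| E bounds | [0.01, 10] | MPa | spans the reported in-vivo/in-vitro range |
| residual tol | 10⁻⁴ | mm | ≪ imaging floor |
| α guard | 10⁻³ | rad | cot α singularity of the edge terms |
| Δ₄ form | λ-scaled | – | boundary-layer scaling; an unscaled variant is a config switch for sensitivity |

Construction warns (never errors) when t/R ≥ 5% — true of typical corneas,
where membrane theory is stretched but serviceable — and when the ridge
kink 2α reaches π/3, beyond which the neglected higher-order bending grows.

## Synthetic data

No measurement data ship with the package; the generator replaces the
cohort.

**Profiles.** The undeformed surface is a circular arc; the deformed one
subtracts a dimple shaped like the scaled mirror inversion with apex depth
given by the forward model, vanishing exactly at the ridge. The sampling
grid contains the apex and ridge abscissae, so noise-free extraction
round-trips (R, α, δ) to 10⁻⁶; pixel quantisation (nearest multiple, ties
away from zero, one sample per pixel column) degrades δ by at most
0.034 mm.

**Cohorts.** Covariates are truncated Gaussians — age 35 ± 15 y (≥ 5), CCT
543 ± 38 µm, R 7.17 ± 1.25 mm, E 0.208 ± 0.079 MPa (spreads converted from
95% bands via sd = width/3.92) — and IOP follows the linear model
−8.106 + 0.034·age + 0.036·CCT + 8.922·E plus a residual of sd 3.18 mmHg,
chosen so the generated IOP spread matches a healthy cohort's (≈ 3.6 mmHg).
Each record's deflection is computed by the forward model, so records are
exactly self-consistent.

Validity screening is deliberately covariate-only: IOP residuals are drawn
symmetrically truncated at 2 sd, and a covariate draw is redrawn whenever
the deflection at the *worst-case* IOP (prediction + 2 sd) would fall below
0.02 mm. Because the rule never inspects the realised residual, the
conditional mean of IOP given the covariates — and therefore every
generating regression coefficient — is preserved exactly, while
monotonicity in IOP guarantees the realised record is valid. The cost is a
trimmed soft tail: the model cannot produce positive deflections below
roughly 0.08 MPa at typical IOP and α = π/6, so the generated modulus mean
sits ≈ 0.008 MPa above the nominal 0.208.

What the generator does *not* emulate: dynamic waveform parameters
(applanation times/velocities, peak distance), between-covariate
correlations, eye motion, segmentation noise beyond pixel quantisation, or
left/right-eye pairing. Passing tests therefore demonstrate internal
consistency of model, extractor, estimator and statistics under the stated
distributions — not agreement with any particular device's raw output.

## Statistics

Pearson correlations use exact two-tailed p-values, reported raw (no
multiplicity correction, matching common cohort-report practice); constant
columns yield flagged-undefined (NaN) entries. The age-group ANOVA uses the
conventional 0–14 / 15–64 / >64 bins. The IOP regression is ordinary least
squares on the fixed covariate triple (age, CCT, E) — a deliberate
replacement for software-specific stepwise selection, whose dialect varies;
the three covariates are the accepted final model. Per-covariate explained
proportions are reported in both the marginal (covariate alone) and
sequential (order-of-entry increments) conventions, since reports rarely
state which they mean; the sequential increments sum to the full-model
pseudo-R² = 1 − RSS/TSS.

## Numerical choices

- Internal mechanics in SI (m, Pa, N, J); boundary I/O in clinical units
  (mm, µm, mmHg, MPa); energies reported in µJ.
- Pixel snapping rounds the coordinate/pixel ratio to 10⁻¹² before the
  tie-away rule so decimal ties survive binary representation.
- Dimple-edge detection: depth > 1 pixel delimits the candidate region;
  each edge is then refined to the interpolated zero crossing of the depth,
  which is exact when a sample sits on the ridge.
- Apex: extremal y within |x| < 1 mm (robust to edge noise).
- The acceptance script uses 600 records for the cohort-mean modulus and
  40 000 for the regression refit — sizes chosen so Monte-Carlo error is
  well below the quantities' own scale while the whole run stays at a few
  seconds.

## Known limitations

- Elastic, isotropic, uniform-thickness, static: no viscoelasticity,
  corneal anisotropy (fibre families), thickness maps or dynamics.
- The quadratic edge-bending energy is leading-order; higher-order
  (cubic-in-strain) edge terms are omitted, an effect estimated at a few
  per cent of the strain corrections at clinical parameters and growing
  with the ridge kink (hence the 2α ≥ π/3 warning).
- Very soft corneas (E ≲ 0.08 MPa at typical IOP and α = π/6) fall outside
  the model's reachable deflection range; the estimator reports a pinned,
  non-converged result there rather than extrapolating.
- The dimple half-angle delimitation on real images is a stand-in rule
  (depth-threshold plus zero-crossing); devices do not document theirs.
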