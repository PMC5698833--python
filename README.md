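# corneashell

Estimation of the corneal Young's modulus *in vivo* from noncontact
(air-puff) tonometry geometry, for ophthalmic-biomechanics researchers and
for anyone who needs an IOP reading corrected for corneal stiffness.

Air-puff tonometers such as the Corvis ST push the cornea through a concave
"dimple" state and image the deformation with high-speed Scheimpflug
photography. The instruments report device-specific indices (deformation
amplitude, applanation times, ...) that entangle geometry, pressure and
material. This package instead extracts the one quantity a mechanician
wants — the Young's modulus *E* — by fitting a mechanical model of the
deformed cornea to the imaged geometry.

## Model

The cornea is a thin fluid-filled hemispherical shell (radius *R*,
thickness *t* = CCT, Poisson's ratio ν = 0.49) clamped at the limbus, whose
apex region is mirror-inverted inside the polar angle α at maximal
deformation. The apex deflection decomposes as

    Δ = Δ₁ + Δ₂ + Δ₄

with the rigid inversion travel Δ₁ = 2R(1 − cos α), the membrane-strain
correction Δ₂ = R(w̄ᵢ(1 − cos α) − w̄ₒ cos α) and a quadratic edge-bending
correction Δ₄ ∝ −R λ w̄ₒ². The normalised strains w̄ᵢ (inverted cap) and w̄ₒ
(outer shell) solve a symmetric 2×2 equilibrium obtained by stationarity of
the total potential Π = U_S + U_B + U_P + U_pr (membrane stretch, edge
bending, puff-force work, pressure work), driven by the normalised pressure
p̄ = pR²/(Et²) with p the measured IOP. λ = R/c and c = t/√(12(1 − ν²)) are
the shell slenderness and bending length. Δ(E) is strictly monotone, so
matching the model deflection to the measured deflection δ by bounded root
bracketing (with an SQP fallback) identifies *E* uniquely. The
pressure-stiffening (Rayleigh) correction E′ = E + pR/2t is reported
alongside.

Inputs per eye: IOP (mmHg), R (mm), CCT (µm), maximal deflection δ (mm) and
dimple half-angle α (rad) — all derivable from two anterior-surface
profiles via `extract_measurement`.

## Worked example

```python
import math
import corneashell as cs

geom = cs.CornealGeometry.from_clinical(R_mm=7.17, cct_um=543.1,
                                        alpha_rad=math.pi / 6)

# forward: deflection of a 0.207 MPa cornea at 14.73 mmHg
delta = cs.forward_deflection(geom, 0.207, 14.73 * cs.MMHG_TO_PA)
print(delta)            # 1.6215440452141294  (mm)

# inverse: modulus of an eye whose measured deflection was 1.55 mm
rec = cs.MeasurementRecord(iop=14.73, R=7.17, cct=543.1,
                           delta=1.55, alpha=math.pi / 6, id="eye-001")
print(cs.estimate_modulus(rec))
# ModulusEstimate(E=0.1744444663577327, T=0.012963250819554411,
#                 E_eff=0.1874077171772871, residual=0.0, n_iter=14,
#                 converged=True, id='eye-001')
```

The forward call says a cornea of modulus 0.207 MPa deflects 1.62 mm under
this IOP and geometry; the inverse call reads a measured 1.55 mm deflection
back into a modulus of 0.174 MPa, to which the IOP adds an effective
pressure-stiffening term T ≈ 0.013 MPa. A smaller measured deflection (at
fixed α) means a softer cornea: the pressurised outer shell swells more and
lifts the dimple ridge.

The same pipeline is scriptable from the shell:

```sh
corneashell forward -R 7.17 --cct-um 543.1 --alpha-rad 0.5236 -E 0.207 -p 14.73
corneashell simulate-cohort --n 100 --seed 1 --out cohort.csv
corneashell estimate cohort.csv --out results.json
corneashell stats cohort.csv --out stats.json
```

## Layout

- `corneashell.core_model` — shell mechanics: deflection/volume components,
  energies, reduced and volume-conserving equilibria, forward deflection.
- `corneashell.geometry` — profile handling: circle fit, dimple extraction,
  pixel quantisation, puff force.
- `corneashell.estimator` — inverse modulus solve and the Rayleigh
  effective-modulus correction.
- `corneashell.synthetic_data` — profile and cohort generators.
- `corneashell.stats` — Pearson matrix, age-group ANOVA, IOP regression and
  pseudo-R².
- `corneashell.cli` — the `corneashell` command.

See `docs/methods.md` for the model derivation, parameter defaults and
known limitations.
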