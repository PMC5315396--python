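# Methods

`aawall` simulates the formation and growth of an abdominal aortic aneurysm
(AAA) as the interaction of two subsystems on a 2D section of the arterial
wall:

1. a **biological network** of 12 fields — MCP-1 (P), macrophages (M), Th1
   cells (T), smooth muscle cells (S, media only), IL-6, IL-10, IL-12,
   TNF-α, IFN-γ, MMP (Q), TIMP (Q_r) and extracellular matrix (ρ) — obeying
   reaction–advection–diffusion equations in the media Ω_M and adventitia
   Ω_A, with Robin exchange against the blood on the lumen boundary Γ_B and
   the outer boundary Γ_A, and Robin transmission across the interlayer
   membrane Γ_M;
2. a **hyperelastic solid** with energy density
   W = β₁(I_B − 3) + β₂(I_B − 3)², Cauchy stress
   σ = −p(ρ) I + (2β₁ + 4β₂(I_B − 3)) B, whose moduli degrade affinely with
   SMC loss, β_i(S) = β_i0 + k_i (S/S₀ − 1), and whose hydrostatic pressure
   follows the ECM, p(ρ) = p* − β_p (1 − ρ/ρ*).

The clinical question it encodes: given the lumen diameter R₀ and the
serum IL-6 concentration I₆₀ at screening, predict R(t).

## Model assumptions

- All cells share one velocity field **v** (the wall's material velocity);
  cytokines diffuse fast enough that their advection is negligible, but for
  uniformity every species is advanced with the same moving-mesh material
  derivative plus a (∇·v)Z compressibility term.
- Macrophages chemotax up MCP-1 and IL-6 gradients with a single
  coefficient χ_C (flux M χ_C ∇(P + I₆)), lagged explicitly in time.
- M1/M2 macrophage phenotypes are not distinguished; IL-10 inhibition of
  IL-12/TNF-α production stands in for the M2 arm.
- Fibroblasts are a constant background: their collagen production enters
  as a constant ECM source λ_ρf active only in the adventitia (χ_A = 1).
- The wall is in quasi-static equilibrium (no inertia, no body force):
  ∇·σ = 0 with blood traction σn = −p_B n − γκn on Γ_B, traction-free Γ_A,
  a surface-tension jump γκn across Γ_M, and displacement clamped on the
  artificial cuts Γ₀ (y = y₁, y₂). Species transport is periodic in y
  across the cuts.
- Plane strain with unit out-of-plane stretch: I_B = tr(B₂ᴅ) + 1, so the
  (I_B − 3) terms vanish in the reference state.

## Interpretation choices the source left open

These were decided once, before any endpoint was measured, and are all
ordinary config keys:

- **Boundary/interface flux coefficients act as exchange velocities.** The
  weak forms pair ⟨α(Z₀ − Z), W⟩ and ⟨γ(Z_A − Z_M), W⟩ directly with the
  tabled coefficients (α = 0.2, γ = 50 for cells, 500 for cytokines).
  Multiplying them by the species diffusivity instead (the literal reading
  of ∂Z/∂n + α(Z−Z₀) = 0) would scale macrophage influx by D_M ≈ 1e-6 and
  no inflammation would ever develop.
- **Moduli in the adventitia.** β_i(S) is defined through S, which exists
  only in the media; the adventitia keeps the healthy baseline (β₁₀, β₂₀).
- **Missing constants.** d_T = 0.197/day (T-cell death), λ_MTα = 1
  (dimensionless TNF-α enhancement of macrophage activation), D_ρ =
  8.64e-7 cm²/day (ECM quasi-immobile), γ_surf = 1e-2 N/cm (surface
  tension). λ_S = d_S·S₀ closes the SMC source so healthy tissue is
  stationary. ρ* = 3.43e-4 g/cm³ (the initial ECM density) in the pressure
  law, distinct from the saturation ρ₀ = 1e-3.
- **Geometry.** The three cosine profiles (x = 0.5cos(πy)/2,
  0.55cos(πy)/2 + 0.2, 0.7cos(πy)/2 + 0.3 on y ∈ [−1, 1]) are scaled
  uniformly so the measured initial lumen diameter — twice the maximal
  horizontal distance from the centerline to Γ_B — equals R₀; the
  centerline offset is −0.75 in profile units.
- **Elastic residual.** The equilibrium residual is the gradient of the
  potential ∫ W − p(J − 1) dΩ̂ with p frozen, i.e. first Piola stress
  P = −pJF^{-T} + (2β₁ + 4β₂(I_B − 3))F. This is the variationally
  consistent form; it agrees with the Piola transform of the pointwise
  Cauchy law up to the near-unity factor J on the elastic part. A config
  switch (`full_stress_coefficient=False`) halves the elastic coefficient,
  reproducing the alternative coefficient some formulations print for the
  pulled-back stress.

## Numerical scheme

Total-Lagrangian, decoupled stepping with k = 0.5 day by default:

1. **Newton solve** of the nonlinear equilibrium on the *reference* mesh
   with β_i(Ŝⁿ⁻¹), p(ρ̂ⁿ⁻¹) frozen per element (explicit coefficients).
   Analytic consistent tangent, including the follower blood-pressure load
   (linear in current positions, hence exact) and the surface-tension
   Hessian (γ/L (I − t̂t̂ᵀ) edge springs). Backtracking line search;
   tolerance 1e-10 relative / 1e-12 absolute; failure → time-step halving
   (≤ 5 levels).
2. **Mesh motion** by the flow map x = x̂ + ûⁿ; discrete velocity
   v̂ⁿ = (ûⁿ − ûⁿ⁻¹)/k; element inversion rejected.
3. **Species update** on the moved mesh: P1 Galerkin with implicit
   diffusion, implicit (∇·v)Z, implicit Robin terms, and the reaction
   split F = prod − loss·Z with productions and the nonlinear loss
   coefficients lagged one step, each species' media/adventitia pair solved
   as one coupled sparse system. The split is exact at a single state and
   makes the stiff linear decays (d_Tα = 55.45/day) unconditionally
   stable. ECM is one continuous field on the merged mesh; SMCs live on
   the media mesh with natural no-flux conditions. Chemotaxis enters the
   macrophage right-hand side explicitly. Nodal undershoots (possible for
   P1 transport with chemotaxis at under-resolved boundary layers) are
   clamped to zero and the clamped mass fraction logged.

Because mesh nodes follow the material, the discrete material derivative
needs no interpolation. Surface tension uses the exact discrete variation
of γ×(current boundary length), which is the pulled-back curvature
traction for piecewise-linear boundaries; the standalone curvature
diagnostic uses the circumscribed-circle formula (exact on circles).

At t = 0 the reference section carries residual stress (p(ρ_init) ≠ 2β₁ in
general), so a pre-step equilibrium solve defines the initial state and
the reference geometry is rescaled (two passes) so the equilibrated
diameter equals R₀.

The constitutive energy is non-convex in compression (W′ < 0 for
I_B − 3 < −β₁/(2β₂) ≈ −0.046): equilibria are only meaningful on the
pre-tensioned branch, which the p* calibration (p* ≈ 2β₁₀) keeps the wall
on. The verification tests therefore manufacture solutions around a
stretched base state.

## Problem sizes

Default ("coarse") desk-scale discretization: target element size 0.05 cm
giving a 41×5 media grid and 41×3 adventitia grid (287 merged nodes,
480 triangles), k = 0.5 day, 1000 steps to day 500 (≈ 1 minute on one
CPU). The verification suite uses smaller meshes and shorter horizons
chosen per test; the convergence studies state their own ladders.

## What the generated conditions do and do not emulate

All inputs are generated programmatically (no external data): the cosine
bulge geometry, the healthy initial state (S = S₀, ρ = 3.43e-4, Q = 3e-8,
Q_r = 1e-8, I₆ = I₆₀/2, all immune fields zero), and the serum boundary
levels. Real AAA walls differ in ways the model does not attempt to
capture: anisotropic collagen fiber families, residual opening-angle
stress, 3D geometry, hemodynamic shear coupling, and patient-specific
parameter spread. Passing tests therefore demonstrate internal
correctness of the stated model, not clinical validity.

## Known limitations and reproduction gaps

Faithful implementation of the printed equations and constants does not
reproduce two headline behaviors reported for this model, and the package
deliberately leaves the discrepancy visible rather than re-tuning:

- **Diameter endpoints.** The simulated R(500) from R₀ = 2 cm is
  ≈ 2.005 cm for both I₆₀ = 6e-9 and 6e-8 g/ml (reported: 2.5 and
  4.5 cm). Two structural reasons: (i) the quadratic modulus
  β₂ ≥ 104 N/cm² over the whole admissible SMC range re-stiffens the wall
  at ~2% strain against a 1.47 N/cm² blood pressure — even imposing the
  maximal admissible degradation uniformly (S = 0.45 S₀, ρ = 0.5 ρ*)
  yields only R = 2.057 cm, and lower S makes β₁ ≤ 0, which aborts the run
  by contract; (ii) with D_M = 8.64e-7 cm²/day and d_M = 0.015/day,
  macrophage invasion is confined to a √(D/d) ≈ 76 µm boundary layer of
  the ≈ 4 mm wall, so bulk SMC loss cannot develop. R(T) is still strictly
  increasing in I₆₀ and R₀, so the qualitative response structure of the
  prediction maps survives at much smaller amplitude.
- **MMP/TIMP time courses.** Under the tabled rates the TIMP pool
  collapses from 1e-8 within hours (d_Qr = 21.6/day against a production
  of ~3e-9/day) and then grows only marginally, and MMP has no interior
  maximum (its production tracks λ_QS·S, which falls as S halves, while
  the TNF-α enhancement is inert because attainable TNF-α ≈ 2.5e-9 g/cm³
  is far below K_Tα = 5e-7). The well-mixed disease course otherwise
  reproduces the expected directions: S and ρ fall; MCP-1, TNF-α, IFN-γ
  rise.

Sensitivity to the assumed surface tension γ_surf = 1e-2 N/cm is
negligible at these deformations: the curvature traction scale γ/R ≈
5e-3 N/cm² sits three orders of magnitude below the blood pressure.
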