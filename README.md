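# aawall

Coupled biological–mechanical simulation of abdominal aortic aneurysm
(AAA) growth on a 2D section of the arterial wall.

AAA is a localized dilation of the infrarenal aorta whose only clinically
established risk marker is the diameter itself; serum IL-6 has been
proposed as a complementary biomarker. `aawall` implements a mechanistic
model connecting the two: a 12-species cytokine/immune-cell
reaction–advection–diffusion network (MCP-1, macrophages, Th1 cells,
SMCs, IL-6/-10/-12, TNF-α, IFN-γ, MMP, TIMP, ECM) in the two wall layers
(media Ω_M, adventitia Ω_A), coupled to a hyperelastic solid

```
W(I_B) = β₁ (I_B − 3) + β₂ (I_B − 3)²,        σ = −p(ρ) I + (2β₁ + 4β₂(I_B − 3)) B,
β_i(S) = β_i0 + k_i (S/S₀ − 1),               p(ρ) = p* − β_p (1 − ρ/ρ*),
```

so that macrophage-driven smooth-muscle-cell (S) apoptosis softens the
wall and MMP-driven matrix (ρ) loss lowers its internal pressure. The
equilibrium ∇·σ = 0 with blood traction −p_B n and surface tension γκn is
solved by Newton iteration in the reference frame; the mesh moves with the
tissue (total-Lagrangian, moving-mesh P1 finite elements) and the species
are advanced implicitly on the moved mesh. Given an initial lumen diameter
R₀ and serum IL-6 level I₆₀, the tool returns the diameter history R(t).

It is intended for modelers studying inflammation-driven vessel-wall
remodeling: every constant is a config key with provenance tracking, and
a well-mixed two-compartment ODE reduction is included for fast kinetic
analysis.

## Worked example

```bash
aawall check-params
```

recomputes the literature-derived constants and prints

```
lam_I6M        computed 1.73e-06  expected 1.73e-06  [ok]
lam_I6S        computed 1.73e-05  expected 1.73e-05  [ok]
k_1            computed 30.4  expected 30.4  [ok]
k_2            computed 84  expected 84  [ok]
p_star         computed 37  expected 37  [ok]
beta_p         computed 18  expected 18  [ok]
lam_S          computed 0.00516  expected 0.00516  [ok]
p_B_N_per_cm2  computed 1.46654  expected 1.46654  [ok]
```

— e.g. `lam_I6M` is the macrophage IL-6 production rate from the
steady-state balance λ·M = d_I6·I₆ of a culture assay (10⁶ cells/ml
producing 10 ng/ml), and `k_1` the modulus-degradation slope solving
β₁ = β₁₀ − k₁/2 at the diseased state S = S₀/2.

A full coupled run (≈ 1 minute on one CPU at the default coarse
discretization):

```bash
aawall run --r0 2.0 --i60 6e-9 --t-end 500 --out out/
# -> final diameter R(500) = 2.0047 cm
```

`out/trajectory.csv` holds R(t) and the per-layer average of every
species; `out/mesh_*.vtk` are field snapshots; `out/params.json` records
every constant with default/override/assumed provenance. The printed
endpoint means: starting from a 2 cm vessel at the low end of the serum
IL-6 range, the simulated wall dilates by ≈ 0.005 cm in 500 days — the
inflammatory softening under the tabled constants is confined to a thin
layer near the lumen, so growth is slight (see `docs/methods.md` for the
quantitative analysis of this regime). The response is nonetheless
strictly monotone in both I₆₀ and R₀, which the prediction-map command
exposes:

```bash
aawall sweep --n-i60 5 --n-r0 5 --t-end 500 --out sweep/   # R(T) matrix + CSV
aawall wellmixed --t-end 500 --out wm.csv                  # ODE reduction
```

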