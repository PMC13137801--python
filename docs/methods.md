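# Methods

`ferropyro` models the physics chain behind NIR-driven pyro-catalytic
nanoparticles: ferroelectric thermodynamics → domain microstructure →
pyroelectric device response → redox feasibility of ROS generation. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic data does and does not emulate.

## Landau–Devonshire thermodynamics (`landau`, `materials`)

The bulk free-energy density is the cubic sextic expansion in the
polarization vector P (C/m²),

    f(P) = α₁ ΣPᵢ² + α₁₁ ΣPᵢ⁴ + α₁₂ Σ_{i<j} Pᵢ²Pⱼ²
         + α₁₁₁ ΣPᵢ⁶ + α₁₁₂ Σ Pᵢ⁴(Pⱼ²+Pₖ²) + α₁₂₃ P₁²P₂²P₃²   [J/m³],

with each coefficient linear in temperature, `α(T) = slope·(T − T_ref) +
offset`. Two materials ship as TOML configs: `btz` (the
Ba(Ti₀.₈₅Zr₀.₁₅)O₃ composition-specific set) and `bto` (the classic
Bell–Cross single-crystal BaTiO₃ parameterization, marked
literature-sourced in the file). Users can load further sets from TOML.

**Phase minima.** Along each high-symmetry line — tetragonal (0,0,p),
orthorhombic (p,p,0), rhombohedral (p,p,p) — the energy reduces to
`A p² + B p⁴ + C p⁶`, whose stationarity condition `A + 2Bu + 3Cu² = 0`
(u = p²) is a quadratic solved in closed form. Only roots with positive
on-line curvature (true local minima) are kept; among them the
lower-energy root wins, and a degenerate double root resolves toward the
larger |P| (the minimum branch when the quartic coefficient is negative).
A minimum with energy ≥ 0 is reported as paraelectric for
global-stability bookkeeping (`stable_phase_diagram`), but
`allow_metastable=True` returns it as a metastable minimum — this is what
`barrier_profile` uses, since rotation paths between metastable wells are
physically meaningful (the BTZ T-phase well already sits slightly above
zero at 298 K).

**Ps(T) and the pyroelectric coefficient.** `stable_phase_diagram`
evaluates the four candidate phases per temperature;
`pyroelectric_coefficient` applies central differences (one-sided at the
ends) on a uniform temperature grid and reports ρ = dPs/dT in
µC m⁻² K⁻¹. The signed derivative convention is kept (ρ < 0 approaching a
transition on heating); `magnitudes` serves |ρ| comparisons, and
`enhancement_percent` compares magnitudes. For the BTZ set the model's
ferroelectric→paraelectric transition falls at ≈ 301 K and |ρ| peaks
there; the model reproduces the *shape* of the composition-tuned
transition, not the experimental T_C (≈ 337 K), because the printed
coefficient set places the stability crossover lower.

**Rotation paths.** `barrier_profile` samples the bulk energy at ≥ 101
points on the straight segment between two phase minima (default), or on
a spherical-interpolation arc with linearly varying magnitude
(`path_mode="arc"`). It reports barrier heights (path maximum minus each
endpoint) and the inter-minimum gap in both J/m³ and J/cm³. Evaluating
the shipped coefficients in SI gives inter-phase gaps of order
0.03–0.14 J/cm³ at 293–298 K, shrinking monotonically on heating; note
that no ferroelectric stationary point of any phase survives above
≈ 298 K (T phase) / ≈ 301 K (O, R), so rotation-path analyses are
restricted to that window.

## TDGL phase-field solver (`tdgl`, `fields`)

The polarization field relaxes by ∂Pᵢ/∂t = −L δF/δPᵢ with
F = f_bulk + f_grad + f_elastic + f_elec on periodic 2-D/3-D grids
(2-D grids carry full 3-component vectors with ∂/∂z = 0, so all variant
families remain representable).

**Nondimensional time.** The kinetic coefficient L is folded into
t* = t·L·κ(T), where κ is 1.5× the largest linearized bulk stiffness
|d²f/dp²| over the phase minima and the origin at the working
temperature. With the bulk force treated explicitly, the linear-stability
limit in these units is O(1) regardless of temperature or material; the
documented safe bound is dt* < 0.5 and the default step is 0.05. Only t*
and step counts are exposed.

**Spectral scheme.** Each step applies one semi-implicit Fourier update:
the gradient operator — K_ii = G₁₁kᵢ² + 2G₄₄(k² − kᵢ²), K_ij = G₁₂kᵢkⱼ,
from f_grad = ½G₁₁Σ(Pᵢ,ᵢ)² + G₁₂Σ_{i<j}Pᵢ,ᵢPⱼ,ⱼ + G₄₄Σ_{i≠j}(Pᵢ,ⱼ)² —
and, when enabled, the longitudinal depolarization projector
n nᵀ/(ε₀ε_b) are inverted implicitly per wavevector (a 3×3 solve
precomputed once per `evolve` call); bulk, elastic, applied-field and
defect-field forces are explicit. Defaults: G₁₁₀ = 7.04×10⁻¹¹ C⁻²m⁴N with
ratios G₁₁/G₁₁₀ = 1.5, G₁₂/G₁₁₀ = 0, G₄₄/G₁₁₀ = 0.75; grid spacing 1 nm,
which resolves the ≈ 3.4 nm wall width √(G₁₁₀/|α₁|) at 273 K with a few
cells. Divergence (|P| above 10× the largest Landau minimum) raises an
error suggesting a smaller dt.

**Electrostatics.** f_elec = −E_appl·P − ½E_dep·P, the standard
applied-field work plus dipolar self-energy. The depolarization field is
the spectral bound-charge solution E_dep(k) = −n(n·P(k))/(ε₀ε_b) with
background permittivity ε_b = 50 by default; the k = 0 mode is zero
(periodic short-circuit), with an `open_circuit` flag that restores the
macroscopic −P̄/(ε₀ε_b). In 1-D this reduces to the closed form
E = −(P − ⟨P⟩)/(ε₀ε_b), which the tests check exactly.

**Elasticity.** Zero-mean-stress periodic microelasticity: the
electrostrictive eigenstrain ε⁰ᵢⱼ = QᵢⱼₖₗPₖPₗ (tensor shear convention
ε⁰ᵢⱼ = ½Q₄₄PᵢPⱼ for i ≠ j) drives a spectral eigenstrain solve with
homogeneous cubic stiffness obtained by inverting the configured
compliances; the homogeneous strain is set by the zero-mean-stress
condition, so a uniform field is exactly stress-free. A config switch
disables elasticity for oracle tests. Caveat: the default compliance set
(s₁₁ = 9.1×10⁻¹², s₁₂ = −3.2×10⁻¹⁰, s₄₄ = 8.2×10⁻¹⁰ m²/N) is *indefinite*
(s₁₁ + 2s₁₂ < 0, giving C₁₁ + 2C₁₂ < 0); the inversion is
well-conditioned and the acoustic tensor remains positive definite, so
the solver is stable in practice, but hydrostatic elastic energies can be
negative. The values are kept as configured rather than silently
corrected; the elastic term is a small perturbation next to the quartic/
sextic bulk terms at the polarizations reached here.

**Defect field.** Local structural heterogeneity enters as a static
random field E_RF: a fraction c = 0.05 of cells (chosen without
replacement) carries i.i.d. zero-mean Gaussian components of
σ_E = 5×10⁵ V/m. Both c and σ_E are config parameters and the field is
seeded. E_RF breaks the ±P symmetry of the dynamics — which is physical
(pinned nanodomains) — so symmetry-based solver checks (hysteresis
antisymmetry) run on defect-free configurations.

**Hysteresis protocol.** A triangular sweep 0 → +E_max → −E_max → +E_max;
at each field value the flow is equilibrated a fixed number of steps and
the spatial mean of the swept component recorded. Fixed-step
equilibration (rather than convergence detection) keeps runs
deterministic and costs predictable; near the coercive field the loop
therefore carries a small kinetic lag that shrinks with more
equilibration steps (≈ 0.5% branch asymmetry at 500 steps/field on the
grids used in the tests).

## Variant classification (`domains`)

The 26 polar variants (6 ⟨100⟩ T, 12 ⟨110⟩ O, 8 ⟨111⟩ R) are enumerated
in a canonical order — T block, then O, then R, each sorted
lexicographically by direction components — which fixes tie-breaking and
export codes (0 = paraelectric, 1–26 = variants). A cell is paraelectric
when |P| falls below the threshold, by default 5% of the largest
single-domain Ps at the state's temperature (separating polar-region
interiors from walls); otherwise it takes the nearest variant direction
by cosine. Wall cells inherit nearest-direction labels;
`angle_tolerance` is advisory metadata rather than a gate, since
nearest-direction assignment always succeeds.

## Photothermal cycling and device response (`photothermal`)

The suspension is a single thermal node with Newtonian exchange; each
laser on/off stage is an exact exponential segment with time constant
τ = C_eff/k_loss and on-stage steady state ambient + η·flux·A_abs/k_loss.
The default coefficients are *calibrated*, not fitted: the two observable
conditions {rise 10 K after 70 s on, decay to within 0.5 K of ambient
after 100 s off} determine τ = 100/ln(10/0.5) ≈ 33.4 s in closed form and
then k_loss from the absorbed power (1.0 W/cm² over a (3000 nm)² cross
section at unit absorption efficiency — the absolute absorbed-power scale
cancels out of the trace shape). Device relations: V = p·ΔT·a/(ε_r·ε₀)
— ε read as the absolute permittivity, the only dimensionally consistent
interpretation — with defaults p = 400 µC m⁻² K⁻¹, ε_r = 2400,
a = 3000 nm (the simulation-cell characteristic size, which is what the
lumped potential describes; the particle diameter does not reproduce the
reference voltage); i = p·A·dT/dt and Q = p·A·ΔT. ΔT for the headline
potential is the 10 K heating-stage peak rise, giving 0.565 V. Traces
store the exact analytic dT/dt per sample so charge integrals carry no
differentiation error.

## Band alignment and Tauc extraction (`bands`)

VBM on the NHE scale: E = Φ + E_f − 4.44 with Φ the spectrometer work
function (4.2 eV here) and E_f the VB-XPS edge; E_f is an input because
the leading-edge vs peak-onset convention is laboratory-specific. CBM =
VBM − Eg, identifying eV and V for one-electron levels. The ROS ladder
defaults to O₂/•O₂⁻ at −0.33 V, H₂O₂/•OH at +0.73 V, OH⁻/•OH at +1.5 V;
a reduction is permitted when the CBM lies below the reaction potential,
an oxidation when the VBM lies above it, with the signed margin reported
and equality counted as not permitted.

Tauc extraction transforms the spectrum to (α·hν)² (direct, the
conventional choice for BaTiO₃ edges and the default) or (α·hν)^½
(indirect) and fits the steepest well-linear window: among sliding
windows of ~n/10 points, the maximal-slope one with R² ≥ 0.995 wins; if
none qualifies the fit falls back to the points whose Savitzky–Golay
smoothed local slope sits in the top quartile, and extraction fails with
diagnostics when even that fit has R² < 0.9. The bandgap is the
x-intercept. Explicit index windows are accepted for reproducibility.

## Synthetic fixtures (`fixtures`)

All pipeline inputs are generated, seeded, and byte-reproducible. A
single integer seed splits into independent per-kind streams via
`SeedSequence((seed, kind_code))` with frozen kind codes, so adding
generators never perturbs existing outputs. The generators emulate the
*statistical structure* the analyses assume — random multiphase starts
(uniform zero-mean components, default amplitude 0.1 C/m², of the order
of the 273 K phase-minimum components so quenches escape the slow
linear-growth regime), sparse Gaussian defect fields, composite variant
fields with exact known composition, direct-gap absorption edges
α = A√(hν − Eg)/hν on a 2.5–4.0 eV/301-point grid with multiplicative
noise and an optional Urbach tail — but not instrument artefacts
(baseline drift, stray light, XPS charging) or real microstructure
(grain boundaries, surface effects). Passing tests therefore demonstrate
correctness of the algorithms under their stated assumptions, not
robustness to raw instrument data.

## Problem sizes and tolerances

The test and acceptance runs use reduced problem sizes chosen as the
package's own desk-scale defaults: 24²–32² TDGL grids with ≤ 3000 steps
(production-style runs on 256²/128³ remain available through the same
API and CLI), 20-seed recovery studies for Tauc, and 10-seed Lyapunov
checks at dt = 0.25 (half the documented bound). Key verified tolerances:
analytic minimizer vs 1e−4-step grid search to 1e−3; uniform TDGL vs an
independent 0-D explicit-Euler oracle to 1e−6 (the oracle shares the
first-order time discretization, isolating the spectral machinery);
single-mode gradient energy and 1-D depolarization to closed forms at
1e−10/1e−6; mesh-refinement drift < 2% on a 64→128 wall test; Tauc
recovery ≤ 0.02 eV at 1% multiplicative noise.

## Known limitations

- The Landau gaps evaluated in SI are orders of magnitude below some
  published J cm⁻³ figures for similar compositions; the unit convention
  of such figures is ambiguous, so this package reports both J/m³ and
  J/cm³ and does not rescale coefficients.
- First-order semi-implicit time stepping only; no adaptive stepping or
  convergence detection.
- Homogeneous elastic moduli, periodic boundary conditions: no
  nanoparticle shape/surface effects, no heat-diffusion coupling inside
  the simulation grid.
- The lumped thermal model has a single time constant; real photothermal
  traces show multi-exponential cooling.
- No ROS chemical kinetics: feasibility is thermodynamic gating only.
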