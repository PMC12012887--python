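# Methods

This note records the models implemented in `relic`, their assumptions, the
numerical choices, and what the shipped parameter sets and synthetic test
conditions do and do not establish.

## Resource-aware rate laws

**Model.** A chemical reaction network contains q resource-limited
*catalytic* production reactions drawing from a conserved pool **R** of
total concentration `R_tot`: zeroth-order (constant inflow), unimolecular
(substrate S, recovered on catalysis) and bimolecular (substrates A, B).
Four bimolecular assembly orders are supported, differing in whether the
two substrates dimerize before the resource binds (scenarios 1/3, which
contribute only the pairwise occupancy term `w_ab·a·b`) or the resource
binds one substrate first (scenarios 2/4, which add a single-substrate
term `w_a·a` because the binary complex already sequesters resource).

**Assumptions.** (i) Deterministic mass action; (ii) all resource-binding
intermediates at quasi-steady state — implemented by scaling binding and
unbinding rates by 1/ε; (iii) total resource conserved over the interval of
interest; (iv) co-substrates in surplus (nucleotides, amino acids) are not
modeled; (v) conversion-type resource-limited reactions, resource-limited
degradation/sequestration, reactions drawing on two pools simultaneously,
and time-varying `R_tot(t)` are out of scope — a reaction naming two pools
is rejected with a configuration error.

Under (i)–(iv) the free resource is

    r = R_tot / (1 + Q0 + Σ w_u s + Σ (w_ab a b + w_a a))

and production rates are `β* r`, `β* s r`, `β* a b r`. `Q0` aggregates all
zeroth-order occupancies; equivalently one can fold `1/(1+Q0)` into an
effective capacity `R_eff` and rescaled gains (both conventions appear in
the API: `ResourcePool.R_eff` implements the scaled one, the circuit
right-hand sides use the conservation form, which makes a step in `Q0`
*exactly* equivalent to jointly rescaling `R_tot` and the gains).

**Lumping map.** `expand_to_mass_action` builds the explicit elementary
network and recomputes the induced reduced parameters as
`w = a/(d + ε·kcat) / (1+Q0)` and `β* = kcat·a/(d + ε·kcat)` (binding a,
unbinding d); the ε-correction makes the induced model the exact
quasi-steady state at finite ε. The reduced API treats (β*, w) as free
parameters, so nothing downstream depends on this convention.

**Oracle regime.** The reduced-vs-full comparisons integrate the elementary
network with free substrates buffered (held constant), which is the regime
in which the reduced law is exact in the ε → 0 limit; a dynamic-substrate
mode exists and is used for the conservation checks. Random oracle networks
draw `R_tot` ∈ [0.05, 0.3] against substrate levels of order one (resource
scarce relative to substrates, so the complexed substrate fraction is
small), binding/unbinding ratios a/d ∈ [0.025, 0.6] and kcat ∈ [0.5, 2].
Comparisons use a fixed horizon of 30 time units for every ε and discard
the initial fast layer of duration 10ε; errors are relative sup norms
(products normalized by their trajectory maximum). Measured errors are
≲ 2% at ε = 10⁻¹ and ≲ 0.1% at ε = 10⁻³, decreasing monotonically in ε.

## Controller motifs

State variables are concentrations in arbitrary units; time is in arbitrary
units intracellularly and in hours for population circuits. Controller
species follow pure positive autoregulation, so z = 0 is absorbing and
trajectories started positive stay positive; the contracts below hold for
strictly positive equilibria.

**Minimal motif.** `ż₁ = z₁(α₁* r − θ x_n)` with resource-limited
actuation `u = k* z₁ r` into the process (default plant
`ẋ₁ = b_p1* r + u − γ_p1 x₁`). Sensing is catalytic second-order
inhibition of Z₁ by the output (a protease mechanism); a Hill-type sensing
variant can be composed via the process hook but is not the default. The
resource denominator carries the controller occupancy `w_z1·z₁` plus
aggregate process-side linear and quadratic terms (`w_bar_lin`,
`w_bar_quad`; the default process load uses the sum of process states and
the sum of their pairwise products). With all gains zero, r is constant and
the loop has RPA; with any gain positive, the equilibrium condition
`x₁* = α₁* r*/θ` couples to the process through r* and adaptation is
imperfect. Shipped demonstration gains (w_z1 = 5, w_bar_lin = 1,
w_bar_quad = 0.1) were chosen so the residual error of a 20% actuation step
is a clearly resolvable few percent at pool sizes 50–200, and the error
shrinks monotonically as the gains are scaled toward zero.

**Layered motif.** A buffer species with bimolecular autocatalysis in
(Z₂, X_n) and constant turnover:

    ż₁ = z₁ (α₁* r − θ x₁)
    ż₂ = z₂ (α₂* x₁ r − γ_c2)
    ẋ₁ = b_p1* r + k* z₁ r − γ_p1 x₁
    r  = R_tot / (1 + Q0 + w₁ z₁ + w₂ z₂)

The two controller null-surfaces give `x₁* = Σ = sqrt(α₁*γ_c2/(α₂*θ))` and
`r* = γ_c2/(α₂*Σ)`: the *product* `r*·x₁* = γ_c2/α₂*` is a controller
constant, so the loop regulates the free resource in parallel with the
output. The bimolecular (rather than unimolecular) Z₂ law is what makes the
buffering *active*: r* scales inversely with the set-point instead of being
clamped globally. γ_c2 must be strictly positive (dilution in growing
cells, or specific proteolysis otherwise); it is validated as such.
Z₁ and Z₂ interact only through r.

Feasibility of the strictly positive equilibrium is exactly `z₁* > 0` and
`z₂* > 0` with

    z₁* = (γ_p1 Σ − b_p1* r*) / (k* r*)
    z₂* = (R_tot/r* − 1 − Q0 − w₁ z₁*) / w₂ ,

equivalent to `γ_p1 α₂* Σ² > b_p1* γ_c2` plus a capacity condition for
which the conservative closed form `R_tot > r* + w₁γ_p1Σ/k*` is reported
(`feasibility_conditions`); in the k* → ∞ limit it reduces to
`R_tot > r*`. The single sufficient stability condition `2γ_c2 ≤ γ_p1`
is exposed as `stability_criterion`; it is sufficient, not necessary, and
the package verifies it empirically: 1000 random feasible
parameterizations drawn log-uniformly from the documented fixture ranges
that satisfy it all have strictly left-half-plane spectra.

**Ratiometric motif.** Both constitutive legs of the layered controller are
replaced by monotone read-outs of a second process species:

    ż₁ = z₁ (α₁* G₁(x₂) r − θ H₁(x₁))
    ż₂ = z₂ (α₂* H₂(x₁) r − γ_c2 G₂(x₂))

Controller degradation/dilution is taken negligible (the only Z₂ turnover
is the X₂-modulated term). Dividing the two equilibrium relations
eliminates r and yields the ratio manifold
`H₁H₂(x₁*) = C·G₁G₂(x₂*)`, `C = α₁*γ_c2/(α₂*θ)` — independent of the
process, the pool and the disturbances. Linear maps make it the line
`x₁* = Γ x₂*` with `Γ = sqrt(C·g₁g₂/(h₁h₂))` (perfect ratiometric
control); Hill maps bend it (imperfect but still controller-determined),
and the manifold is inverted numerically by bisection, with a domain error
when the commanded value exceeds the saturation range of H₁H₂. The
stabilizing input `u` is a design hook of the embedding circuit; the
default embedding actuates the first species with `k* z₁ r`, which can
steer the ratio only upward from the open-loop value — commanded ratios
must sit above it.

## Intracellular application circuits

**Embedded gene-expression control.** The layered loop around the
single-gene plant, sharing its (translational) pool with L external load
modules that contain only zeroth-order resource-limited reactions; their
entire effect is the aggregate `Q0`, and individual module dynamics are
never simulated. Reference parameterization: α₂* = γ_c2 = 0.25,
w₁ = w₂ = 1, R_tot = 100, nominal Q0 = 10⁻³, completed by α₁* = θ = 1
(giving Σ = r* = 1), b_p1* = 0.1, γ_p1 = 1 (so 2γ_c2 ≤ γ_p1 holds with
margin and feasibility is comfortable), started from x₁ = 0, z₁ = 0.1,
z₂ = 50.

**Operon gene-ratio circuit.** Two genes translated (rates η₁*, η₂*) from
one polycistronic transcript M_P — both production terms read the same
transcript state, which is why transcriptional competition cancels from
the open-loop ratio `x₁*/x₂* = η₁*γ_x2/(η₂*γ_x1)`. Transcription draws
from pool R₁, translation from pool R₂. The controller genes are
two-stage (transcribed then translated), so with fast mRNA their effective
laws carry the product r₁r₂; actuation is a Z₁-activated auxiliary
transcript M_A translated into extra X₁ (strength k*, a config
parameter). mRNAs are explicit by default; `mrna_qss=1` slaves them to
their quasi-steady state. At any strictly positive equilibrium the ratio
equals Γ while the *product* of the two free-resource levels is pinned,
`r₁*r₂* = γ_c2 G₂(x₂*)/(α₂* H₂(x₁*))` — the two-pool analog of the
parallel resource regulation. The shipped demonstration commands Γ = 2
(α₁* = 1, α₂* = 0.5, γ_c2 = 1, θ = 0.5) across γ_x2 ∈ {0.4, 0.6, 0.8,
1.0}, all strictly below the commanded ratio so the upward-only actuation
can reach it.

## Population-level circuits

Generalized Lotka–Volterra competition models the consortium; the logistic
free-capacity factor `φ = 1 − (Σ weighted densities)/N_m` plays the free-
resource role. Controller strains N₁, N₂ are strains of one species: equal
carrying capacity, unit mutual competition coefficients, and equal
cross-coefficients to any process population (`c_jj = 1` is enforced).
Growth terms are capacity-modulated; killing terms are unmodulated mass
action; growth induction is first order (`μ = ρ·x`) by default, with an
optional saturating form `ρ·x/(1 + x/K)` that recovers first order when K
far exceeds the operating range (verified to 2%).

**Generic consortium / population control.** X_n kills N₁ (gain θ₁) and
induces N₂'s growth (gain ρ); with dilution γ the balance of N₁'s death
and N₂'s doubling pins the output at the positive root of

    θ₁ ρ x*² + γ ρ x* − μ₁ γ = 0,

independent of the process network, capacities and competition
coefficients. γ > 0 is required for a positive set-point — it plays the
same role as the buffer turnover γ_c2; the right-hand sides accept γ = 0
(batch mode) but the set-point helper raises. In the three-strain circuit
the channels are AHLs with birth–death dynamics (`ȧ = σN − δa`):
A₃ ← N₃ is sensed (kills N₁, grows N₂), A₁ ← N₁ actuates N₃'s growth.
The regulated quantity is a₃* (hence N₃* = δ₃a₃*/σ₃), insensitive to
N₃-side parameters (ρ₁, N_m3, c₁₃, c₃₁) and monotone in ρ₃.

**Coculture composition control.** Four strains, four AHLs. Growth wiring:
A₁ → N₃ (ρ₁), A₂ → N₄ (ρ₂) actuation; A₄ → N₁ (ρ₄), A₃ → N₂ (ρ₃)
sensing. Two toxin legs — A₃ kills N₁ (θ₁₃) and A₄ kills N₂ (θ₂₄) —
complete the ratiometric structure: dividing the two controller-strain
equilibrium relations eliminates the shared capacity factor and yields

    Γ = N₃*/N₄* = (δ₃σ₄/σ₃δ₄)·sqrt(ρ₄θ₂₄/(ρ₃θ₁₃)),

with the capacity factor pinned at `φ_c* = sqrt(θ₁₃θ₂₄/(ρ₃ρ₄))`;
admissibility therefore requires `ρ₃ρ₄ > θ₁₃θ₂₄` (raise ρ₃ or ρ₄), which
is checked and reported when violated. Process strains are diluted at γ;
controller strains are retained (`retentive_controller`), the structural
asymmetry that makes the composition control perfect — washing out the
controllers demonstrably degrades it to approximate adaptation.

Nominal population parameters were fixed once, inside the analytically and
numerically verified stable region, at values a microbial-consortium
modeler would call ordinary: growth-scale rates below 1 h⁻¹ (μ₁ = 0.8,
actuation/sensing gains 0.5–2 h⁻¹·a.u.⁻¹), AHL turnover faster than growth
(δ = 5–10 h⁻¹), carrying capacities 10³ density units, unit competition
coefficients, dilution γ = 0.1 h⁻¹. The three-strain circuit uses
N_m3 = 3000 so that ±50% perturbations of N_m3, c₁₃, c₃₁ keep the
consortium coexistent. The coculture circuit's worst eigenvalue at these
nominals is ≈ −0.016 h⁻¹ at Γ = 2 and ≈ −0.04 h⁻¹ at Γ = 4, so both
operating points of the 4-fold retargeting experiment are solidly damped.
Populations below 10⁻⁹ of carrying capacity are reported as excluded
(competitive-exclusion diagnostics) but never clamped by the integrator.

## Numerics

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiffness-switching),
  rtol 10⁻⁸ / atol 10⁻¹⁰ by default; the ε-scaled elementary networks use
  rtol 10⁻¹⁰ / atol 10⁻¹². Disturbance schedules integrate piecewise with
  parameters updated exactly at event times; identical schedules are
  bit-identical. Negative undershoot below 10× atol is clipped to zero in
  reported trajectories only, never in solver state.
* Steady states: doubling-horizon integration until
  ‖dx/dt‖∞/(‖x‖∞+1) < 10⁻⁹ (hard cap 10⁶ time units, after which
  non-convergence is reported — periodic attractors land here), followed by
  an optional Newton polish accepted only if it is non-negative and reduces
  the residual.
* Equilibria and stability: forward integration from the seed selects the
  basin (and the tie-break among multiple roots), then a hybrid-Powell root
  solve; residual tolerance 10⁻¹⁰, strict-positivity threshold 10⁻⁹ in
  model units. Jacobians by central differences with step
  max(10⁻⁶, 10⁻⁶|xᵢ|); stable means max Re λ < −10⁻⁸, eigenvalues with
  |Re λ| ≤ 10⁻⁸ are flagged marginal and excluded from "stable";
  ill-conditioned Jacobians trigger a warning with the condition estimate.
  Scan cells are evaluated independently; per-cell failures are recorded,
  never fatal.
* Fixture sampling: log-uniform draws from the documented ranges with
  rejection under named constraints; same seed, same fixture.

## What the synthetic conditions do and do not show

All inputs are synthetic: parameterized ODE circuits, random reduced
networks, and seeded parameter fixtures. They establish the *structural*
claims — which architectures preserve adaptation under resource coupling,
which closed forms the equilibria obey, where stability holds — under mass
action, deterministic dynamics and conserved totals. They do not establish
behaviour under intrinsic noise at low copy number (autocatalytic species
extinction is a stochastic phenomenon outside scope), under growth-rate
feedback on the resource pool itself, saturation beyond the provided Hill
forms, spatial structure, or parameter regimes far from the documented
sampling ranges. The Lotka–Volterra consortium results inherit that
model's usual idealizations (well-mixed culture, constant coefficients,
instantaneous AHL mixing).

## Problem sizes

The shipped verification suite uses the sizes at which the claims are
sharp and the closed forms make larger sweeps redundant: 20 random
networks × 3 ε values for the oracle, 1000 parameter draws for the
stability-criterion sweep, 20 stable fixtures for the set-point closed
form, four degradation settings for ratio robustness, six ±50%
perturbations for population insensitivity. The full suite and the
reproduction script each run in well under a minute on one CPU.
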