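# Methods

## Model

A controller network is a list of species annotated with integer segment
counts: active Int^C (q⁺ᵢ), active Int^N (q⁻ᵢ), monomers without an active
segment (q⁰ᵢ), and — for competing-sequestration designs — inactive
(mutationally dead) Int^N segments (q*ᵢ). Species with both active segment
types are rejected at construction: such a molecule would splice
intramolecularly, which is outside the supported rule set.

Dynamics are deterministic mass action over concentrations (arbitrary
units, time in hours), with three exceptions:

* **Actuation** is Hill-type. Activators and repressors enter through
  weighted sums A = Σ wᵢzᵢ/K_act and R = Σ wᵢzᵢ/K_rep; competitive binding
  to shared promoter sites gives h⁺ = k⁺Aⁿ/(1 + Aⁿ + Rⁿ), plain activation
  h⁺ = k⁺Aⁿ/(1 + Aⁿ), and a linear form is kept for the textbook AIF
  motif. Weights encode multiplicity (a dimer carrying two activation
  domains gets weight 2).
* **Splicing** between a C-class species Zᵢ and an N-class species Zⱼ has
  propensity η·max(q⁺ᵢ, q⁻ⱼ)·zᵢzⱼ; the integer multiplier counts the
  pairing opportunities between the participating segments.
* **Turnover** is structural: every species dilutes at δ; only S-class
  species (no active segments) degrade, at δ₀. C/N-class degradation is not
  representable at all (no rate field), mirroring the reaction rules rather
  than merely defaulting to zero.

Stochastic simulation uses the exact direct method on integer copy numbers
with combinatorial propensities (a homodimerization of n copies fires at
kf·n(n−1)/2); one named, seeded generator per path, seeds recorded.

## Rule engine

Species Rules 1–3 (the C/N/S classification) and Reaction Rules 2–8 are
graphical in origin and are implemented as the following independently
toggleable checks: RR2 splicing is between exactly one C- and one N-class
reactant and inactivates exactly one segment pair; RR3/RR4 binding and
conversion have association/complex shape; RR5/RR6 actuation uses declared
activator/repressor species with nonnegative rates; RR7 the controller
touches the plant only via actuation (X₁) and sensing (X_L) — structural in
this data model. The reduction-mode rules add: RR9 every C-class species
has a splicing channel with every N-class species; RR10 binding/conversion
are reversible and conserve all segment counts; RR11 only S-class degrades;
RR12 dilution is uniform; RR13 the splicing multiplier equals the
max-count rule. Violations are reported, never raised.

## Screening and reduction

The RPA screen computes q = q⁺ − q⁻ and the setpoint −qᵀμ/qᵀθ. The verdict
is explicitly *conditional on closed-loop stability*, which the screen does
not decide; simulations detect non-convergence and report it instead of
asserting adaptation. With monotone nonlinear sensing fᵢ(x_L) installed,
eligibility requires the net drift qᵀμ + qᵀf(x) to be strictly decreasing
with a positive root (negative feedback); the setpoint is then implicit and
available numerically as that root.

Reduction conditions are checked with exact ranks (Fraction-based Gaussian
elimination — stoichiometries are integers, so no floating-point rank
tolerance is needed). The reduced vector field is obtained by
left-multiplying the full right-hand side by Q = [q⁺ q⁻ q⁰]ᵀ (plus q* on
the generalized path): because every charge vector is conserved by every
binding/conversion column, the fast fluxes cancel *exactly* under Q, so no
symbolic elimination is performed and the boxed closed forms are recovered
implicitly. The extra z⁰ production term δ₀[𝟙(q⁺+q⁻)∘q⁰]ᵀψ(z^tot) arises
automatically from projecting the S-class-only degradation; it is exposed
separately (`extra_production`) for inspection and vanishes when δ₀ = 0 or
when no species holds both an active segment and a neutral monomer.

The DAE is integrated by index-1 direct substitution: inside the right-hand
side the algebraic system (fast net fluxes zero at fixed totals) is solved
by damped Newton on the fast-reaction extents (warm-started across calls),
with two safety nets — a nonnegative-least-squares feasible point and
relaxation integration of the fast subsystem alone — and a scaled residual
tolerance of 10⁻¹⁰. A single homodimerization is special-cased to its
quadratic closed form. Degenerate inputs: zero totals return the zero
state; negative totals beyond −10⁻⁶ (relative) are an error, smaller
excursions (solver trial steps) are clamped.

## Simulation and protocols

Stiff integration (LSODA, rtol 10⁻⁸, atol 10⁻¹⁰). Steady state is declared
when the output varies by less than 10⁻⁶ (relative) over the trailing 10 %
of the elapsed time, and is additionally refined by an algebraic
fixed-point solve; both values are reported, and the refinement is skipped
when no finite fixed point exists (see below). The disturbance protocol
scales the plant gain (the in-silico analogue of raising the output-plasmid
copy number) and never touches μ₁ or θ₂; open loop is realized as a
non-reactive intein pairing (η = 0), matching the experimental design,
with dilution δ = 0.05 h⁻¹ so that the open-loop controller state remains
bounded.

### The dilution-free regime

The exact setpoint guarantee needs δ = 0. It does *not* need δ₀ = 0:
S-class species carry q = 0, so their degradation never enters ż_I. This
matters structurally: every splicing event deposits a tracked neutral
product, and if that product acts on the promoter or controller (ZF, TetR,
Gal4) the loop has no finite steady state without the δ₀ sink — the output
then converges to a biased value, not the setpoint. The exact-adaptation
suites therefore run δ = 0 with δ₀ > 0 (default 0.1 h⁻¹), which is the
regime in which the theory promises — and the tests verify — exact
adaptation at 10⁻³ relative tolerance.

The competing-sequestration (inactive-intein) circuit is the one exception:
its dead-Int^N pool species are S-class, so δ₀ > 0 would drain the actuator
reservoir, while its only accumulating splice product is inert and
decouples. That preset runs δ₀ = 0 with the pool supplied as a conserved
initial endowment `pool` (the δ→0 limit of constitutive expression μ₄/δ);
`mu4 > 0` is meaningful when δ > 0. The supply-independence test sweeps the
endowment over a 100-fold range; the formula-level independence of the
setpoint from μ₄ is asserted separately.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| μ₁ | 10 h⁻¹ | constitutive setpoint-encoding production |
| θ₂ | 1 h⁻¹ | output-proportional sensing production |
| η | 100 (a.u.·h)⁻¹ | splicing rate |
| a, d | 100, 10 | association / dissociation of reversible binding |
| k_act, K, n | 50 h⁻¹, 1 a.u., 1 | Hill actuation |
| γ | 1 h⁻¹ | plant turnover |
| δ, δ₀ | 0, 0.1 h⁻¹ | dilution; S-class degradation |

Main-text circuit structure fixes none of these; the values were chosen
once so that (i) closed loops on one- and two-stage plants are stable,
(ii) the actuation ceiling comfortably exceeds the setpoint demand
γ·(μ₁/θ₂), and (iii) binding is fast relative to production/turnover so
that timescale separation is realizable by scaling a, d upward.

## Synthetic networks

The random factory grows networks from the core triplet Z1 (+1, produced
at μ₁), Z2 (−1, produced at θ₂x_L), Z3 (neutral splice product): reversible
dimerizations of the two monomeric species add complexes, reversible
isomerizations of Z3 add conversions, and every C-class species gets a
splicing channel with Z2 whose products dissociate into Z1/Z3 monomers —
so M = 3 + n_binding + n_conversion and the reduction conditions hold by
construction. Two deliberate restrictions keep the emitted study
conditions inside the regime the theory addresses ("stabilizing
parameters"): the actuation ceiling is drawn as 1.3–2× the setpoint demand
(deep actuator saturation keeps the proportional loop gain below the Hopf
threshold of two-stage plants), and complexes are dimers of monomers only
(stacking complexes onto complexes creates degradation-protected pools
whose equilibrium size grows geometrically with affinity and whose filling,
rate-limited by μ₁, stalls the transient for hundreds of hours).

What the generator emulates: rule-compliant topological diversity around
the built circuits. What it does not: resource competition and burden,
cross-talk between circuits, transport/compartments, cell-to-cell
variability in rates, and plants with embedded feedback. Passing tests
therefore demonstrate the structural theory under mass-action kinetics,
not performance in a loaded mammalian chassis.

## Problem sizes used by the verification suites

Setpoint theorem: the five TF circuits plus 50 random networks (M = 3–5)
closed on a one-stage plant or a two-stage plant with a fast conversion
stage and unit dc gain, integrated to steady state (cap t = 5000 h).
Reduction fidelity: binding rates scaled by 10, 10², 10³ over a 30 h
transient, output RMSE compared on a common grid. Stochastic setpoint:
copy scale 20, 50 paths of 600 h, burn-in 300 h, bootstrap standard error
over path means (1000 resamples). Sweeps: 8 setpoints spanning 0.125–16 in
factors of 2.

## Known limitations

* Stability is never proven — only detected numerically; the screen's
  verdict is conditional by design.
* The generalized (four-state) reduction path requires the extra
  conservation law to come from the `q_inactive` annotations; arbitrary
  additional conservation laws are not discovered automatically.
* The slow-manifold solver assumes the fast subsystem has a unique
  nonnegative equilibrium at given totals (guaranteed for the supported
  detailed-balanced binding networks, not for arbitrary fast kinetics).
* SBML export is one-way (no import) and targets Level 3 core with one
  irreversible reaction per channel; the exporter refuses callable
  (custom) actuation and sensing, which have no declarative form.
* The stochastic validity of the reduction is not established here; the
  SSA route always simulates the full network.
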