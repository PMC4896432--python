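# Methods

## The model class

`offl` handles deterministic compartmental models understood as
*interaction networks*: a bipartite directed graph whose nodes are M
dynamical **species** X^i (boxes) and N **interactions** (dots), each dot
carrying an interaction function f_a. Every edge ties one species to one
interaction: source edges (species → dot) carry weights β_{a,n}, the parcel
size drawn from the species per interaction event; target edges (dot →
species) carry weights α_{a,m}, the parcel size delivered. The diagram
grammar requires every dot to have at least one incoming and one outgoing
edge — no loose ends — so open-system processes (death, immigration)
acquire explicit auxiliary species (dead pool Δ, community pool K) whose
equations decouple from the species of interest.

The model *is* its relational representation: four linked tables (species,
interactions, source edges, target edges) plus a parameter table. The
parameter table is this package's addition — symbolic compilation leaves
parameters free, but numeric evaluation needs bound values, and the rate
constants have to live somewhere concrete. Edge order is insertion order,
and the dense `edge_index` is the authoritative edge ordinal everywhere
downstream, which makes array construction, CSV output, and DOT export
deterministic.

Two grammar rules need no validator code at all: "boxes cannot connect to
boxes" and "dots cannot connect to dots" (including splits/merges joining
dots directly) are unrepresentable in the tables, since every edge row
links exactly one species to exactly one interaction. The relational
representation itself is the enforcement.

## The translation rule

Compilation implements, literally,

    dX^i/dt = Σ_a [ Σ_m α_{a,m} t^i_{a,m} − Σ_n β_{a,n} s^i_{a,n} ]
              · f_a · Π_{ℓ=0}^{q_a−1} ( Σ_j s^j_{a,ℓ} X^j )

with t/s the per-edge 0/1 species indicators (stored densely as one species
index per edge; exactly one species per edge by construction). Two
deliberate conventions:

* The kinetic product runs over source **edges**, one factor per edge. A
  species on two source edges of the same interaction contributes its value
  squared. Factors are never raised to the weight β — weights appear only
  in the net-change coefficient. This is the schema's mass-action
  convention (absolute rate = fractional rate × the value of each source
  species) and it reproduces all the worked systems below; it deliberately
  differs from stoichiometric mass action, where exponents equal
  stoichiometric coefficients.
* Weights are expressions, not numbers. They participate symbolically in
  the coefficient sums with no constancy assumption; an interaction
  function may reference *any* declared species (the immigration rate θ/K
  references its own source; a type II response references prey density),
  so the validator permits any declared name in any expression.

The indicator subscripts are read uniformly in the interaction index a;
each worked example disambiguates the convention fully.

Symbolic equality in tests is always checked by expanding and simplifying
the difference to zero, never by string comparison — term order is
arbitrary.

## Worked systems the library reproduces

* growth: N →(κ) 2N gives dN/dt = (2−1)κN = κN; death as change of state
  gives dN/dt = −κN, dΔ/dt = +κN; death as eradication is the growth
  diagram with target weight 0, dN/dt = −κN with no Δ.
* general consumer-resource: a parcels of A + b parcels of B →(κ) c parcels
  of B gives dA/dt = −aκAB, dB/dt = (c−b)κAB; the total A+B is conserved
  exactly when c = a + b.
* SIR with demography: 5 species (S, I, R, K, Δ), 7 interactions; infection
  is 1+1→2 at rate a·c; immigration at constant absolute rate θ uses the
  interaction function θ/K.
* Lotka-Volterra: predation draws (R, α) and (F, 1) and deposits (F, β) and
  (F, 1) — the fox parcel entering the interaction is returned distinctly
  from the new foxes created. Merging the two F target edges into one of
  weight β+1 compiles to the identical system (a model symmetry); the
  two-edge form is kept because it states the process honestly. The type II
  variant only changes the predation rate to a/(1+h·a·R).

## Parameters that matter

All quantities are dimensionless populations and per-unit-time rates; time
units are whatever the rate constants imply (days for the epidemic
defaults).

* SIR defaults: contact rate c = 0.005 /infected/day with infection
  fraction a = 0.2 (so a·c = 10⁻³), recovery ρ = 0.1 /day, immunity waning
  σ = 0.01 /day, death d = 10⁻⁴ /day (S, R) and δ = 5·10⁻³ /day (I),
  immigration θ = 1 susceptible/day; S(0)=990, I(0)=10, R(0)=0. K(0)
  defaults to 10⁶·θ so that K does not change appreciably over typical run
  times (K(0) ≫ θτ); users wanting dK/dt = 0 exactly can set the
  immigration source weight to 0, which leaves the other equations
  unchanged.
* Lotka-Volterra defaults: k = 1, a = 0.1, α = 1, β = 0.5, δ = 0.5,
  R(0)=20, F(0)=5 — an orbit circling the coexistence point R* = δ/(aβ) =
  10, F* = k/(aα) = 10.
* SI/consumer-resource defaults: κ = 10⁻³, populations 990/10, the scale at
  which the bilinear term is O(10) per unit time.

These defaults were chosen once as representative textbook magnitudes; all
are overridable per call.

## Numerical choices

* Integration uses scipy's `solve_ivp` with LSODA (adaptive,
  stiff-capable), rtol 10⁻⁸ / atol 10⁻¹⁰, overridable via `options`. The
  integrator follows the ODE literally — no clamping of negative
  populations; a RuntimeWarning is attached if any species drops below
  −atol.
* The numeric rate evaluator is built by substituting parameter values into
  the symbolic system and lambdifying per species; tests require it to
  agree with direct symbolic substitution to 10⁻¹⁰ relative and with the
  independent edge-walking oracle to 10⁻¹² relative.
* Expression parsing uses sympy with a minimal namespace: declared names
  map to plain symbols (so `I`, `S`, `E`, `beta` never collide with
  sympy built-ins), `t` is the reserved time symbol, and only elementary
  functions (exp, log, sqrt, trig, Abs, Min, Max) are available. ASCII
  Greek spellings (kappa, theta, Delta, …) are normalized to the Greek
  characters on read, in names and inside expressions.
* Validation severity: every violation code is an error except the
  negative-constant-weight warning — negative weights are nowhere used by
  the worked systems but nowhere forbidden either, so they load and
  compile, flagged.
* Degenerate inputs: a species touched by no edge compiles to dX/dt = 0; a
  self-loop through a dot with equal source and target weight simplifies to
  zero net change; zero target weights are accepted silently (eradication).

## The random-model generator and what tests do (not) show

`testkit.random_model` draws grammatically valid models — exact species and
interaction counts, 1–3 edges per side referencing uniformly chosen
species, constant weights in [0.5, 3] and rates in [0.1, 2], strictly
positive random states — fully reproducible from a seed. Weights are kept
constant (not expressions) so the edge-walking oracle stays trivially
auditable; expression-valued weights are exercised by the library models
instead. States are drawn strictly positive so sign errors cannot hide
behind zeros.

These generated models emulate the *structure* of interaction networks,
not any particular biology: passing the oracle-equivalence and
conservation properties shows the compiler implements the translation rule
correctly, not that any particular model is a good description of a real
system. Model adequacy, parameter identifiability, and fit to data are out
of scope.

## Problem sizes

The property suites use ~20–30 random models of 4–6 species/interactions
with ~5 states each (≥100 model/state pairs), trajectories of 100–300
output points over t ≤ 50, and symbolic checks on the worked systems; the
whole suite runs in a few seconds on one CPU.

## Known limitations

* Append-only construction: no mutation/deletion API, no schema migration.
* No stochastic (Gillespie) simulation, steady-state solving, bifurcation
  analysis, symmetry detection, or automatic conserved-quantity discovery.
* No SBML/SBGN-PD interchange; DOT export is text only (no rendering).
* Units on weights are not modeled; weights are treated as pure numbers or
  expressions.
* Time-dependent interaction functions are supported and unit-tested, but
  no worked reference system exercises them.
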