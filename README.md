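# offl — formalized flow diagrams for interaction-network models

`offl` is a small Python library and command-line tool for building,
validating, compiling, and simulating deterministic compartmental models —
SIR-style epidemics, predator-prey systems, consumer-resource processes,
chemical-kinetics-like networks — written as *formalized flow diagrams*.

It is aimed at modelers in epidemiology, ecology, and systems biology who
want the discipline of a strict diagram grammar: every process in the model
is an explicit **interaction** node ("dot") that draws *parcels* from one or
more **source species** ("boxes") and deposits transformed parcels into
**target species**. Species never connect directly to species; arrows never
come from or go to "nowhere". External sources and sinks become explicit
auxiliary species (a community pool `K`, a dead pool `Δ`) whose dynamics
decouple from the system of interest.

## The model representation

A model with `M` species and `N` interactions is held as a relational table
set — the diagram and the database are in one-to-one correspondence:

| table | columns |
|---|---|
| species | `node_index`, `name`, `initial_value` |
| interactions | `interaction_index`, `name`, `rate_expression` |
| sources | `interaction_index`, `edge_index`, `species_node_index`, `weight` |
| targets | `interaction_index`, `edge_index`, `species_node_index`, `weight` |
| parameters | `name`, `value` |

Each interaction `a` carries an interaction function `f_a` (its *fractional*
rate — per capita-product per unit time), source weights `β_{a,n}` (parcel
size drawn per event) and target weights `α_{a,m}` (parcel size delivered
per event). Weights and rates are expressions: they may reference species,
parameters, and time.

## The translation rule

The whole system of ODEs follows from one rule. With `t^i_{a,m}` and
`s^i_{a,n}` the 0/1 indicators marking which species sits on the *m*-th
target (*n*-th source) edge of interaction *a*,

```
dX^i/dt = Σ_a [ Σ_m α_{a,m} t^i_{a,m} − Σ_n β_{a,n} s^i_{a,n} ]
          · f_a · Π_{ℓ=0}^{q_a−1} ( Σ_j s^j_{a,ℓ} X^j )
```

The kinetic product has **one factor per source edge** (a species on two
source edges contributes its value squared), and the factors are never
raised to the weight — weights enter only the net-change coefficient. An
interaction's absolute rate is therefore its interaction function times the
population value of each of its source species (mass-action kinetics).

## Worked example: SIR with demography and immigration

```sh
offl example sir --out sir.yaml
offl validate sir.yaml
offl compile sir.yaml
```

prints

```
OK: model is valid (5 species, 7 interactions)
dS/dt = -I*S*a*c + R*σ - S*d + θ
dI/dt = I*S*a*c - I*δ - I*ρ
dR/dt = I*ρ - R*d - R*σ
dK/dt = -θ
dΔ/dt = I*δ + R*d + S*d
```

The seven interactions are three deaths (S and R at rate `d`, I at rate
`δ`, all into the dead pool `Δ`), recovery `ρ` (I→R), waning immunity `σ`
(R→S), infection (1 S + 1 I → 2 I at rate `a·c` — the target edge carries
weight 2, so every encounter conserves the number of people), and
immigration from the community pool `K` at constant absolute rate `θ`
(interaction function `θ/K`, so the `θ/K · K` flux is exactly `θ`). Note
how the `K` and `Δ` equations decouple: they are the grammar's price for
refusing loose ends, not extra dynamics.

Simulating,

```sh
offl simulate sir.yaml --t-end 50 --points 3 --out traj.csv
```

```
t,S,I,R,K,Δ
0.0,990.0,10.0,0.0,1000000.0,0.0
25.0,35.42951207148506,172.47279108524182,771.6286703331689,999974.9999999991,45.46902651010428
50.0,101.4125182236175,71.94010968627062,816.4559615501935,999949.9999999987,60.19141053991836
```

The outbreak peaks and recedes; `K` falls by exactly `θ·t = 50`; and the
all-ones combination S+I+R+K+Δ is conserved to solver tolerance, because
every one of the seven interactions redeposits as many parcels as it draws.

The same workflow runs from Python:

```python
from offl import build_example, generate_odes, integrate, check_conservation

sir = build_example("sir")
print(generate_odes(sir).equations_text())
traj = integrate(sir, t_end=50.0, n_points=201)
print(check_conservation(traj, [1, 1, 1, 1, 1]))  # ~1e-9
```

Other library examples: `growth`, `death_state`, `death_eradication`,
`consumer_resource`, `si`, `lotka_volterra`, `lotka_volterra_type2`.
Models can also be written by hand as YAML files or as CSV table sets
(`offl export MODEL --format tables|dot --out PATH` writes the table set or
a Graphviz DOT rendering of the diagram).

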