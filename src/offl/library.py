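"""Builders for the classic example models, used as fixtures and docs.

Each builder returns a fully validated model with default numeric parameter
values (all overridable downstream).  The examples cover the elementary
processes — exponential growth, death as a change of state, death as
eradication, the general bilinear consumer-resource process — and the two
canonical applications: an SIR epidemic with demography and immigration,
and the Lotka-Volterra predator-prey system (type I and type II functional
response).

Auxiliary species appear wherever the diagram grammar forbids loose ends:
a dead pool Δ absorbing death flows, and a community pool K sourcing
immigration.  Their dynamics decouple from the species of interest.
"""

from __future__ import annotations

from .core import OfflModel
from .grammar import assert_valid

__all__ = ["EXAMPLES", "build_example", "build_consumer_resource"]


def _growth() -> OfflModel:
    """Exponential growth: each parcel of N duplicates at rate κ.

    A self-loop through the reproduction dot with target weight 2 gives
    dN/dt = (2 - 1)·κ·N = κN.
    """
    m = OfflModel()
    m.add_species("N", 2.0)
    m.add_parameter("κ", 0.3)
    m.add_interaction("reproduction", "κ", sources=["N"],
                      targets=[("N", 2)])
    return m


def _death_state() -> OfflModel:
    """Death as a change of state: parcels move from N to a dead pool Δ."""
    m = OfflModel()
    m.add_species("N", 100.0)
    m.add_species("Δ", 0.0)
    m.add_parameter("κ", 0.3)
    m.add_interaction("death", "κ", sources=["N"], targets=["Δ"])
    return m


def _death_eradication() -> OfflModel:
    """Death as spontaneous eradication: the growth diagram with target
    weight 0, so dN/dt = (0 - 1)·κ·N = -κN and no dead pool is needed."""
    m = OfflModel()
    m.add_species("N", 100.0)
    m.add_parameter("κ", 0.3)
    m.add_interaction("death", "κ", sources=["N"], targets=[("N", 0)])
    return m


def build_consumer_resource(a="a", b="b", c="c") -> OfflModel:
    """General two-species consumer-resource process.

    *a* parcels of A combine with *b* parcels of B at rate κ to become *c*
    parcels of B, giving dA/dt = -aκAB and dB/dt = (c - b)κAB.  The weights
    default to the symbolic parameters a, b, c; pass numbers or expression
    strings to specialize.  When a + b = c the total A + B is conserved.
    """
    m = OfflModel()
    m.add_species("A", 990.0)
    m.add_species("B", 10.0)
    m.add_parameter("κ", 0.001)
    defaults = {"a": 1.0, "b": 1.0, "c": 2.0}
    for name, arg in (("a", a), ("b", b), ("c", c)):
        if str(arg) == name:  # weight left symbolic: declare the parameter
            m.add_parameter(name, defaults[name])
    m.add_interaction("conversion", "κ",
                      sources=[("A", a), ("B", b)], targets=[("B", c)])
    return m


def _si() -> OfflModel:
    """SI epidemic: one parcel each of S and I combine into two parcels of
    I at rate κ, conserving S + I in every encounter."""
    m = OfflModel()
    m.add_species("S", 990.0)
    m.add_species("I", 10.0)
    m.add_parameter("κ", 0.001)
    m.add_interaction("infection", "κ", sources=["S", "I"],
                      targets=[("I", 2)])
    return m


def _sir() -> OfflModel:
    """SIR epidemic with demography and immigration; 5 species and 7
    interactions.

    Susceptibles S contact the infected I at rate c, a fraction a of
    contacts infecting (1 S + 1 I -> 2 I at rate a·c); infected recover at
    rate ρ into R; immunity wanes at rate σ (R -> S); S and R die at rate
    d and I at rate δ, all into the dead pool Δ; and susceptibles immigrate
    from a community pool K at constant absolute rate θ, so the attracting
    interaction function is θ/K.  K(0) defaults to 1e6·θ so K does not
    change appreciably over typical run times.
    """
    m = OfflModel()
    θ = 1.0
    m.add_species("S", 990.0)
    m.add_species("I", 10.0)
    m.add_species("R", 0.0)
    m.add_species("K", 1.0e6 * θ * 1.0)
    m.add_species("Δ", 0.0)
    m.add_parameter("a", 0.2)       # infection probability per contact
    m.add_parameter("c", 0.005)     # contact rate, per infected per day
    m.add_parameter("ρ", 0.1)       # recovery rate
    m.add_parameter("σ", 0.01)      # immunity-waning rate
    m.add_parameter("d", 1.0e-4)    # death rate of S and R
    m.add_parameter("δ", 5.0e-3)    # death rate of I
    m.add_parameter("θ", θ)         # immigration, susceptibles per day
    m.add_interaction("death_S", "d", sources=["S"], targets=["Δ"])
    m.add_interaction("death_I", "δ", sources=["I"], targets=["Δ"])
    m.add_interaction("death_R", "d", sources=["R"], targets=["Δ"])
    m.add_interaction("recovery", "ρ", sources=["I"], targets=["R"])
    m.add_interaction("immunity_loss", "σ", sources=["R"], targets=["S"])
    m.add_interaction("infection", "a*c", sources=["S", "I"],
                      targets=[("I", 2)])
    m.add_interaction("immigration", "θ/K", sources=["K"], targets=["S"])
    return m


def _lotka_volterra(type2: bool = False) -> OfflModel:
    """Lotka-Volterra predator-prey system.

    Rabbits R reproduce at rate k; foxes F consume α rabbits at rate a and
    convert them into β new foxes; foxes die at rate δ into the dead pool
    Δ.  The predation dot draws (R, α) and (F, 1) and deposits (F, β) and
    (F, 1) — the fox parcel entering the interaction is returned distinctly
    from the new foxes created — giving dR/dt = kR - aαRF and
    dF/dt = aβRF - δF.  With ``type2`` the predation rate becomes the
    saturating a/(1 + h·a·R) (type II functional response with handling
    time h).
    """
    m = OfflModel()
    m.add_species("R", 20.0)
    m.add_species("F", 5.0)
    m.add_species("Δ", 0.0)
    m.add_parameter("k", 1.0)      # prey reproduction rate
    m.add_parameter("a", 0.1)      # predation encounter rate
    m.add_parameter("α", 1.0)      # rabbits consumed per predation event
    m.add_parameter("β", 0.5)      # new foxes per predation event
    m.add_parameter("δ", 0.5)      # fox death rate
    if type2:
        m.add_parameter("h", 0.05)  # handling time
        predation_rate = "a/(1 + h*a*R)"
    else:
        predation_rate = "a"
    m.add_interaction("reproduction", "k", sources=["R"],
                      targets=[("R", 2)])
    m.add_interaction("predation", predation_rate,
                      sources=[("R", "α"), ("F", 1)],
                      targets=[("F", "β"), ("F", 1)])
    m.add_interaction("death_F", "δ", sources=["F"], targets=["Δ"])
    return m


EXAMPLES = {
    "growth": _growth,
    "death_state": _death_state,
    "death_eradication": _death_eradication,
    "consumer_resource": build_consumer_resource,
    "si": _si,
    "sir": _sir,
    "lotka_volterra": _lotka_volterra,
    "lotka_volterra_type2": lambda: _lotka_volterra(type2=True),
}


def build_example(name: str, **kwargs) -> OfflModel:
    """Build a named example model; extra kwargs go to its builder."""
    try:
        builder = EXAMPLES[name]
    except KeyError:
        raise KeyError(f"unknown example {name!r}; choose from "
                       f"{sorted(EXAMPLES)}") from None
    return assert_valid(builder(**kwargs))
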