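"""The translation rule: indicator arrays, symbolic ODEs, numeric evaluator.

Symbolic expectations are checked by expanding the difference and
simplifying to zero, never by string comparison.
"""

import numpy as np
import pytest
import sympy

from offl import (MissingBinding, OfflModel, build_example,
                  build_indicator_arrays, generate_odes,
                  make_rate_evaluator, oracle_rhs)
from offl.expressions import parse_expression


def sym_eq(expr, text, declared):
    """expr == parse(text) after expansion/simplification."""
    diff = sympy.simplify(sympy.expand(expr - parse_expression(text,
                                                               declared)))
    return diff == 0


def system_matches(model, expected):
    system = generate_odes(model)
    declared = model.declared_names()
    by_name = dict(zip(system.species_names, system.ode_expressions))
    return all(sym_eq(by_name[name], text, declared)
               for name, text in expected.items())


# -- indicator arrays --------------------------------------------------------

def test_si_indicator_arrays(si):
    arrays = build_indicator_arrays(si)
    assert arrays.q == [2] and arrays.p == [1]
    assert arrays.alpha[0][0] == 2
    assert arrays.beta[0] == [1, 1]
    # infection: sources S (node 0) and I (node 1), target I
    assert arrays.s_array[0] == [0, 1]
    assert arrays.t_array[0] == [1]


def test_indicator_rows_sum_to_one_per_edge(sir):
    arrays = build_indicator_arrays(sir)
    m = sir.n_species
    for a in range(sir.n_interactions):
        for e in range(arrays.p[a]):
            assert sum(arrays.t_indicator(i, a, e) for i in range(m)) == 1
        for e in range(arrays.q[a]):
            assert sum(arrays.s_indicator(i, a, e) for i in range(m)) == 1


def test_sir_arrays_cover_seven_interactions(sir):
    arrays = build_indicator_arrays(sir)
    assert len(arrays.p) == len(arrays.q) == 7
    assert [len(al) for al in arrays.alpha] == arrays.p
    assert [len(be) for be in arrays.beta] == arrays.q


# -- symbolic ODE generation -------------------------------------------------

def test_sir_compiles_to_printed_system(sir):
    assert system_matches(sir, {
        "S": "-a*c*S*I + σ*R - d*S + θ",
        "I": "a*c*S*I - ρ*I - δ*I",
        "R": "ρ*I - σ*R - d*R",
        "K": "-θ",
        "Δ": "d*S + δ*I + d*R",
    })


def test_lotka_volterra_compiles_to_printed_system(lotka_volterra):
    assert system_matches(lotka_volterra, {
        "R": "k*R - a*α*R*F",
        "F": "a*β*R*F - δ*F",
        "Δ": "δ*F",
    })


def test_general_consumer_resource_compiles_symbolically():
    model = build_example("consumer_resource")
    assert system_matches(model, {"A": "-a*κ*A*B", "B": "(c - b)*κ*A*B"})


def test_growth_and_death_compile_to_printed_equations():
    assert system_matches(build_example("growth"), {"N": "κ*N"})
    assert system_matches(build_example("death_state"),
                          {"N": "-κ*N", "Δ": "κ*N"})
    assert system_matches(build_example("death_eradication"), {"N": "-κ*N"})


def test_balanced_self_loop_has_zero_net_change():
    # equal source and target weight through one dot: parcels leave and
    # re-enter, so the net rate simplifies to zero
    m = OfflModel()
    m.add_species("X", 1.0)
    m.add_parameter("w", 3.0)
    m.add_parameter("r", 1.0)
    m.add_interaction("loop", "r", sources=[("X", "w")], targets=[("X", "w")])
    system = generate_odes(m)
    assert sympy.simplify(system.ode_expressions[0]) == 0


def test_kinetic_product_is_one_factor_per_source_edge():
    # a species on two source edges contributes its value squared, and the
    # factors are never raised to the weight
    m = OfflModel()
    m.add_species("A", 1.0)
    m.add_species("B", 0.0)
    m.add_parameter("r", 1.0)
    m.add_interaction("pair", "r", sources=[("A", 3), ("A", 3)],
                      targets=[("B", 1)])
    system = generate_odes(m)
    assert system_matches(m, {"A": "-6*r*A**2", "B": "r*A**2"})
    del system


def test_untouched_species_has_zero_rate():
    m = OfflModel()
    m.add_species("A", 1.0)
    m.add_species("Z", 5.0)  # never on any edge
    m.add_parameter("r", 1.0)
    m.add_interaction("loop", "r", sources=["A"], targets=[("A", 2)])
    system = generate_odes(m)
    assert system.ode_expressions[1] == 0


def test_balanced_weights_conserve_total_symbolically():
    # single interaction, constant weights with sum(targets) == sum(sources)
    m = OfflModel()
    m.add_species("A", 1.0)
    m.add_species("B", 1.0)
    m.add_parameter("κ", 1.0)
    m.add_interaction("swap", "κ", sources=[("A", 2), ("B", 1)],
                      targets=[("B", 3)])
    total = sum(generate_odes(m).ode_expressions)
    assert sympy.simplify(sympy.expand(total)) == 0


def test_free_parameters_are_reported():
    system = generate_odes(build_example("sir"))
    assert set(system.free_parameters) == {"a", "c", "ρ", "σ", "d", "δ", "θ"}


# -- numeric evaluator -------------------------------------------------------

def test_growth_evaluator_closed_form(growth):
    system = generate_odes(growth)
    rhs = make_rate_evaluator(system, {"κ": 0.5})
    assert rhs(0.0, [1.0]) == pytest.approx([0.5])
    assert rhs(17.3, [1.0]) == pytest.approx([0.5])  # autonomous


def test_lotka_volterra_fixed_point(lotka_volterra):
    # at R* = δ/(aβ), F* = k/(aα) the R and F rates vanish and the dead
    # pool grows at δF* = δk/(aα)
    p = dict(k=1.2, a=0.3, α=0.7, β=0.4, δ=0.9)
    system = generate_odes(lotka_volterra)
    rhs = make_rate_evaluator(system, p)
    r_star = p["δ"] / (p["a"] * p["β"])
    f_star = p["k"] / (p["a"] * p["α"])
    rates = rhs(0.0, [r_star, f_star, 0.0])
    assert rates[:2] == pytest.approx([0.0, 0.0], abs=1e-12)
    assert rates[2] == pytest.approx(p["δ"] * p["k"] / (p["a"] * p["α"]))


def test_evaluator_requires_all_bindings(sir):
    system = generate_odes(sir)
    with pytest.raises(MissingBinding):
        make_rate_evaluator(system, {"a": 1.0})


def test_evaluator_accepts_ascii_greek_binding_names(growth):
    system = generate_odes(growth)
    rhs = make_rate_evaluator(system, {"kappa": 2.0})
    assert rhs(0.0, [3.0]) == pytest.approx([6.0])


def test_evaluator_matches_symbolic_substitution_on_random_models():
    from offl import GeneratorConfig, random_model
    rng = np.random.default_rng(7)
    for seed in range(30):
        model = random_model(GeneratorConfig(n_species=4, n_interactions=5,
                                             seed=seed))
        system = generate_odes(model)
        rhs = make_rate_evaluator(system, model.parameter_values())
        state = rng.uniform(0.5, 5.0, size=4)
        subs = {sympy.Symbol(n): v
                for n, v in zip(system.species_names, state)}
        subs.update({sympy.Symbol(k): v
                     for k, v in model.parameter_values().items()})
        expected = [float(e.subs(subs)) for e in system.ode_expressions]
        got = rhs(0.0, state)
        assert got == pytest.approx(expected, rel=1e-10)


def test_evaluator_agrees_with_edge_walking_oracle_on_library_models():
    for name in ("growth", "si", "sir", "lotka_volterra",
                 "lotka_volterra_type2"):
        model = build_example(name)
        system = generate_odes(model)
        rhs = make_rate_evaluator(system, model.parameter_values())
        state = np.linspace(1.0, 2.0, model.n_species)
        assert rhs(0.0, state) == pytest.approx(
            oracle_rhs(model, state), rel=1e-12, abs=1e-12)


def test_time_dependent_rate_is_supported():
    m = OfflModel()
    m.add_species("N", 1.0)
    m.add_parameter("κ", 2.0)
    m.add_interaction("pulse", "κ*t", sources=["N"], targets=[("N", 2)])
    rhs = make_rate_evaluator(generate_odes(m), {"κ": 2.0})
    assert rhs(3.0, [5.0]) == pytest.approx([2.0 * 3.0 * 5.0])
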