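"""Translation of a validated model into a system of ODEs.

For a model with M species X^i and N interactions f_a the translation rule
is, per species i,

    dX^i/dt = sum_a [ sum_m alpha_{a,m} t^i_{a,m}
                      - sum_n beta_{a,n} s^i_{a,n} ]
              * f_a * prod_{l=0}^{q_a - 1} ( sum_j s^j_{a,l} X^j )

where alpha_{a,m} / beta_{a,n} are the target/source edge weights, and the
indicator arrays t^i_{a,m} / s^i_{a,n} are 1 exactly when species i sits on
the m-th target (n-th source) edge of interaction a.  The kinetic product
runs over source *edges* — one factor per edge, so a species appearing on
two source edges contributes its value squared — and the factors are never
raised to the weight: weights enter only the net-change coefficient.  This
is deliberately not stoichiometric mass action (where exponents would equal
weights); it is the convention that an interaction's absolute rate is the
interaction function times the population value of each source species.

Weights may themselves be expressions of species, parameters, and time, and
participate symbolically in the coefficient sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy

from .core import OfflModel
from .errors import MissingBinding
from .expressions import TIME_SYMBOL, bindings_with_aliases, parse_expression
from .grammar import assert_valid

__all__ = ["IndicatorArrays", "CompiledSystem", "build_indicator_arrays",
           "generate_odes", "make_rate_evaluator"]


@dataclass(frozen=True)
class IndicatorArrays:
    """Edge weights and species indicators, one row per interaction.

    ``alpha[a][m]`` / ``beta[a][n]`` are the target / source weights as
    sympy expressions; ``t_array[a][m]`` / ``s_array[a][n]`` hold the node
    index of the species each edge touches (the dense encoding of the 0/1
    indicator arrays: exactly one species index per edge).  ``p`` and ``q``
    are the per-interaction target and source edge counts.
    """

    alpha: list[list[sympy.Expr]]
    beta: list[list[sympy.Expr]]
    t_array: list[list[int]]
    s_array: list[list[int]]
    p: list[int]
    q: list[int]

    def t_indicator(self, i: int, a: int, m: int) -> int:
        """The 0/1 indicator t^i_{a,m}."""
        return 1 if self.t_array[a][m] == i else 0

    def s_indicator(self, i: int, a: int, n: int) -> int:
        """The 0/1 indicator s^i_{a,n}."""
        return 1 if self.s_array[a][n] == i else 0


@dataclass(frozen=True)
class CompiledSystem:
    """Per-species symbolic rates F^i of dX^i/dt = F^i(X, t)."""

    species_names: list[str]
    ode_expressions: list[sympy.Expr]
    free_parameters: list[str]

    def equations_text(self) -> list[str]:
        """One ``d<name>/dt = <expression>`` line per species."""
        return [f"d{n}/dt = {sympy.sstr(e)}"
                for n, e in zip(self.species_names, self.ode_expressions)]

    def equations_latex(self) -> list[str]:
        return [rf"\frac{{d{n}}}{{dt}} = {sympy.latex(e)}"
                for n, e in zip(self.species_names, self.ode_expressions)]


def build_indicator_arrays(model: OfflModel) -> IndicatorArrays:
    """Derive the weight and indicator arrays from the edge tables."""
    assert_valid(model)
    declared = model.declared_names()
    alpha, beta, t_array, s_array, p, q = [], [], [], [], [], []
    for rec in model.interactions:
        tgt = model.target_edges_of(rec.interaction_index)
        src = model.source_edges_of(rec.interaction_index)
        alpha.append([parse_expression(e.weight, declared) for e in tgt])
        beta.append([parse_expression(e.weight, declared) for e in src])
        t_array.append([e.species_node_index for e in tgt])
        s_array.append([e.species_node_index for e in src])
        p.append(len(tgt))
        q.append(len(src))
    return IndicatorArrays(alpha, beta, t_array, s_array, p, q)


def generate_odes(model: OfflModel) -> CompiledSystem:
    """Emit the symbolic system of ODEs for a validated model."""
    arrays = build_indicator_arrays(model)
    names = model.species_names()
    x = [sympy.Symbol(n) for n in names]

    rates = [sympy.Integer(0) for _ in names]
    for a, rec in enumerate(model.interactions):
        f_a = parse_expression(rec.rate_expression, model.declared_names())
        # mass-action kinetics: one factor per source edge
        kinetic = sympy.Integer(1)
        for j in arrays.s_array[a]:
            kinetic *= x[j]
        flux = f_a * kinetic
        for i in range(len(names)):
            net = sympy.Integer(0)
            for m in range(arrays.p[a]):
                if arrays.t_array[a][m] == i:
                    net += arrays.alpha[a][m]
            for n in range(arrays.q[a]):
                if arrays.s_array[a][n] == i:
                    net -= arrays.beta[a][n]
            if net != 0:
                rates[i] = rates[i] + net * flux

    species = set(names)
    free = sorted({s.name for e in rates for s in e.free_symbols}
                  - species - {TIME_SYMBOL})
    return CompiledSystem(names, [sympy.expand(e) for e in rates], free)


def make_rate_evaluator(
    system: CompiledSystem,
    parameter_bindings: Mapping[str, float] | None = None,
) -> Callable[[float, Sequence[float]], np.ndarray]:
    """Bind parameters and return a numeric ``(t, state) -> rates`` function.

    Every free parameter of the compiled system must receive a value;
    unbound names raise :class:`MissingBinding`.  The evaluator is a
    deterministic closure over a lambdified copy of the expressions.
    """
    bindings = bindings_with_aliases(parameter_bindings or {})
    missing = [p for p in system.free_parameters if p not in bindings]
    if missing:
        raise MissingBinding(f"no value bound for parameter(s) {missing}")

    subs = {sympy.Symbol(k): sympy.Float(v) for k, v in bindings.items()
            if k in system.free_parameters}
    bound = [e.subs(subs) for e in system.ode_expressions]
    args = [sympy.Symbol(TIME_SYMBOL)] + [sympy.Symbol(n)
                                          for n in system.species_names]
    funcs = [sympy.lambdify(args, e, modules="numpy") for e in bound]

    m = len(system.species_names)

    def rate_evaluator(time: float, state: Sequence[float]) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (m,):
            raise ValueError(f"state must have length {m}")
        return np.array([f(time, *state) for f in funcs], dtype=float)

    return rate_evaluator
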