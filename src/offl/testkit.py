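"""Property-testing support: random valid models and a brute-force oracle.

``random_model`` draws grammatically valid models with constant weights and
rates, fully reproducible from a seed.  ``oracle_rhs`` computes the rate
vector by walking the edge tables directly — per interaction, evaluate the
interaction function, multiply by each source species' value, then subtract
the source weight times that flux from each source species and add the
target weight times it to each target species.  It never touches the
indicator-array formulation, so agreement between the two routes is a
meaningful check of the compiler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import OfflModel
from .errors import MissingBinding
from .expressions import TIME_SYMBOL, bindings_with_aliases, parse_expression
from .grammar import assert_valid

__all__ = ["GeneratorConfig", "random_model", "oracle_rhs"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-model generator; all counts must be positive."""
    n_species: int = 5
    n_interactions: int = 7
    max_edges_per_side: int = 3
    weight_range: tuple[float, float] = (0.5, 3.0)
    rate_range: tuple[float, float] = (0.1, 2.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.n_interactions,
               self.max_edges_per_side) < 1:
            raise ValueError("all counts must be >= 1")
        if (self.weight_range[0] > self.weight_range[1]
                or self.rate_range[0] > self.rate_range[1]
                or self.rate_range[0] <= 0):
            raise ValueError("empty weight/rate range")


def random_model(config: GeneratorConfig) -> OfflModel:
    """Draw a random valid model, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    model = OfflModel()
    for i in range(config.n_species):
        model.add_species(f"X{i}", float(rng.uniform(1.0, 10.0)))
    names = model.species_names()
    for a in range(config.n_interactions):
        rate = float(rng.uniform(*config.rate_range))
        n_src = int(rng.integers(1, config.max_edges_per_side + 1))
        n_tgt = int(rng.integers(1, config.max_edges_per_side + 1))
        sources = [(names[int(rng.integers(config.n_species))],
                    repr(float(rng.uniform(*config.weight_range))))
                   for _ in range(n_src)]
        targets = [(names[int(rng.integers(config.n_species))],
                    repr(float(rng.uniform(*config.weight_range))))
                   for _ in range(n_tgt)]
        model.add_interaction(f"proc{a}", repr(rate), sources, targets)
    return model


def oracle_rhs(model: OfflModel, state: Sequence[float],
               parameter_bindings: Mapping[str, float] | None = None,
               time: float = 0.0) -> np.ndarray:
    """Rate vector by direct edge walking (independent of the compiler).

    For each interaction: flux = f_a(state, t) x the product of the source
    species' values (one factor per source edge); then each source edge
    subtracts weight x flux from its species and each target edge adds
    weight x flux.
    """
    assert_valid(model)
    state = np.asarray(state, dtype=float)
    names = model.species_names()
    if state.shape != (len(names),):
        raise ValueError(f"state must have length {len(names)}")

    bindings = dict(model.parameter_values())
    bindings.update(bindings_with_aliases(parameter_bindings or {}))
    env = {name: float(x) for name, x in zip(names, state)}
    env.update(bindings)
    env[TIME_SYMBOL] = float(time)
    declared = model.declared_names()

    def evaluate(text: str) -> float:
        expr = parse_expression(text, declared)
        missing = {s.name for s in expr.free_symbols} - set(env)
        if missing:
            raise MissingBinding(
                f"no value bound for parameter(s) {sorted(missing)}")
        return float(expr.evalf(subs=env))

    rates = np.zeros(len(names))
    for rec in model.interactions:
        flux = evaluate(rec.rate_expression)
        for edge in model.source_edges_of(rec.interaction_index):
            flux *= state[edge.species_node_index]
        for edge in model.source_edges_of(rec.interaction_index):
            rates[edge.species_node_index] -= evaluate(edge.weight) * flux
        for edge in model.target_edges_of(rec.interaction_index):
            rates[edge.species_node_index] += evaluate(edge.weight) * flux
    return rates
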