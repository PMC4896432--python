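"""Relational data model for OFFL diagrams.

An interaction-network model is held as five linked tables: species
(the "boxes" of the diagram, each a dynamical quantity X^i), interactions
(the "dots", each carrying an interaction function f_a), source edges and
target edges (the linking tables, each row tying one interaction to one
species with a weight), and parameters (named constants the expressions may
reference).  Because every edge row links exactly one species to exactly one
interaction, box-to-box and dot-to-dot connections are unrepresentable by
construction.

Index columns are dense: species occupy node indices 0..M-1, interactions
0..N-1, and within each interaction the source (resp. target) edges occupy
edge indices 0..q-1 (resp. 0..p-1) in insertion order.  These ordinals are
authoritative for array construction and export, making every downstream
artifact deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import DanglingReference, DomainError, GrammarError, NameCollision
from .expressions import TIME_SYMBOL, is_identifier, normalize_name

__all__ = [
    "SpeciesRecord", "InteractionRecord", "SourceEdgeRecord",
    "TargetEdgeRecord", "ParameterRecord", "OfflModel",
    "add_species", "add_interaction", "add_parameter",
]

#: Default edge weight when a diagram arrow carries no label.
DEFAULT_WEIGHT = "1"


@dataclass(frozen=True)
class SpeciesRecord:
    """One dynamical quantity (a box of the diagram)."""
    node_index: int
    name: str
    initial_value: float


@dataclass(frozen=True)
class InteractionRecord:
    """One process (a dot of the diagram) with its interaction function."""
    interaction_index: int
    name: str
    rate_expression: str


@dataclass(frozen=True)
class SourceEdgeRecord:
    """An arrow from a species box into an interaction dot.

    ``weight`` is the parcel size drawn from the species per interaction
    event (the source weight), stored as an expression string.
    """
    interaction_index: int
    edge_index: int
    species_node_index: int
    weight: str = DEFAULT_WEIGHT


@dataclass(frozen=True)
class TargetEdgeRecord:
    """An arrow from an interaction dot out to a species box.

    ``weight`` is the parcel size delivered per event (the target weight);
    zero is allowed and models eradication-style processes.
    """
    interaction_index: int
    edge_index: int
    species_node_index: int
    weight: str = DEFAULT_WEIGHT


@dataclass(frozen=True)
class ParameterRecord:
    """A named constant available to rate and weight expressions."""
    name: str
    value: float


@dataclass
class OfflModel:
    """The five tables of an OFFL model; the single source of truth."""

    species: list[SpeciesRecord] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)
    source_edges: list[SourceEdgeRecord] = field(default_factory=list)
    target_edges: list[TargetEdgeRecord] = field(default_factory=list)
    parameters: list[ParameterRecord] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def species_names(self) -> list[str]:
        """Species names in node-index order."""
        return [s.name for s in
                sorted(self.species, key=lambda s: s.node_index)]

    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def declared_names(self) -> list[str]:
        """All names an expression may legally reference (except time)."""
        return self.species_names() + self.parameter_names()

    def species_index(self, name: str) -> int:
        """Node index of the species called *name* (aliases normalized)."""
        name = normalize_name(name)
        for rec in self.species:
            if rec.name == name:
                return rec.node_index
        raise DanglingReference(f"unknown species {name!r}")

    def initial_state(self) -> list[float]:
        """Initial values in node-index order."""
        return [s.initial_value for s in
                sorted(self.species, key=lambda s: s.node_index)]

    def parameter_values(self) -> dict[str, float]:
        return {p.name: p.value for p in self.parameters}

    def source_edges_of(self, interaction_index: int) -> list[SourceEdgeRecord]:
        rows = [e for e in self.source_edges
                if e.interaction_index == interaction_index]
        return sorted(rows, key=lambda e: e.edge_index)

    def target_edges_of(self, interaction_index: int) -> list[TargetEdgeRecord]:
        rows = [e for e in self.target_edges
                if e.interaction_index == interaction_index]
        return sorted(rows, key=lambda e: e.edge_index)

    # -- construction ----------------------------------------------------

    def add_species(self, name: str, initial_value: float = 0.0) -> int:
        """Append one species row; returns its (dense) node index."""
        name = normalize_name(name)
        if not is_identifier(name):
            raise NameCollision(f"{name!r} is not a valid species name")
        if name == TIME_SYMBOL:
            raise NameCollision(f"{name!r} is the reserved time symbol")
        if name in self.species_names() or name in self.parameter_names():
            raise NameCollision(f"name {name!r} already declared")
        initial_value = float(initial_value)
        if initial_value < 0:
            raise DomainError(
                f"initial value of {name!r} must be >= 0, got {initial_value}")
        index = len(self.species)
        self.species.append(SpeciesRecord(index, name, initial_value))
        return index

    def add_parameter(self, name: str, value: float) -> None:
        """Declare a named constant usable in rate and weight expressions."""
        name = normalize_name(name)
        if not is_identifier(name):
            raise NameCollision(f"{name!r} is not a valid parameter name")
        if name == TIME_SYMBOL:
            raise NameCollision(f"{name!r} is the reserved time symbol")
        if name in self.species_names() or name in self.parameter_names():
            raise NameCollision(f"name {name!r} already declared")
        self.parameters.append(ParameterRecord(name, float(value)))

    def add_interaction(self, name: str, rate_expression: str,
                        sources: list, targets: list) -> int:
        """Append one interaction with its source and target edges.

        *sources* and *targets* are lists whose entries are either a species
        name (weight defaults to 1) or a ``(species name, weight)`` pair;
        weights may be numbers or expression strings.  Edge indices follow
        list order.  Returns the interaction's dense index.
        """
        name = normalize_name(name)
        if not is_identifier(name):
            raise NameCollision(f"{name!r} is not a valid interaction name")
        if name in (rec.name for rec in self.interactions):
            raise NameCollision(f"interaction name {name!r} already used")
        src = [_as_edge_spec(entry) for entry in sources]
        tgt = [_as_edge_spec(entry) for entry in targets]
        if not src or not tgt:
            raise GrammarError(
                "every interaction needs at least one source and one target "
                "edge (all dots must have at least one incoming and one "
                "outgoing edge)")
        # resolve names before mutating anything
        src_idx = [self.species_index(s) for s, _ in src]
        tgt_idx = [self.species_index(s) for s, _ in tgt]

        a = len(self.interactions)
        self.interactions.append(
            InteractionRecord(a, name, str(rate_expression)))
        for n, ((_, w), i) in enumerate(zip(src, src_idx)):
            self.source_edges.append(SourceEdgeRecord(a, n, i, w))
        for m, ((_, w), i) in enumerate(zip(tgt, tgt_idx)):
            self.target_edges.append(TargetEdgeRecord(a, m, i, w))
        return a

    def with_initial_values(self, **values: float) -> "OfflModel":
        """Copy of the model with some species' initial values replaced."""
        out = OfflModel(list(self.species), list(self.interactions),
                        list(self.source_edges), list(self.target_edges),
                        list(self.parameters))
        for name, value in values.items():
            i = out.species_index(name)
            out.species[i] = replace(out.species[i],
                                     initial_value=float(value))
        return out


def _as_edge_spec(entry) -> tuple[str, str]:
    """Normalize an edge request to (species name, weight string)."""
    if isinstance(entry, str):
        name, weight = entry, DEFAULT_WEIGHT
    else:
        name, weight = entry
    return normalize_name(str(name)), str(weight)


# Free-function spellings of the construction operations.

def add_species(model: OfflModel, name: str, initial_value: float = 0.0) -> int:
    return model.add_species(name, initial_value)


def add_interaction(model: OfflModel, name: str, rate_expression: str,
                    sources: list, targets: list) -> int:
    return model.add_interaction(name, rate_expression, sources, targets)


def add_parameter(model: OfflModel, name: str, value: float) -> None:
    model.add_parameter(name, value)
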