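"""Diagram-grammar validation.

The grammar of a well-formed flow diagram: every interaction dot has at
least one incoming and one outgoing edge; every edge ties exactly one
species to exactly one interaction (no loose ends); index columns are dense
and names unique; every rate and weight expression parses and references
only declared names (plus the reserved time symbol).  Dot-to-dot and
box-to-box connections need no check — the relational representation cannot
express them.

``validate`` is pure: it inspects arbitrary table content (including
hand-edited files) and returns a list of violations, never raising.
Negative constant weights are reported as a warning rather than an error:
the schema neither uses nor forbids them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core import OfflModel
from .errors import InvalidModel
from .expressions import (TIME_SYMBOL, is_identifier, parse_expression,
                          undeclared_symbols)

__all__ = ["Code", "Violation", "validate", "assert_valid"]


class Code(str, enum.Enum):
    """Closed enumeration of grammar-violation codes."""
    DOT_NO_SOURCE = "DOT_NO_SOURCE"
    DOT_NO_TARGET = "DOT_NO_TARGET"
    DANGLING_EDGE = "DANGLING_EDGE"
    DUPLICATE_EDGE_INDEX = "DUPLICATE_EDGE_INDEX"
    NON_DENSE_INDEX = "NON_DENSE_INDEX"
    NAME_COLLISION = "NAME_COLLISION"
    UNPARSEABLE_EXPRESSION = "UNPARSEABLE_EXPRESSION"
    UNDECLARED_SYMBOL = "UNDECLARED_SYMBOL"
    NEGATIVE_WEIGHT_WARNING = "NEGATIVE_WEIGHT_WARNING"


#: Codes that do not invalidate a model.
WARNING_CODES = frozenset({Code.NEGATIVE_WEIGHT_WARNING})


@dataclass(frozen=True)
class Violation:
    code: Code
    index: int | None  # interaction or species index, when applicable
    message: str

    @property
    def is_warning(self) -> bool:
        return self.code in WARNING_CODES

    def __str__(self) -> str:
        where = "" if self.index is None else f" [#{self.index}]"
        return f"{self.code.value}{where}: {self.message}"


def validate(model: OfflModel) -> list[Violation]:
    """Check *model* against every grammar rule; empty list iff valid.

    Warnings appear in the list but are flagged non-fatal via
    :attr:`Violation.is_warning`.
    """
    out: list[Violation] = []
    out += _check_indices(model)
    out += _check_names(model)
    out += _check_edges(model)
    out += _check_degrees(model)
    out += _check_expressions(model)
    return out


def assert_valid(model: OfflModel) -> OfflModel:
    """Return *model* unchanged, raising InvalidModel on any error."""
    errors = [v for v in validate(model) if not v.is_warning]
    if errors:
        raise InvalidModel(errors)
    return model


def _check_indices(model: OfflModel) -> list[Violation]:
    out = []
    got = [s.node_index for s in model.species]
    if sorted(got) != list(range(len(got))):
        out.append(Violation(
            Code.NON_DENSE_INDEX, None,
            f"species node_index column is {got}, expected a dense "
            f"0..{len(got) - 1}"))
    got = [r.interaction_index for r in model.interactions]
    if sorted(got) != list(range(len(got))):
        out.append(Violation(
            Code.NON_DENSE_INDEX, None,
            f"interaction_index column is {got}, expected a dense "
            f"0..{len(got) - 1}"))
    return out


def _check_names(model: OfflModel) -> list[Violation]:
    out = []
    seen: dict[str, str] = {}
    groups = [("species", [s.name for s in model.species]),
              ("parameter", [p.name for p in model.parameters])]
    for kind, names in groups:
        for name in names:
            if not is_identifier(name):
                out.append(Violation(
                    Code.NAME_COLLISION, None,
                    f"{kind} name {name!r} is not a valid identifier"))
            elif name == TIME_SYMBOL:
                out.append(Violation(
                    Code.NAME_COLLISION, None,
                    f"{kind} name {name!r} collides with the time symbol"))
            elif name in seen:
                out.append(Violation(
                    Code.NAME_COLLISION, None,
                    f"{kind} name {name!r} already used as a {seen[name]}"))
            else:
                seen[name] = kind
    inames = [r.name for r in model.interactions]
    for name in {n for n in inames if inames.count(n) > 1}:
        out.append(Violation(Code.NAME_COLLISION, None,
                             f"duplicate interaction name {name!r}"))
    return out


def _check_edges(model: OfflModel) -> list[Violation]:
    out = []
    n_species = len(model.species)
    n_inter = len(model.interactions)
    for side, rows in (("source", model.source_edges),
                       ("target", model.target_edges)):
        seen_pairs = set()
        per_interaction: dict[int, list[int]] = {}
        for row in rows:
            if not 0 <= row.interaction_index < n_inter:
                out.append(Violation(
                    Code.DANGLING_EDGE, row.interaction_index,
                    f"{side} edge refers to interaction "
                    f"{row.interaction_index}, which does not exist"))
                continue
            if not 0 <= row.species_node_index < n_species:
                out.append(Violation(
                    Code.DANGLING_EDGE, row.interaction_index,
                    f"{side} edge {row.edge_index} of interaction "
                    f"{row.interaction_index} refers to species "
                    f"{row.species_node_index}, which does not exist"))
            pair = (row.interaction_index, row.edge_index)
            if pair in seen_pairs:
                out.append(Violation(
                    Code.DUPLICATE_EDGE_INDEX, row.interaction_index,
                    f"duplicate {side} edge index {row.edge_index} on "
                    f"interaction {row.interaction_index}"))
            seen_pairs.add(pair)
            per_interaction.setdefault(row.interaction_index,
                                       []).append(row.edge_index)
        for a, idxs in per_interaction.items():
            if sorted(set(idxs)) != list(range(len(set(idxs)))):
                out.append(Violation(
                    Code.NON_DENSE_INDEX, a,
                    f"{side} edge indices of interaction {a} are "
                    f"{sorted(idxs)}, expected dense from 0"))
    return out


def _check_degrees(model: OfflModel) -> list[Violation]:
    out = []
    with_source = {e.interaction_index for e in model.source_edges}
    with_target = {e.interaction_index for e in model.target_edges}
    for rec in model.interactions:
        if rec.interaction_index not in with_source:
            out.append(Violation(
                Code.DOT_NO_SOURCE, rec.interaction_index,
                f"interaction {rec.name!r} has no incoming (source) edge"))
        if rec.interaction_index not in with_target:
            out.append(Violation(
                Code.DOT_NO_TARGET, rec.interaction_index,
                f"interaction {rec.name!r} has no outgoing (target) edge"))
    return out


def _check_expressions(model: OfflModel) -> list[Violation]:
    out = []
    declared = model.declared_names()
    items = [(r.interaction_index, f"rate of interaction {r.name!r}",
              r.rate_expression, False) for r in model.interactions]
    items += [(e.interaction_index,
               f"weight of {side} edge {e.edge_index} on interaction "
               f"{e.interaction_index}", e.weight, True)
              for side, rows in (("source", model.source_edges),
                                 ("target", model.target_edges))
              for e in rows]
    for index, what, text, is_weight in items:
        try:
            expr = parse_expression(text, declared)
        except ValueError as exc:
            out.append(Violation(Code.UNPARSEABLE_EXPRESSION, index,
                                 f"{what}: {exc}"))
            continue
        unknown = undeclared_symbols(expr, declared)
        if unknown:
            out.append(Violation(
                Code.UNDECLARED_SYMBOL, index,
                f"{what} references undeclared name(s) "
                f"{sorted(unknown)}"))
        elif is_weight and expr.is_number and expr.is_negative:
            out.append(Violation(
                Code.NEGATIVE_WEIGHT_WARNING, index,
                f"{what} is the negative constant {expr}"))
    return out
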