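"""Reading and writing model representations.

Three interchange formats are supported:

* the relational **table set** — four mandatory CSV files (species,
  interactions, sources, targets) plus an optional parameters file,
  mirroring the model's database representation row for row;
* a human-writable single-file **model definition** in YAML, mirroring the
  modeling procedure (declare species, declare parameters, then one entry
  per interaction with its rate, sources, and targets);
* **Graphviz DOT** export of the bipartite diagram (boxes for species,
  dots for interactions).

Reading never validates: load/validate separation lets the grammar checker
report problems in hand-edited files instead of refusing to open them.
Expressions are carried verbatim (ASCII Greek spellings normalized);
nothing is evaluated at write time.
"""

from __future__ import annotations

import csv
from pathlib import Path

import yaml

from .core import (DEFAULT_WEIGHT, InteractionRecord, OfflModel,
                   ParameterRecord, SourceEdgeRecord, SpeciesRecord,
                   TargetEdgeRecord)
from .errors import ParseError
from .expressions import (normalize_expression_text, normalize_name,
                          parse_expression)
from .grammar import assert_valid

__all__ = ["write_tables", "read_tables", "read_model_file",
           "write_model_file", "export_dot", "TABLE_FILES"]

#: File names and column layouts of the table-set representation.
TABLE_FILES = {
    "species": ("species.csv", ["node_index", "name", "initial_value"]),
    "interactions": ("interactions.csv",
                     ["interaction_index", "name", "rate_expression"]),
    "sources": ("sources.csv",
                ["interaction_index", "edge_index", "species_node_index",
                 "weight"]),
    "targets": ("targets.csv",
                ["interaction_index", "edge_index", "species_node_index",
                 "weight"]),
    "parameters": ("parameters.csv", ["name", "value"]),
}


# ---------------------------------------------------------------------------
# table set

def write_tables(model: OfflModel, directory) -> list[Path]:
    """Write the five CSV tables into *directory*; returns the paths."""
    assert_valid(model)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def rows_for(key):
        if key == "species":
            return [[s.node_index, s.name, repr(s.initial_value)]
                    for s in sorted(model.species, key=lambda s: s.node_index)]
        if key == "interactions":
            return [[r.interaction_index, r.name, r.rate_expression]
                    for r in sorted(model.interactions,
                                    key=lambda r: r.interaction_index)]
        if key == "parameters":
            return [[p.name, repr(p.value)] for p in model.parameters]
        rows = model.source_edges if key == "sources" else model.target_edges
        return [[e.interaction_index, e.edge_index, e.species_node_index,
                 e.weight]
                for e in sorted(rows, key=lambda e: (e.interaction_index,
                                                     e.edge_index))]

    paths = []
    for key, (fname, header) in TABLE_FILES.items():
        path = directory / fname
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            writer.writerows(rows_for(key))
        paths.append(path)
    return paths


def read_tables(directory) -> OfflModel:
    """Load a model from a table-set directory (validation not run)."""
    directory = Path(directory)
    for key in ("species", "interactions", "sources", "targets"):
        if not (directory / TABLE_FILES[key][0]).exists():
            raise IOError(f"missing table file {TABLE_FILES[key][0]} "
                          f"in {directory}")

    def load(key, required=True):
        fname, header = TABLE_FILES[key]
        path = directory / fname
        if not path.exists():
            return []
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            rows = list(reader)
        if not rows or rows[0] != header:
            raise ParseError(f"expected header {','.join(header)}",
                             str(path) + ":1")
        out = []
        for lineno, row in enumerate(rows[1:], start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}",
                    f"{path}:{lineno}")
            out.append((lineno, row))
        return out

    model = OfflModel()
    for lineno, (idx, name, x0) in load("species"):
        model.species.append(SpeciesRecord(
            _int(idx, "node_index", f"species.csv:{lineno}"),
            normalize_name(name),
            _float(x0, "initial_value", f"species.csv:{lineno}")))
    for lineno, (idx, name, rate) in load("interactions"):
        model.interactions.append(InteractionRecord(
            _int(idx, "interaction_index", f"interactions.csv:{lineno}"),
            normalize_name(name), normalize_expression_text(rate)))
    for key, cls, table in (("sources", SourceEdgeRecord, "source_edges"),
                            ("targets", TargetEdgeRecord, "target_edges")):
        for lineno, (a, e, i, w) in load(key):
            where = f"{key}.csv:{lineno}"
            getattr(model, table).append(cls(
                _int(a, "interaction_index", where),
                _int(e, "edge_index", where),
                _int(i, "species_node_index", where),
                normalize_expression_text(w)))
    for lineno, (name, value) in load("parameters", required=False):
        model.parameters.append(ParameterRecord(
            normalize_name(name),
            _float(value, "value", f"parameters.csv:{lineno}")))
    return model


def _int(text, what, where):
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{what} must be an integer, got {text!r}", where)


def _float(text, what, where):
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{what} must be a number, got {text!r}", where)


# ---------------------------------------------------------------------------
# single-file model definition (YAML dialect)

class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys."""


def _strict_mapping(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ParseError(f"duplicate name {key!r}",
                             f"line {key_node.start_mark.line + 1}")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping)


def read_model_file(path) -> OfflModel:
    """Parse a single-file YAML model definition into a model."""
    path = Path(path)
    try:
        with path.open(encoding="utf-8") as fh:
            doc = yaml.load(fh, Loader=_StrictLoader)
    except ParseError as exc:
        raise ParseError(str(exc), str(path)) from None
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f"{path}:{mark.line + 1}" if mark else str(path)
        raise ParseError(f"invalid YAML: {exc}", where) from None
    if not isinstance(doc, dict):
        raise ParseError("model file must be a mapping with keys "
                         "species/parameters/interactions", str(path))
    unknown = set(doc) - {"species", "parameters", "interactions"}
    if unknown:
        raise ParseError(f"unknown top-level key(s) {sorted(unknown)}",
                         str(path))

    model = OfflModel()
    try:
        for name, x0 in _named_values(doc.get("species"), "species", path):
            model.add_species(name, x0)
        for name, value in _named_values(doc.get("parameters"),
                                         "parameters", path):
            model.add_parameter(name, value)
        for entry in doc.get("interactions") or []:
            if not isinstance(entry, dict) or "rate" not in entry:
                raise ParseError(
                    "each interaction needs at least a 'rate' key",
                    str(path))
            name = str(entry.get("name",
                                 f"interaction_{model.n_interactions}"))
            model.add_interaction(
                name,
                normalize_expression_text(str(entry["rate"])),
                [_edge_entry(x, path) for x in entry.get("sources") or []],
                [_edge_entry(x, path) for x in entry.get("targets") or []])
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(str(exc), str(path)) from None
    return model


def _named_values(section, what, path):
    """Yield (name, value) pairs from a mapping or list-of-pairs section."""
    if section is None:
        return
    if isinstance(section, dict):
        items = section.items()
    elif isinstance(section, list):
        items = []
        for entry in section:
            if isinstance(entry, dict) and len(entry) == 1:
                items.append(next(iter(entry.items())))
            elif isinstance(entry, str):
                items.append((entry, 0.0))
            else:
                raise ParseError(
                    f"bad {what} entry {entry!r}", str(path))
    else:
        raise ParseError(f"{what} must be a mapping or list", str(path))
    for name, value in items:
        yield str(name), float(value if value is not None else 0.0)


def _edge_entry(entry, path):
    """Normalize a source/target list item to (species, weight string)."""
    if isinstance(entry, str):
        return (entry, DEFAULT_WEIGHT)
    if isinstance(entry, dict) and len(entry) == 1:
        (name, weight), = entry.items()
        if weight is None:
            weight = DEFAULT_WEIGHT
        return (str(name), normalize_expression_text(str(weight)))
    raise ParseError(f"bad edge entry {entry!r}; use 'name' or "
                     "'name: weight'", str(path))


def write_model_file(model: OfflModel, path) -> Path:
    """Write a model as a single-file YAML definition."""
    path = Path(path)
    doc: dict = {"species": {s.name: s.initial_value for s in model.species}}
    if model.parameters:
        doc["parameters"] = {p.name: p.value for p in model.parameters}
    doc["interactions"] = []
    names = model.species_names()

    def edge_out(edge):
        name = names[edge.species_node_index]
        if edge.weight == DEFAULT_WEIGHT:
            return name
        return {name: edge.weight}

    for rec in model.interactions:
        doc["interactions"].append(
            {"name": rec.name, "rate": rec.rate_expression,
             "sources": [edge_out(e) for e in
                         model.source_edges_of(rec.interaction_index)],
             "targets": [edge_out(e) for e in
                         model.target_edges_of(rec.interaction_index)]})
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True,
                          default_flow_style=False)
    path.write_text(text, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# DOT export

def export_dot(model: OfflModel) -> str:
    """Render the diagram as deterministic Graphviz DOT text.

    Species are boxes, interactions are points carrying their rate as an
    external label; source edges run species -> dot, target edges
    dot -> species.  Weight labels are omitted when the weight is the
    constant 1.  A model with M species and N interactions yields exactly
    M + N nodes.
    """
    assert_valid(model)
    declared = model.declared_names()
    lines = ["digraph offl_model {", "  rankdir=LR;"]
    for s in sorted(model.species, key=lambda s: s.node_index):
        lines.append(f'  s{s.node_index} [shape=box, label="{s.name}"];')
    for r in sorted(model.interactions, key=lambda r: r.interaction_index):
        lines.append(f'  i{r.interaction_index} [shape=point, '
                     f'xlabel="{r.rate_expression}"];')
    for e in sorted(model.source_edges,
                    key=lambda e: (e.interaction_index, e.edge_index)):
        lines.append(f"  s{e.species_node_index} -> i{e.interaction_index}"
                     f"{_dot_label(e.weight, declared)};")
    for e in sorted(model.target_edges,
                    key=lambda e: (e.interaction_index, e.edge_index)):
        lines.append(f"  i{e.interaction_index} -> s{e.species_node_index}"
                     f"{_dot_label(e.weight, declared)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_label(weight: str, declared) -> str:
    try:
        if parse_expression(weight, declared) == 1:
            return ""
    except ValueError:
        pass
    return f' [label="{weight}"]'
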