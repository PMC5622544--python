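"""Ontology-driven search (ODS): incremental query models compiled to SPARQL.

A :class:`QueryModel` is a small AST — a root class plus an ordered list of
constraints (object-property hops to further class-typed nodes, and datatype
filters) with optional aggregation — built from ontology entities instead of
SPARQL text.  Compilation expands every type constraint into its subclass
closure inlined in a ``FILTER (?t IN (...))`` clause, so the store needs no
RDFS entailment.

Two dialects are emitted.  ``display`` reproduces the registry platform's
canonical query shape, including its Virtuoso-style aggregate select list
(``SELECT count(DISTINCT ?s), ?t``); ``standard`` is valid SPARQL 1.1 and is
what :func:`run_query` executes.  Variable naming is deterministic: the root
is ``?s`` (type ``?t``); children of the root are numbered 0, 1, 2, ... in
insertion order (``?a0``, ``?a1``); children of a node whose suffix ends in
digit d are numbered from d+1 (``?a0`` -> ``?a01``, ``?a1`` -> ``?a12``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import QueryValidationError, UnknownEntityError
from .ontology import OntologyModel, local_name, subclass_closure
from .rdf_store import SemanticStore

RDF_IRI = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

_NUMERIC_OPS = {"=", "!=", "<", "<=", ">", ">="}
_STRING_OPS = {"=", "!="}
AGGREGATE_FUNCTIONS = {"count", "avg", "min", "max"}


@dataclass(frozen=True)
class Param:
    """A literal placeholder in a stored template, bound at instantiation."""

    name: str


@dataclass
class Filter:
    """Datatype-property comparison at a node."""

    prop: str
    op: str
    value: object  # int | float | str | Param


@dataclass
class Link:
    """Object-property hop to a class-typed node, with nested constraints."""

    prop: str
    cls: str
    constraints: list = field(default_factory=list)


@dataclass
class Aggregation:
    function: str = "count"
    distinct: bool = True
    group_node: list[int] = field(default_factory=list)  # path to the grouped node
    group_prop: str | None = None  # group by a datatype property instead of the type
    target_prop: str | None = None  # aggregated property for avg/min/max


@dataclass
class QueryModel:
    root_cls: str
    constraints: list = field(default_factory=list)
    aggregation: Aggregation | None = None
    name: str | None = None

    # -- parameters --------------------------------------------------------

    def parameters(self) -> set[str]:
        out: set[str] = set()

        def walk(constraints):
            for c in constraints:
                if isinstance(c, Filter) and isinstance(c.value, Param):
                    out.add(c.value.name)
                elif isinstance(c, Link):
                    walk(c.constraints)

        walk(self.constraints)
        return out

    def bind(self, params: dict) -> "QueryModel":
        """Return a copy with parameter placeholders replaced by literals."""

        def walk(constraints):
            out = []
            for c in constraints:
                if isinstance(c, Filter) and isinstance(c.value, Param):
                    if c.value.name not in params:
                        out.append(c)
                    else:
                        out.append(replace(c, value=params[c.value.name]))
                elif isinstance(c, Link):
                    out.append(replace(c, constraints=walk(c.constraints)))
                else:
                    out.append(c)
            return out

        return replace(self, constraints=walk(self.constraints))


def validate_model(model: QueryModel, ontology: OntologyModel) -> None:
    """Check the model against the ontology's domains, ranges and kinds."""
    ontology.require_class(model.root_cls)

    def check(constraints, cls):
        for c in constraints:
            if isinstance(c, Link):
                pairs = ontology.object_property_pairs(c.prop)
                if not pairs:
                    raise QueryValidationError(f"unknown object property {c.prop}")
                if not any(ontology.is_subclass_of(cls, dom) for dom, _ in pairs):
                    raise QueryValidationError(
                        f"property {c.prop} does not apply to class {local_name(cls)}"
                    )
                target = ontology.require_class(c.cls)
                if not any(ontology.is_subclass_of(target, rng) for _, rng in pairs):
                    raise QueryValidationError(
                        f"class {c.cls} is outside the range of {c.prop}"
                    )
                check(c.constraints, target)
            elif isinstance(c, Filter):
                kinds = ontology.datatype_property_kinds(c.prop)
                if not kinds:
                    raise QueryValidationError(f"unknown datatype property {c.prop}")
                if not ontology.property_applies(c.prop, cls):
                    raise QueryValidationError(
                        f"property {c.prop} does not apply to class {local_name(cls)}"
                    )
                if isinstance(c.value, Param):
                    continue
                kind = next(iter(kinds))
                numeric = kind in ("integer", "decimal")
                if numeric and not isinstance(c.value, (int, float)):
                    raise QueryValidationError(
                        f"filter on {c.prop} needs a numeric literal, got {c.value!r}"
                    )
                if not numeric and not isinstance(c.value, str):
                    raise QueryValidationError(
                        f"filter on {c.prop} needs a string literal, got {c.value!r}"
                    )
                ops = _NUMERIC_OPS if numeric else _NUMERIC_OPS  # strings compare via str()
                if c.op not in ops:
                    raise QueryValidationError(f"unsupported operator {c.op!r}")
            else:
                raise QueryValidationError(f"unknown constraint type {type(c).__name__}")

    check(model.constraints, ontology.iri(model.root_cls))

    agg = model.aggregation
    if agg is not None:
        if agg.function not in AGGREGATE_FUNCTIONS:
            raise QueryValidationError(f"unknown aggregate function {agg.function!r}")
        node_cls = _node_class(model, agg.group_node, ontology)
        if agg.group_prop is not None and not ontology.property_applies(agg.group_prop, node_cls):
            raise QueryValidationError(
                f"group-by property {agg.group_prop} does not apply to {local_name(node_cls)}"
            )
        if agg.function != "count":
            if agg.target_prop is None:
                raise QueryValidationError(f"{agg.function} needs a target property")
            if not ontology.property_applies(agg.target_prop, ontology.iri(model.root_cls)):
                raise QueryValidationError(
                    f"aggregate property {agg.target_prop} does not apply to the root class"
                )


def _node_class(model: QueryModel, path: list[int], ontology: OntologyModel) -> str:
    cls, constraints = ontology.iri(model.root_cls), model.constraints
    for idx in path:
        try:
            node = constraints[idx]
        except IndexError:
            raise QueryValidationError(f"aggregation group node path {path} is invalid")
        if not isinstance(node, Link):
            raise QueryValidationError("aggregation group node must be an object link")
        cls, constraints = ontology.iri(node.cls), node.constraints
    return cls


# ---------------------------------------------------------------------------
# emission


def _child_suffixes(suffix: str, count: int) -> list[str]:
    start = int(suffix[-1]) + 1 if suffix else 0
    return [suffix + str(start + i) for i in range(count)]


def _type_list(ontology: OntologyModel, cls: str) -> list[str]:
    """Subclass closure in filter order: descendants depth-first, root last."""
    closure = subclass_closure(ontology, cls)
    return closure[1:] + [closure[0]] if len(closure) > 1 else closure


def _term(iri: str, ontology: OntologyModel, dialect: str) -> str:
    name = local_name(iri, ontology.namespace)
    if dialect == "standard" and name.endswith("."):
        return f"<{ontology.iri(name)}>"  # PN_LOCAL may not end with '.'
    return f"ods:{name}"


def _literal_text(value) -> str:
    if isinstance(value, Param):
        raise QueryValidationError(f"unbound template parameter {value.name!r}")
    if isinstance(value, bool):
        raise QueryValidationError("boolean literals are not supported")
    if isinstance(value, (int, float)):
        return repr(value)
    return "'" + str(value).replace("'", "\\'") + "'"


def _filter_condition(c: Filter, var: str, ontology: OntologyModel) -> str:
    kinds = ontology.datatype_property_kinds(c.prop)
    numeric = bool(kinds & {"integer", "decimal"})
    if numeric:
        return f"?{var} {c.op} {_literal_text(c.value)}"
    op = "=" if c.op == "=" else "!="
    return f"str(?{var}) {op} {_literal_text(c.value)}"


def _emit_groups(constraints, parent_var: str, suffix: str,
                 ontology: OntologyModel, dialect: str) -> list[str]:
    """Nested-group emission: the platform's canonical (display) shape."""
    groups: list[str] = []
    for c, child_suffix in zip(constraints, _child_suffixes(suffix, len(constraints))):
        var = f"a{child_suffix}"
        if isinstance(c, Link):
            types = ", ".join(
                _term(t, ontology, dialect) for t in _type_list(ontology, ontology.iri(c.cls))
            )
            groups.append(
                f"{{?{parent_var} {_term(c.prop, ontology, dialect)} ?{var}."
                f"{{?{var} rdf:type ?t{var} FILTER (?t{var} IN ({types}))}}}}"
            )
            groups.extend(
                _emit_groups(c.constraints, var, child_suffix, ontology, dialect)
            )
        else:
            groups.append(
                f"{{?{parent_var} {_term(c.prop, ontology, dialect)} ?{var}. "
                f"FILTER ({_filter_condition(c, var, ontology)})}}"
            )
    return groups


def _emit_flat(constraints, parent_var: str, suffix: str,
               ontology: OntologyModel, forced_suffixes=None) -> list[str]:
    """Flat single-BGP emission (standard dialect): same semantics as the
    nested display shape — purely conjunctive — but orders of magnitude
    faster under rdflib's evaluator."""
    lines: list[str] = []
    child_suffixes = forced_suffixes or _child_suffixes(suffix, len(constraints))
    for c, child_suffix in zip(constraints, child_suffixes):
        var = f"a{child_suffix}"
        if isinstance(c, Link):
            types = ", ".join(
                _term(t, ontology, "standard")
                for t in _type_list(ontology, ontology.iri(c.cls))
            )
            lines.append(f"?{parent_var} {_term(c.prop, ontology, 'standard')} ?{var} .")
            lines.append(f"?{var} rdf:type ?t{var} . FILTER (?t{var} IN ({types}))")
            lines.extend(_emit_flat(c.constraints, var, child_suffix, ontology))
        else:
            lines.append(
                f"?{parent_var} {_term(c.prop, ontology, 'standard')} ?{var} . "
                f"FILTER ({_filter_condition(c, var, ontology)})"
            )
    return lines


def build_query(model: QueryModel, ontology: OntologyModel,
                dialect: str = "display") -> str:
    """Compile a validated model to SPARQL text (byte-deterministic).

    ``display`` is the platform's canonical shape; ``standard`` is valid
    SPARQL 1.1 for execution.
    """
    if dialect not in ("display", "standard"):
        raise ValueError(f"unknown dialect {dialect!r}")
    validate_model(model, ontology)

    root_types = ", ".join(
        _term(t, ontology, dialect)
        for t in _type_list(ontology, ontology.iri(model.root_cls))
    )
    root_group = f"{{?s rdf:type ?t FILTER (?t IN ({root_types}))}}"

    suffix_of_node: dict[tuple, str] = {(): ""}

    def collect_suffixes(constraints, suffix, path):
        for i, (c, child_suffix) in enumerate(
            zip(constraints, _child_suffixes(suffix, len(constraints)))
        ):
            suffix_of_node[path + (i,)] = child_suffix
            if isinstance(c, Link):
                collect_suffixes(c.constraints, child_suffix, path + (i,))

    collect_suffixes(model.constraints, "", ())

    agg = model.aggregation
    group_var = agg_target_var = None
    extra_display: list[str] = []
    extra_flat: list[str] = []
    if agg is not None:
        node_suffix = suffix_of_node.get(tuple(agg.group_node))
        node_var = "s" if not agg.group_node else f"a{node_suffix}"
        if agg.group_prop is None:
            group_var = "t" if not agg.group_node else f"ta{node_suffix}"
        else:
            group_var = "g"
            pattern = f"?{node_var} {_term(agg.group_prop, ontology, dialect)} ?{group_var}"
            extra_display.append("{" + pattern + "}")
            extra_flat.append(pattern + " .")
        if agg.function != "count":
            agg_target_var = "v"
            pattern = f"?s {_term(agg.target_prop, ontology, dialect)} ?{agg_target_var}"
            extra_display.append("{" + pattern + "}")
            extra_flat.append(pattern + " .")

    prefix = f"PREFIX ods: <{ontology.namespace}>"
    if dialect == "standard":
        prefix += f"\nPREFIX rdf: <{RDF_IRI}>"
        # selectivity ordering: root datatype filters bind ?s cheaply, the
        # type pattern then runs over a small binding set, links follow
        suffixes = _child_suffixes("", len(model.constraints))
        filter_lines, link_lines = [], []
        for c, sfx in zip(model.constraints, suffixes):
            emitted = _emit_flat([c], "s", "", ontology, (sfx,))
            (filter_lines if isinstance(c, Filter) else link_lines).extend(emitted)
        lines = (filter_lines
                 + [f"?s rdf:type ?t . FILTER (?t IN ({root_types}))"]
                 + link_lines + extra_flat)
        body = "\n".join(lines)
        if agg is None:
            return f"{prefix}\nSELECT DISTINCT ?s WHERE {{\n{body}\n}}"
        distinct = "DISTINCT " if agg.distinct else ""
        inner = f"?{agg_target_var}" if agg.function != "count" else "?s"
        select = f"SELECT ({agg.function.upper()}({distinct}{inner}) AS ?agg) ?{group_var}"
        return f"{prefix}\n{select} WHERE {{\n{body}\n}} GROUP BY ?{group_var}"

    groups = _emit_groups(model.constraints, "s", "", ontology, dialect) + extra_display
    body = root_group + (".{" + ".".join(groups) + "}" if groups else "")
    if agg is None:
        return f"{prefix}\nSELECT DISTINCT ?s WHERE {{{body}}}"
    distinct = "DISTINCT " if agg.distinct else ""
    inner = f"?{agg_target_var}" if agg.function != "count" else "?s"
    select = f"SELECT {agg.function}({distinct}{inner}), ?{group_var}"
    return f"{prefix}\n{select} WHERE {{{body}}} group by ?{group_var}"


def run_query(model: QueryModel, store: SemanticStore) -> list[dict]:
    """Compile (standard dialect) and execute against the store."""
    return store.execute_sparql(build_query(model, store.ontology, dialect="standard"))


# ---------------------------------------------------------------------------
# template persistence

TEMPLATE_SCHEMA = "oncoreg-query/1"


def _constraint_to_json(c) -> dict:
    if isinstance(c, Link):
        return {
            "kind": "link", "property": c.prop, "class": c.cls,
            "constraints": [_constraint_to_json(x) for x in c.constraints],
        }
    value = {"param": c.value.name} if isinstance(c.value, Param) else c.value
    return {"kind": "filter", "property": c.prop, "op": c.op, "value": value}


def _constraint_from_json(d: dict):
    if d["kind"] == "link":
        return Link(
            prop=d["property"], cls=d["class"],
            constraints=[_constraint_from_json(x) for x in d.get("constraints", [])],
        )
    if d["kind"] != "filter":
        raise QueryValidationError(f"unknown constraint kind {d.get('kind')!r}")
    value = d["value"]
    if isinstance(value, dict):
        value = Param(value["param"])
    return Filter(prop=d["property"], op=d["op"], value=value)


def model_to_dict(model: QueryModel) -> dict:
    out = {
        "schema": TEMPLATE_SCHEMA,
        "root_class": model.root_cls,
        "constraints": [_constraint_to_json(c) for c in model.constraints],
    }
    if model.name:
        out["name"] = model.name
    if model.aggregation:
        agg = model.aggregation
        out["aggregation"] = {
            "function": agg.function, "distinct": agg.distinct,
            "group_node": list(agg.group_node), "group_prop": agg.group_prop,
            "target_prop": agg.target_prop,
        }
    return out


def model_from_dict(data: dict) -> QueryModel:
    if data.get("schema") != TEMPLATE_SCHEMA:
        raise QueryValidationError(
            f"unsupported template schema {data.get('schema')!r}"
        )
    agg = None
    if data.get("aggregation"):
        a = data["aggregation"]
        agg = Aggregation(
            function=a.get("function", "count"), distinct=a.get("distinct", True),
            group_node=list(a.get("group_node", [])), group_prop=a.get("group_prop"),
            target_prop=a.get("target_prop"),
        )
    return QueryModel(
        root_cls=data["root_class"],
        constraints=[_constraint_from_json(c) for c in data.get("constraints", [])],
        aggregation=agg, name=data.get("name"),
    )


def save_template(model: QueryModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n",
                          encoding="utf-8")


def load_template(path, params: dict | None = None) -> QueryModel:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise QueryValidationError(f"template is not valid JSON: {exc}") from exc
    model = model_from_dict(data)
    return model.bind(params) if params else model


# ---------------------------------------------------------------------------
# defined classes and dashboards


@dataclass
class DefinedClass:
    """A named class whose membership is a stored query's result set."""

    name: str
    query: QueryModel

    def __post_init__(self):
        if self.query.aggregation is not None:
            raise QueryValidationError("a defined class query cannot aggregate")


def register_defined_class(dc: DefinedClass, store: SemanticStore) -> frozenset[str]:
    """Record the class on the store (virtual, recomputed) and return members."""
    if store.ontology.has_class(dc.name):
        raise QueryValidationError(
            f"defined-class name collides with ontology class {dc.name!r}"
        )
    registry = getattr(store, "defined_classes", None)
    if registry is None:
        registry = {}
        store.defined_classes = registry
    registry[dc.name] = dc
    return defined_class_members(store, dc.name)


def defined_class_members(store: SemanticStore, name: str) -> frozenset[str]:
    registry = getattr(store, "defined_classes", {})
    if name not in registry:
        raise UnknownEntityError(f"no defined class named {name!r}")
    rows = run_query(registry[name].query, store)
    return frozenset(str(r["s"]) for r in rows)


def dashboard_result(models: list[QueryModel], store: SemanticStore) -> list[dict]:
    """Run aggregation queries and shape results as labelled key-value tables."""
    out = []
    for i, model in enumerate(models):
        if model.aggregation is None:
            raise QueryValidationError("dashboard queries must aggregate")
        rows = run_query(model, store)
        group_key = next(k for k in (rows[0].keys() if rows else ["agg", "x"])
                         if k != "agg")
        pairs = []
        for row in rows:
            key = row.get(group_key)
            if isinstance(key, str) and key.startswith("http"):
                key = local_name(key, store.ontology.namespace)
            value = row.get("agg")
            pairs.append((str(key), float(value) if value is not None else 0.0))
        pairs.sort(key=lambda kv: kv[0])
        out.append({"label": model.name or f"query-{i}", "rows": pairs})
    return out
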