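"""Registry-to-RDF transformation and the SPARQL-queriable semantic store.

The transformation follows a three-step scheme: declarative mapping rules
(CSV table/column -> ontology class/property), generation of the RDF
individuals, and import into a queriable store.  The store is an in-memory
graph with Turtle / N-Triples persistence; every individual carries exactly
one asserted most-specific type, and emitted triples are validated
structurally against the ontology's domains and ranges (no DL reasoner).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import importlib.resources
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import pandas as pd
import rdflib
import yaml
from rdflib import RDF, XSD, Literal, URIRef

from .errors import MappingError, OncoregError, QueryValidationError, ReferentialIntegrityError
from .ontology import OntologyModel, load_ontology, local_name
from .registry import Registry


@dataclass
class LinkRule:
    column: str
    table: str
    property: str
    inverse: str | None = None
    via_table: str | None = None   # chained links follow via_column into via_table
    via_column: str | None = None


@dataclass
class TypedIndividualRule:
    column: str
    property: str
    prefix: str


@dataclass
class TableRule:
    cls: str
    key: str
    datatype: dict[str, str] = field(default_factory=dict)
    class_column: str | None = None
    links: list[LinkRule] = field(default_factory=list)
    typed_individuals: list[TypedIndividualRule] = field(default_factory=list)


@dataclass
class MappingRules:
    namespace: str
    tables: dict[str, TableRule]

    @classmethod
    def load(cls, path=None) -> "MappingRules":
        if path is None:
            ref = importlib.resources.files("oncoreg.data") / "mapping_rules.yaml"
            raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        else:
            with open(path, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        tables = {}
        for name, spec in raw["tables"].items():
            tables[name] = TableRule(
                cls=spec["class"],
                key=spec["key"],
                datatype=dict(spec.get("datatype", {})),
                class_column=spec.get("class_column"),
                links=[LinkRule(**d) for d in spec.get("links", [])]
                + [LinkRule(**d) for d in spec.get("chains", [])],
                typed_individuals=[TypedIndividualRule(**d)
                                   for d in spec.get("typed_individuals", [])],
            )
        return cls(namespace=raw["namespace"], tables=tables)

    def validate(self, ontology: OntologyModel) -> None:
        for name, rule in self.tables.items():
            ontology.require_class(rule.cls)
            for column, prop in rule.datatype.items():
                if not ontology.datatype_property_kinds(prop):
                    raise MappingError(f"{name}.{column}: unknown datatype property {prop}")
            for link in rule.links:
                if not ontology.object_property_pairs(link.property):
                    raise MappingError(f"{name}: unknown object property {link.property}")
                if link.inverse and not ontology.object_property_pairs(link.inverse):
                    raise MappingError(f"{name}: unknown object property {link.inverse}")
            for ti in rule.typed_individuals:
                if not ontology.object_property_pairs(ti.property):
                    raise MappingError(f"{name}: unknown object property {ti.property}")


def individual_iri(namespace: str, table: str, key: str) -> str:
    """Deterministic IRI scheme: <base>/individual/<table>/<key>."""
    return f"{namespace.rstrip('#/')}/individual/{table}/{key}"


@dataclass
class SemanticStore:
    """RDF triples of a transformed registry plus the ontology that typed them."""

    graph: rdflib.Graph
    ontology: OntologyModel
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def namespace(self) -> str:
        return self.ontology.namespace

    def execute_sparql(self, query: str) -> list[dict]:
        """Run a SPARQL 1.1 SELECT; rows are dicts of variable -> python value."""
        try:
            result = self.graph.query(query)
        except Exception as exc:
            raise QueryValidationError(f"SPARQL error: {exc}") from exc
        rows = []
        variables = [str(v) for v in result.vars or []]
        for binding in result:
            row = {}
            for var in variables:
                term = binding[var] if var in binding.asdict() else None
                row[var] = term.toPython() if term is not None else None
                if isinstance(row[var], Decimal):
                    row[var] = float(row[var])
                elif isinstance(row[var], (dt.date, dt.datetime)):
                    row[var] = row[var].isoformat()
            rows.append(row)
        return rows

    def count_class(self, cls: str) -> int:
        """COUNT of distinct individuals over the subclass closure of *cls*."""
        from .ontology import subclass_closure
        closure = subclass_closure(self.ontology, cls)
        values = ", ".join(f"<{c}>" for c in closure)
        rows = self.execute_sparql(
            "SELECT (COUNT(DISTINCT ?s) AS ?n) WHERE "
            f"{{?s <{RDF.type}> ?t FILTER (?t IN ({values}))}}"
        )
        return int(rows[0]["n"] or 0)

    def digest(self) -> str:
        """SHA-256 of the canonically sorted N-Triples serialisation."""
        lines = sorted(self.graph.serialize(format="nt").splitlines())
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()


_XSD_BY_KIND = {"integer": XSD.integer, "decimal": XSD.decimal, "date": XSD.date}


def _literal(value: str, kind: str) -> Literal:
    if kind == "integer":
        return Literal(int(value))
    if kind == "decimal":
        return Literal(Decimal(value), datatype=XSD.decimal)
    if kind == "date":
        return Literal(value, datatype=XSD.date)
    return Literal(str(value))


def transform(registry: Registry, rules: MappingRules | None = None,
              ontology: OntologyModel | None = None) -> SemanticStore:
    """Generate the semantic store from registry tables via mapping rules.

    One individual per row, typed with its most-specific class (the
    ``class_column`` value when present); foreign keys become object
    properties with their configured inverses.  Dangling keys raise
    :class:`ReferentialIntegrityError` naming the row; unknown therapy or
    course classes raise :class:`MappingError`.
    """
    ontology = ontology or load_ontology()
    rules = rules or MappingRules.load()
    rules.validate(ontology)
    ns = rules.namespace

    graph = rdflib.Graph()
    graph.bind("ods", ns)
    tables = registry.tables()
    keys: dict[str, set[str]] = {
        name: set(frame[rules.tables[name].key]) if name in rules.tables else set()
        for name, frame in tables.items()
    }

    provenance = {}
    for name, frame in tables.items():
        provenance[name] = hashlib.sha256(
            frame.to_csv(index=False).encode()
        ).hexdigest()

    for name, rule in rules.tables.items():
        frame = tables[name]
        if frame[rule.key].duplicated().any():
            raise MappingError(f"key column {rule.key} of {name} is not unique")
        kinds = {col: next(iter(ontology.datatype_property_kinds(prop)))
                 for col, prop in rule.datatype.items()}
        via_maps = {}
        for link in rule.links:
            if link.via_table:
                via = tables[link.via_table]
                via_key = rules.tables[link.via_table].key
                via_maps[(link.via_table, link.column)] = dict(
                    zip(via[via_key], via[link.column])
                )

        for _, row in frame.iterrows():
            key = str(row[rule.key])
            subject = URIRef(individual_iri(ns, name, key))

            cls = rule.cls
            if rule.class_column:
                cls = str(row[rule.class_column])
                if not ontology.has_class(cls) or not ontology.is_subclass_of(cls, rule.cls):
                    raise MappingError(
                        f"{name} row {key}: class {cls!r} is not a subclass of {rule.cls}"
                    )
            graph.add((subject, RDF.type, URIRef(ontology.iri(cls))))

            for column, prop in rule.datatype.items():
                value = row[column]
                if value is None or str(value) == "" or pd.isna(value):
                    continue
                graph.add((subject, URIRef(ontology.iri(prop)), _literal(str(value), kinds[column])))

            for link in rule.links:
                if link.via_table:
                    via_value = str(row[link.via_column])
                    lookup = via_maps[(link.via_table, link.column)]
                    if via_value not in lookup:
                        raise ReferentialIntegrityError(
                            f"{name} row {key}: {link.via_column} {via_value!r} "
                            f"not found in {link.via_table}"
                        )
                    target_key = str(lookup[via_value])
                else:
                    target_key = str(row[link.column])
                if target_key not in keys[link.table]:
                    raise ReferentialIntegrityError(
                        f"{name} row {key}: {link.column} {target_key!r} "
                        f"not found in {link.table}"
                    )
                target = URIRef(individual_iri(ns, link.table, target_key))
                graph.add((subject, URIRef(ontology.iri(link.property)), target))
                if link.inverse:
                    graph.add((target, URIRef(ontology.iri(link.inverse)), subject))

            for ti in rule.typed_individuals:
                value = str(row[ti.column])
                if not value:
                    continue
                if not ontology.has_class(value):
                    raise MappingError(
                        f"{name} row {key}: {ti.column} value {value!r} is not an ontology class"
                    )
                helper = URIRef(individual_iri(ns, ti.prefix, key))
                graph.add((helper, RDF.type, URIRef(ontology.iri(value))))
                graph.add((subject, URIRef(ontology.iri(ti.property)), helper))

    store = SemanticStore(graph=graph, ontology=ontology, provenance=provenance)
    _validate_structure(store)
    return store


def _validate_structure(store: SemanticStore) -> None:
    """Domain/range conformance of every object triple; no untyped individuals."""
    graph, onto = store.graph, store.ontology
    types = {s: str(o) for s, _, o in graph.triples((None, RDF.type, None))}
    obj_props = {p for p, _, _ in onto.object_properties}
    cache: dict[tuple[str, str, str], bool] = {}
    for s, p, o in graph:
        if str(p) not in obj_props:
            continue
        if s not in types or o not in types:
            raise MappingError(f"untyped individual in triple {s} {local_name(str(p))} {o}")
        sig = (str(p), types[s], types[o])
        if sig not in cache:
            cache[sig] = any(
                onto.is_subclass_of(types[s], dom) and onto.is_subclass_of(types[o], rng)
                for dom, rng in onto.object_property_pairs(str(p))
            )
        if not cache[sig]:
            raise MappingError(f"triple violates domain/range: {s} {local_name(str(p))} {o}")


def save_store(store: SemanticStore, path) -> None:
    """Serialise to Turtle (.ttl) or N-Triples (.nt), by extension."""
    path = Path(path)
    fmt = "nt" if path.suffix == ".nt" else "turtle"
    store.graph.serialize(destination=str(path), format=fmt)


def load_store(path, ontology: OntologyModel | None = None) -> SemanticStore:
    path = Path(path)
    graph = rdflib.Graph()
    fmt = "nt" if path.suffix == ".nt" else "turtle"
    try:
        graph.parse(str(path), format=fmt)
    except Exception as exc:
        raise OncoregError(f"cannot parse store {path}: {exc}") from exc
    return SemanticStore(graph=graph, ontology=ontology or load_ontology())
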