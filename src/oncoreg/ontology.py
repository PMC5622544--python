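"""Cancer-registry ontology: loading, lookup and subclass closure.

The toolkit ships a minimal self-contained OWL ontology (Turtle) with the
record classes (Patient, Patient_condition, Diagnosis, Therapy,
Disease_course), a therapy-kind taxonomy, disease-course kinds, cancer
pathological structures and a small ICD-10 subset.  The in-memory
:class:`OntologyModel` drives CSV-to-RDF transformation, query validation
and subclass expansion of type filters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import rdflib
from rdflib import OWL, RDF, RDFS, XSD

from .errors import OntologyFormatError, OntologySchemaError, UnknownEntityError

#: Default namespace of the shipped ontology.
DEFAULT_NAMESPACE = "http://www.imib.es/ontologies/disease-times#"

#: Classes every usable registry ontology must declare.
CORE_CLASSES = ("Patient", "Diagnosis", "Therapy", "Disease_course", "Patient_condition")

_XSD_KINDS = {
    XSD.string: "string",
    XSD.integer: "integer",
    XSD.decimal: "decimal",
    XSD.date: "date",
}


def local_name(iri: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Strip the namespace (or any fragment/path prefix) from an IRI."""
    if iri.startswith(namespace):
        return iri[len(namespace):]
    for sep in ("#", "/"):
        if sep in iri:
            return iri.rsplit(sep, 1)[1]
    return iri


@dataclass
class OntologyModel:
    """Declarative view of the registry ontology.

    Properties may carry several alternative domains (the draft ontology
    reuses e.g. ``date`` on both Diagnosis and Disease_course); domain and
    range checks therefore use any-of semantics.
    """

    namespace: str = DEFAULT_NAMESPACE
    classes: set[str] = field(default_factory=set)
    datatype_properties: set[tuple[str, str, str]] = field(default_factory=set)
    object_properties: set[tuple[str, str, str]] = field(default_factory=set)
    subclass_edges: dict[str, set[str]] = field(default_factory=dict)

    # -- lookup helpers ----------------------------------------------------

    def iri(self, name: str) -> str:
        """Full IRI of a class/property given its local name (idempotent)."""
        return name if name.startswith("http") else self.namespace + name

    def has_class(self, name_or_iri: str) -> bool:
        return self.iri(name_or_iri) in self.classes

    def require_class(self, name_or_iri: str) -> str:
        iri = self.iri(name_or_iri)
        if iri not in self.classes:
            raise UnknownEntityError(f"unknown ontology class: {name_or_iri}")
        return iri

    def parent_of(self, iri: str) -> str | None:
        for parent, children in self.subclass_edges.items():
            if iri in children:
                return parent
        return None

    def ancestors(self, iri: str) -> set[str]:
        """All strict superclasses of *iri*."""
        out: set[str] = set()
        cur = self.parent_of(iri)
        while cur is not None and cur not in out:
            out.add(cur)
            cur = self.parent_of(cur)
        return out

    def is_subclass_of(self, sub: str, sup: str) -> bool:
        sub, sup = self.iri(sub), self.iri(sup)
        return sub == sup or sup in self.ancestors(sub)

    def datatype_property_kinds(self, prop: str) -> set[str]:
        prop = self.iri(prop)
        return {kind for p, _, kind in self.datatype_properties if p == prop}

    def datatype_property_domains(self, prop: str) -> set[str]:
        prop = self.iri(prop)
        return {dom for p, dom, _ in self.datatype_properties if p == prop}

    def object_property_pairs(self, prop: str) -> set[tuple[str, str]]:
        prop = self.iri(prop)
        return {(dom, rng) for p, dom, rng in self.object_properties if p == prop}

    def property_applies(self, prop: str, cls: str) -> bool:
        """True if *prop* (datatype or object) has a domain covering *cls*."""
        cls = self.iri(cls)
        domains = self.datatype_property_domains(prop) | {
            dom for dom, _ in self.object_property_pairs(prop)
        }
        return any(self.is_subclass_of(cls, dom) for dom in domains)


def load_ontology(path=None) -> OntologyModel:
    """Parse a Turtle ontology file into an :class:`OntologyModel`.

    With no argument the ontology shipped with the package is loaded.
    Raises :class:`OntologyFormatError` on unparseable input and
    :class:`OntologySchemaError` when a core registry class is missing.
    """
    graph = rdflib.Graph()
    try:
        if path is None:
            ref = importlib.resources.files("oncoreg.data") / "ontology.ttl"
            graph.parse(data=ref.read_text(encoding="utf-8"), format="turtle")
        else:
            graph.parse(str(path), format="turtle")
    except Exception as exc:  # rdflib raises several parser exception types
        raise OntologyFormatError(f"cannot parse ontology: {exc}") from exc

    namespace = _detect_namespace(graph)
    model = OntologyModel(namespace=namespace)

    for cls in graph.subjects(RDF.type, OWL.Class):
        model.classes.add(str(cls))

    for parent_term in set(graph.objects(None, RDFS.subClassOf)):
        parent = str(parent_term)
        children = {str(c) for c in graph.subjects(RDFS.subClassOf, parent_term)}
        model.subclass_edges.setdefault(parent, set()).update(children)

    for prop in graph.subjects(RDF.type, OWL.DatatypeProperty):
        ranges = list(graph.objects(prop, RDFS.range))
        kind = _XSD_KINDS.get(ranges[0], "string") if ranges else "string"
        for dom in graph.objects(prop, RDFS.domain):
            model.datatype_properties.add((str(prop), str(dom), kind))

    for prop in graph.subjects(RDF.type, OWL.ObjectProperty):
        for dom in graph.objects(prop, RDFS.domain):
            for rng in graph.objects(prop, RDFS.range):
                model.object_properties.add((str(prop), str(dom), str(rng)))

    _validate(model)
    return model


def _detect_namespace(graph: rdflib.Graph) -> str:
    for prefix, ns in graph.namespaces():
        if prefix == "ods":
            return str(ns)
    return DEFAULT_NAMESPACE


def _validate(model: OntologyModel) -> None:
    missing = [c for c in CORE_CLASSES if not model.has_class(c)]
    if missing:
        raise OntologySchemaError(
            f"ontology is missing core registry classes: {', '.join(missing)}"
        )
    for parent, children in model.subclass_edges.items():
        for child in children:
            if parent in {child} | _all_descendants(model, child):
                raise OntologySchemaError(f"subclass cycle through {parent}")
    for prop, dom, rng in model.object_properties:
        for target, role in ((dom, "domain"), (rng, "range")):
            if target not in model.classes:
                raise OntologySchemaError(
                    f"object property {prop} has undeclared {role} {target}"
                )
    for prop, dom, _ in model.datatype_properties:
        if dom not in model.classes:
            raise OntologySchemaError(
                f"datatype property {prop} has undeclared domain {dom}"
            )


def _all_descendants(model: OntologyModel, iri: str) -> set[str]:
    out: set[str] = set()
    stack = [iri]
    while stack:
        for child in model.subclass_edges.get(stack.pop(), ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def subclass_closure(model: OntologyModel, root: str) -> list[str]:
    """Root plus all transitive subclasses, in deterministic order.

    Order is the root first, then a pre-order depth-first traversal with
    lexicographic (local-name) tie-break among siblings — the order in which
    type filters enumerate a class hierarchy.
    """
    root = model.require_class(root)
    out: list[str] = []

    def visit(iri: str) -> None:
        out.append(iri)
        children = sorted(
            model.subclass_edges.get(iri, ()),
            key=lambda c: local_name(c, model.namespace),
        )
        for child in children:
            visit(child)

    visit(root)
    return out
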