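"""Semantic profiles, per-patient disease timelines and group timeline matrices.

A *semantic profile* is the subset of an individual's datatype values and
linked individuals selected for an analysis: SP(i) = S(d) u S(SP(o)), where
S(d) picks datatype properties and S(SP(o)) recursively profiles the
individuals reached through object properties.  Extraction is guarded
against cycles by a path-based visited set plus a depth bound.

A *disease timeline* normalises a patient's events to calendar months
counted from each diagnosis date: therapies cover every month their span
overlaps, the disease course contributes at most one kind per month (the
event with the higher order wins), and the Karnofsky index is read off the
patient conditions.  Group matrices count, per (month, event category), the
patients of a selection whose timeline shows that category, and can be
re-filtered by a condition on a cell (or on the first therapy) to the
satisfying subgroup.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd
from rdflib import RDF, URIRef

from .dates import month_index, parse_date
from .errors import DataError, QueryValidationError, UnknownEntityError
from .ontology import local_name, subclass_closure
from .rdf_store import SemanticStore

NO_COURSE = None


# ---------------------------------------------------------------------------
# semantic profiles


@dataclass
class PropertySelection:
    """Which properties a profile keeps: S(d) and the nested S(SP(o))."""

    datatype_props: set[str] = field(default_factory=set)
    object_props: dict[str, "PropertySelection"] = field(default_factory=dict)
    max_depth: int = 4


@dataclass
class SemanticProfile:
    subject: str
    values: dict[str, list] = field(default_factory=dict)
    links: dict[str, list["SemanticProfile"]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "values": self.values,
            "links": {p: [q.to_dict() for q in subs] for p, subs in self.links.items()},
        }


def extract_profile(store: SemanticStore, subject: str,
                    sel: PropertySelection) -> SemanticProfile:
    """Extract SP(subject) under the selection; terminates on any finite graph."""
    node = URIRef(subject)
    if (node, None, None) not in store.graph:
        raise UnknownEntityError(f"no individual {subject} in the store")
    return _extract(store, node, sel, depth=1, path=frozenset())


def _extract(store, node, sel, depth, path) -> SemanticProfile:
    onto = store.ontology
    profile = SemanticProfile(subject=str(node))
    for prop in sorted(sel.datatype_props):
        values = [o.toPython() for o in store.graph.objects(node, URIRef(onto.iri(prop)))]
        if values:
            profile.values[prop] = sorted(map(str, values))
    if depth >= sel.max_depth:
        return profile
    for prop, nested in sorted(sel.object_props.items()):
        subs = []
        for obj in sorted(store.graph.objects(node, URIRef(onto.iri(prop)))):
            if str(obj) in path or obj == node:
                continue  # cycle guard: never revisit an IRI on the current path
            nested_sel = replace(nested, max_depth=sel.max_depth)
            subs.append(_extract(store, obj, nested_sel, depth + 1,
                                 path | {str(node)}))
        if subs:
            profile.links[prop] = subs
    return profile


# ---------------------------------------------------------------------------
# individual timelines


@dataclass
class MonthCell:
    therapies: list[str] = field(default_factory=list)  # therapy class local names
    course: str | None = NO_COURSE
    karnofsky: int | None = None


@dataclass
class DiagnosisTimeline:
    diagnosis: str
    icd10_code: str
    pathology: str | None
    date: dt.date
    last_encounter: dt.date
    months: dict[int, MonthCell] = field(default_factory=dict)

    @property
    def first_therapy_month(self) -> int | None:
        months = [m for m, c in sorted(self.months.items()) if c.therapies]
        return months[0] if months else None

    def categories_at(self, month: int) -> set[str]:
        cell = self.months.get(month)
        if cell is None:
            return set()
        out = set(cell.therapies)
        if cell.course:
            out.add(cell.course)
        return out


@dataclass
class PatientTimeline:
    patient: str
    diagnoses: list[DiagnosisTimeline] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient": self.patient,
            "diagnoses": [
                {
                    "diagnosis": d.diagnosis, "icd10_code": d.icd10_code,
                    "pathology": d.pathology, "date": d.date.isoformat(),
                    "last_encounter": d.last_encounter.isoformat(),
                    "months": {
                        str(m): {
                            "therapies": c.therapies, "course": c.course,
                            "karnofsky": c.karnofsky,
                        } for m, c in sorted(d.months.items())
                    },
                } for d in self.diagnoses
            ],
        }


def _one(graph, s, p):
    for o in graph.objects(s, p):
        return o
    return None


def build_timeline(store: SemanticStore, patient: str) -> PatientTimeline:
    """Normalise a patient's diagnoses, therapies, courses and Karnofsky
    readings into month-indexed timelines (0 = diagnosis month)."""
    onto = store.ontology
    graph = store.graph
    p = URIRef(patient)
    iri = onto.iri
    if (p, RDF.type, URIRef(iri("Patient"))) not in graph:
        raise UnknownEntityError(f"{patient} is not a Patient in the store")

    conditions = []
    for cond in graph.objects(p, URIRef(iri("hasPatientCondition"))):
        ref = _one(graph, cond, URIRef(iri("ref_date")))
        karno = _one(graph, cond, URIRef(iri("karnofsky")))
        if ref is not None:
            conditions.append((parse_date(ref.toPython()),
                               int(karno.toPython()) if karno is not None else None))

    timelines = []
    for dx in graph.objects(p, URIRef(iri("hasDiagnosis"))):
        date_term = _one(graph, dx, URIRef(iri("date")))
        if date_term is None:
            raise DataError(f"diagnosis {dx} has no date")
        dx_date = parse_date(date_term.toPython())
        code = _one(graph, dx, URIRef(iri("icd10_code")))
        pathology = _one(graph, dx, URIRef(iri("hasPathologicalStructure")))
        pathology_cls = None
        if pathology is not None:
            ptype = _one(graph, pathology, RDF.type)
            pathology_cls = local_name(str(ptype), onto.namespace) if ptype else None

        tl = DiagnosisTimeline(
            diagnosis=str(dx), icd10_code=str(code) if code else "",
            pathology=pathology_cls, date=dx_date, last_encounter=dx_date,
        )

        def cell(m: int) -> MonthCell:
            return tl.months.setdefault(m, MonthCell())

        for tx in graph.objects(dx, URIRef(iri("hasTherapy"))):
            ttype = _one(graph, tx, RDF.type)
            start = _one(graph, tx, URIRef(iri("start_date")))
            end = _one(graph, tx, URIRef(iri("end_date")))
            if ttype is None or start is None or end is None:
                continue
            cls = local_name(str(ttype), onto.namespace)
            m0 = max(0, month_index(parse_date(start.toPython()), dx_date))
            m1 = month_index(parse_date(end.toPython()), dx_date)
            for m in range(m0, m1 + 1):
                c = cell(m)
                if cls not in c.therapies:
                    c.therapies.append(cls)
            tl.last_encounter = max(tl.last_encounter, parse_date(end.toPython()))

        events = []
        for course in graph.objects(dx, URIRef(iri("hasDiseaseCourse"))):
            ctype = _one(graph, course, RDF.type)
            cdate = _one(graph, course, URIRef(iri("date")))
            order = _one(graph, course, URIRef(iri("order")))
            if ctype is None or cdate is None:
                continue
            events.append((
                int(order.toPython()) if order is not None else 0,
                parse_date(cdate.toPython()),
                local_name(str(ctype), onto.namespace),
            ))
        for order, cdate, kind in sorted(events):
            m = month_index(cdate, dx_date)
            if m >= 0:
                cell(m).course = kind  # ties: the higher order wins (sorted order)
            tl.last_encounter = max(tl.last_encounter, cdate)

        for ref_date, karno in sorted(conditions):
            m = month_index(ref_date, dx_date)
            if m >= 0 and karno is not None:
                cell(m).karnofsky = karno
            tl.last_encounter = max(tl.last_encounter, ref_date)

        for c in tl.months.values():
            c.therapies.sort()
        timelines.append(tl)

    timelines.sort(key=lambda t: (t.date, t.diagnosis))
    return PatientTimeline(patient=patient, diagnoses=timelines)


# ---------------------------------------------------------------------------
# group matrices


@dataclass
class TimelineMatrix:
    """Months x event-category patient counts for a group selection."""

    group: frozenset[str]
    max_month: int
    cells: dict[tuple[int, str], int]
    categories: list[str]
    diagnosis_filter: str | None = None
    empty: bool = False
    _timelines: dict[str, DiagnosisTimeline] = field(default_factory=dict, repr=False)

    def count(self, month: int, category: str) -> int:
        return self.cells.get((month, category), 0)

    def to_frame(self) -> pd.DataFrame:
        """Long format: month, category, count (only non-zero cells)."""
        rows = [
            {"month": m, "category": c, "count": n}
            for (m, c), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["month", "category", "count"])


def _matching_timeline(timeline: PatientTimeline, store: SemanticStore,
                       diagnosis_filter: str | None) -> DiagnosisTimeline | None:
    if not timeline.diagnoses:
        return None
    if diagnosis_filter is None:
        return timeline.diagnoses[0]
    allowed = {
        local_name(c, store.ontology.namespace)
        for c in subclass_closure(store.ontology, diagnosis_filter)
    }
    for tl in timeline.diagnoses:  # earliest matching diagnosis
        if tl.pathology in allowed:
            return tl
    return None


def aggregate_timelines(store: SemanticStore, group,
                        diagnosis_filter: str | None = None) -> TimelineMatrix:
    """Aggregate the timelines of a patient group into a count matrix.

    ``group`` is any iterable of patient IRIs (typically a query result);
    ``diagnosis_filter`` restricts each patient to their earliest diagnosis
    of that pathology class (subclass closure applies).
    """
    group = sorted(set(map(str, group)))
    if not group:
        raise QueryValidationError("cannot aggregate an empty patient group")
    selected: dict[str, DiagnosisTimeline] = {}
    for patient in group:
        tl = _matching_timeline(build_timeline(store, patient), store, diagnosis_filter)
        if tl is not None:
            selected[patient] = tl
    return _matrix_from_timelines(selected, diagnosis_filter)


def _matrix_from_timelines(selected: dict[str, DiagnosisTimeline],
                           diagnosis_filter: str | None) -> TimelineMatrix:
    cells: dict[tuple[int, str], int] = {}
    max_month = 0
    for tl in selected.values():
        if tl.months:
            max_month = max(max_month, max(tl.months))
        for m in tl.months:
            for cat in tl.categories_at(m):
                cells[(m, cat)] = cells.get((m, cat), 0) + 1
    return TimelineMatrix(
        group=frozenset(selected),
        max_month=max_month,
        cells=cells,
        categories=sorted({c for _, c in cells}),
        diagnosis_filter=diagnosis_filter,
        empty=not selected,
        _timelines=selected,
    )


def refilter_matrix(matrix: TimelineMatrix, condition: tuple) -> TimelineMatrix:
    """Recompute the matrix over the subgroup satisfying *condition*.

    ``condition`` is ``(month, category)`` — the category is active or
    occurring at that month — or ``("first", category)`` — the patient's
    first therapy month includes that therapy class.  A condition nobody
    satisfies yields a zero matrix flagged ``empty`` rather than an error.
    """
    when, category = condition
    kept: dict[str, DiagnosisTimeline] = {}
    for patient, tl in matrix._timelines.items():
        if when == "first":
            m = tl.first_therapy_month
            ok = m is not None and category in tl.months[m].therapies
        else:
            ok = category in tl.categories_at(int(when))
        if ok:
            kept[patient] = tl
    return _matrix_from_timelines(kept, matrix.diagnosis_filter)
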