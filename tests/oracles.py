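"""Independent oracles for the test suite.

``RowOracle`` evaluates a QueryModel directly against the registry
DataFrames — straightforward nested-loop filtering with existential link
semantics — without touching RDF or SPARQL, so it can cross-check the
compile-and-execute path.  ``random_model`` draws randomised but valid
query models over the registry vocabulary.
"""

from __future__ import annotations

from oncoreg.ontology import local_name, subclass_closure
from oncoreg.query import Aggregation, Filter, Link, QueryModel
from oncoreg.rdf_store import individual_iri

# property -> column per table; None marks object links handled in _neighbors
_NUMERIC_COLS = {"age", "karnofsky", "asa", "order"}
_FLOAT_COLS = {"weight_kg", "height_cm"}

_COLUMNS = {
    "patients": {"gender": "gender", "birth_date": "birth_date", "age": "age"},
    "conditions": {
        "ref_date": "ref_date", "age": "age", "weight_kg": "weight_kg",
        "height_cm": "height_cm", "karnofsky": "karnofsky", "asa": "asa",
        "menopause_status": "menopause_status",
    },
    "diagnoses": {
        "icd10_code": "icd10_code", "grading": "grading", "tnm_t": "tnm_t",
        "tnm_n": "tnm_n", "tnm_m": "tnm_m", "date": "date",
        "tumor_type": "tumor_type",
    },
    "therapies": {
        "medication": "medication", "start_date": "start_date",
        "end_date": "end_date",
    },
    "courses": {"stage": "stage", "order": "order", "date": "date"},
    "pathology": {},
    "anatomy": {},
}


class RowOracle:
    """Direct-filter evaluation of query models over registry tables."""

    def __init__(self, registry, ontology):
        self.onto = ontology
        self.ns = ontology.namespace
        t = registry.tables()
        self.rows = {name: {str(r[k]): r for r in frame.to_dict("records")}
                     for name, frame, k in (
                         ("patients", t["patients"], "patient_id"),
                         ("conditions", t["conditions"], "condition_id"),
                         ("diagnoses", t["diagnoses"], "diagnosis_id"),
                         ("therapies", t["therapies"], "therapy_id"),
                         ("courses", t["courses"], "course_id"),
                     )}
        self.dx_of_patient: dict[str, list[str]] = {}
        for did, row in self.rows["diagnoses"].items():
            self.dx_of_patient.setdefault(str(row["patient_id"]), []).append(did)
        self.tx_of_dx: dict[str, list[str]] = {}
        for tid, row in self.rows["therapies"].items():
            self.tx_of_dx.setdefault(str(row["diagnosis_id"]), []).append(tid)
        self.course_of_dx: dict[str, list[str]] = {}
        for cid, row in self.rows["courses"].items():
            self.course_of_dx.setdefault(str(row["diagnosis_id"]), []).append(cid)
        self.cond_of_patient: dict[str, list[str]] = {}
        for cid, row in self.rows["conditions"].items():
            self.cond_of_patient.setdefault(str(row["patient_id"]), []).append(cid)
        self._closure_cache: dict[str, set[str]] = {}

    # -- ontology helpers --------------------------------------------------

    def closure_names(self, cls: str) -> set[str]:
        if cls not in self._closure_cache:
            self._closure_cache[cls] = {
                local_name(c, self.ns) for c in subclass_closure(self.onto, cls)
            }
        return self._closure_cache[cls]

    def type_of(self, ind) -> str:
        table, _, row = ind
        return {
            "patients": lambda r: "Patient",
            "conditions": lambda r: "Patient_condition",
            "diagnoses": lambda r: "Diagnosis",
            "therapies": lambda r: str(r["therapy_class"]),
            "courses": lambda r: str(r["course_kind"]),
            "pathology": lambda r: str(r["pathological_structure"]),
            "anatomy": lambda r: str(r["anatomical_structure"]),
        }[table](row)

    def roots(self, root_cls: str):
        names = self.closure_names(root_cls)
        root_local = local_name(self.onto.iri(root_cls), self.ns)
        if root_local == "Patient":
            pool = [("patients", k, r) for k, r in self.rows["patients"].items()]
        elif root_local == "Diagnosis":
            pool = [("diagnoses", k, r) for k, r in self.rows["diagnoses"].items()]
        elif root_local == "Patient_condition":
            pool = [("conditions", k, r) for k, r in self.rows["conditions"].items()]
        elif root_local in self.closure_names("Therapy"):
            pool = [("therapies", k, r) for k, r in self.rows["therapies"].items()]
        elif root_local in self.closure_names("Disease_course"):
            pool = [("courses", k, r) for k, r in self.rows["courses"].items()]
        elif root_local in self.closure_names("Pathological_structure"):
            pool = [("pathology", k, r) for k, r in self.rows["diagnoses"].items()
                    if str(r["pathological_structure"])]
        else:
            raise ValueError(f"oracle does not know root class {root_cls}")
        return [ind for ind in pool if self.type_of(ind) in names]

    # -- graph navigation --------------------------------------------------

    def _neighbors(self, ind, prop: str):
        table, key, row = ind
        R = self.rows
        if table == "patients":
            if prop == "hasDiagnosis":
                return [("diagnoses", d, R["diagnoses"][d])
                        for d in self.dx_of_patient.get(key, [])]
            if prop == "hasTherapy":
                return [("therapies", t, R["therapies"][t])
                        for d in self.dx_of_patient.get(key, [])
                        for t in self.tx_of_dx.get(d, [])]
            if prop == "hasPatientCondition":
                return [("conditions", c, R["conditions"][c])
                        for c in self.cond_of_patient.get(key, [])]
        elif table == "diagnoses":
            if prop == "hasPatient":
                pid = str(row["patient_id"])
                return [("patients", pid, R["patients"][pid])]
            if prop == "hasTherapy":
                return [("therapies", t, R["therapies"][t])
                        for t in self.tx_of_dx.get(key, [])]
            if prop == "hasDiseaseCourse":
                return [("courses", c, R["courses"][c])
                        for c in self.course_of_dx.get(key, [])]
            if prop == "hasPathologicalStructure":
                return [("pathology", key, row)] if str(row["pathological_structure"]) else []
            if prop == "hasAnatomicalStructure":
                return [("anatomy", key, row)] if str(row["anatomical_structure"]) else []
        elif table == "therapies":
            if prop == "hasDiagnosis":
                did = str(row["diagnosis_id"])
                return [("diagnoses", did, R["diagnoses"][did])]
            if prop == "hasPatient":
                did = str(row["diagnosis_id"])
                pid = str(R["diagnoses"][did]["patient_id"])
                return [("patients", pid, R["patients"][pid])]
        elif table == "courses":
            if prop == "hasDiagnosis":
                did = str(row["diagnosis_id"])
                return [("diagnoses", did, R["diagnoses"][did])]
        elif table == "conditions":
            if prop == "hasPatient":
                pid = str(row["patient_id"])
                return [("patients", pid, R["patients"][pid])]
        return []

    # -- evaluation --------------------------------------------------------

    def _filter_ok(self, ind, flt: Filter) -> bool:
        table, _, row = ind
        column = _COLUMNS[table].get(flt.prop)
        if column is None:
            return False
        raw = row.get(column)
        if raw is None or str(raw) == "":
            return False
        if column in _NUMERIC_COLS:
            value = int(raw)
        elif column in _FLOAT_COLS:
            value = float(raw)
        else:
            value = str(raw)
            if flt.op == "=":
                return value == str(flt.value)
            return value != str(flt.value)
        ops = {
            "=": value == flt.value, "!=": value != flt.value,
            "<": value < flt.value, "<=": value <= flt.value,
            ">": value > flt.value, ">=": value >= flt.value,
        }
        return ops[flt.op]

    def _satisfies(self, ind, constraints) -> bool:
        for c in constraints:
            if isinstance(c, Filter):
                if not self._filter_ok(ind, c):
                    return False
            else:
                allowed = self.closure_names(c.cls)
                if not any(
                    self.type_of(t) in allowed and self._satisfies(t, c.constraints)
                    for t in self._neighbors(ind, c.prop)
                ):
                    return False
        return True

    def evaluate(self, model: QueryModel) -> set[str]:
        """IRIs of the root individuals matching the model (no aggregation)."""
        out = set()
        for ind in self.roots(model.root_cls):
            if self._satisfies(ind, model.constraints):
                out.add(individual_iri(self.ns, ind[0], ind[1]))
        return out

    def evaluate_grouped(self, model: QueryModel) -> dict[str, int]:
        """Group label (type IRI) -> distinct root count, mirroring a
        count-distinct aggregation grouped by a node's type variable."""
        agg = model.aggregation
        assert agg is not None and agg.group_prop is None
        groups: dict[str, set[str]] = {}
        for ind in self.roots(model.root_cls):
            if not self._satisfies(ind, model.constraints):
                continue
            iri = individual_iri(self.ns, ind[0], ind[1])
            for label in self._group_types(ind, model.constraints, agg.group_node):
                groups.setdefault(label, set()).add(iri)
        return {k: len(v) for k, v in groups.items()}

    def _group_types(self, ind, constraints, path) -> set[str]:
        if not path:
            return {self.onto.iri(self.type_of(ind))}
        link = constraints[path[0]]
        allowed = self.closure_names(link.cls)
        out: set[str] = set()
        for t in self._neighbors(ind, link.prop):
            if self.type_of(t) in allowed and self._satisfies(t, link.constraints):
                out |= self._group_types(t, link.constraints, path[1:])
        return out


# ---------------------------------------------------------------------------
# randomised model generation


_CANCER_CLASSES = ["Colorectal_cancer", "Lung_cancer", "Breast_cancer",
                   "Prostate_cancer", "Melanoma", "Pharynx_cancer"]
_THERAPY_CLASSES = ["Therapy", "DrugTherapy", "Radiotherapy", "Chemotherapy",
                    "Teletherapy", "SurgicalTreatment", "Immunotherapy",
                    "Brachytherapy", "Wait_and_see"]
_COURSE_CLASSES = ["Disease_course", "Progression", "Complete_remission", "Death"]
_ICD10 = ["C18.7", "C20", "C34.1", "C34.9", "C50", "C61", "C43", "C14"]


def _patient_filters(rng):
    out = []
    if rng.random() < 0.6:
        out.append(Filter("age", str(rng.choice([">=", "<=", ">", "<"])),
                          int(rng.integers(30, 86))))
    if rng.random() < 0.5:
        out.append(Filter("gender", "=", str(rng.choice(["M", "F"]))))
    return out


def _diagnosis_constraints(rng):
    out = []
    if rng.random() < 0.7:
        out.append(Link("hasPathologicalStructure", str(rng.choice(_CANCER_CLASSES))))
    if rng.random() < 0.25:
        out.append(Filter("icd10_code", "=", str(rng.choice(_ICD10))))
    if rng.random() < 0.2:
        out.append(Filter("grading", "=", f"G{int(rng.integers(1, 5))}"))
    return out


def random_model(rng) -> QueryModel:
    """A random valid QueryModel over the registry vocabulary (seeded rng)."""
    kind = rng.choice(["patient", "therapy", "diagnosis", "course"],
                      p=[0.4, 0.25, 0.2, 0.15])
    if kind == "patient":
        constraints = _patient_filters(rng)
        if rng.random() < 0.8:
            constraints.append(Link("hasDiagnosis", "Diagnosis",
                                    _diagnosis_constraints(rng)))
        if rng.random() < 0.5:
            constraints.append(Link("hasTherapy", str(rng.choice(_THERAPY_CLASSES))))
        if rng.random() < 0.2:
            constraints.append(Link("hasPatientCondition", "Patient_condition",
                                    [Filter("karnofsky", ">=", int(rng.integers(10, 100)))]))
        return QueryModel("Patient", constraints)
    if kind == "therapy":
        constraints = []
        if rng.random() < 0.7:
            constraints.append(Link("hasDiagnosis", "Diagnosis",
                                    _diagnosis_constraints(rng)))
        if rng.random() < 0.7:
            constraints.append(Link("hasPatient", "Patient", _patient_filters(rng)))
        agg = Aggregation() if rng.random() < 0.4 else None
        return QueryModel(str(rng.choice(_THERAPY_CLASSES)), constraints, aggregation=agg)
    if kind == "diagnosis":
        constraints = _diagnosis_constraints(rng)
        if rng.random() < 0.6:
            constraints.append(Link("hasPatient", "Patient", _patient_filters(rng)))
        if rng.random() < 0.3:
            constraints.append(Link("hasTherapy", str(rng.choice(_THERAPY_CLASSES))))
        agg = Aggregation() if rng.random() < 0.2 else None
        return QueryModel("Diagnosis", constraints, aggregation=agg)
    constraints = []
    if rng.random() < 0.8:
        constraints.append(Link("hasDiagnosis", "Diagnosis", _diagnosis_constraints(rng)))
    return QueryModel(str(rng.choice(_COURSE_CLASSES)), constraints)
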