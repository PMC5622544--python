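"""Ontology-driven query compilation: emission fidelity, execution, templates."""

import importlib.resources
import re

import numpy as np
import pytest

from oncoreg.errors import QueryValidationError
from oncoreg.query import (
    Aggregation,
    DefinedClass,
    Filter,
    Link,
    Param,
    QueryModel,
    build_query,
    dashboard_result,
    defined_class_members,
    load_template,
    register_defined_class,
    run_query,
    save_template,
)
from oracles import RowOracle

# The reference queries of the registry platform, as published (typographic
# quotes/brackets normalised to ASCII; one unbalanced trailing brace in the
# aggregation query's source print dropped).  The fidelity check is on the
# token sequence, so whitespace and the '#' at the namespace boundary are
# immaterial.

REFERENCE_FILTER_QUERY = (
    "PREFIX ods: <http://www.imib.es/ontologies/disease-times> "
    "SELECT DISTINCT ?s WHERE {{?s rdf:type ?t FILTER (?t IN (ods:Patient))}."
    "{{?s ods:hasDiagnosis ?a0.{?a0 rdf:type ?ta0 FILTER (?ta0 IN (ods:Diagnosis))}}. "
    "{?a0 ods:hasPathologicalStructure ?a01.{?a01 rdf:type ?ta01 FILTER "
    "(?ta01 IN (ods:Colorectal_cancer))}}. "
    "{?s ods:gender ?a1. FILTER (str(?a1) = 'M')}."
    "{?s ods:age ?a2. FILTER (?a2 >= 50)}."
    "{?s ods:age ?a3. FILTER (?a3 <= 70)}."
    "{?s ods:hasTherapy ?a4.{?a4 rdf:type ?ta4 FILTER (?ta4 IN (ods:Chemotherapy))}}}}"
)

REFERENCE_DASHBOARD_QUERY = (
    "PREFIX ods: <http://www.imib.es/ontologies/disease-times> "
    "SELECT count(DISTINCT ?s), ?t WHERE"
    "{{?s rdf:type ?t FILTER (?t IN (ods:DrugTherapy, ods:Anti-hormoneTherapy,"
    "ods:Anti-hormonal_anti-androgens, ods:Anti-hormonal_anti-estrogens,"
    "ods:Anti-hormone_therapy_aromatase, ods:Other_Anti-hormoneTherapy,"
    "ods:Chemotherapy, ods:Immunotherapy, ods:OtherdrugTherapy,"
    "ods:Bisphosphonates, ods:Other_med_therapy,"
    "ods:NuclearMedicineTherapy, ods:OpenRadionuclides,"
    "ods:Other_nuclear_medicine_therapy, ods:RadioiodineTherapy,"
    "ods:OtherTherapy, ods:Hyperthermia, ods:Locoregional_hyperthermia,"
    "ods:Part-body_hyperthermia, ods:LightTherapy, ods:OtherLightTherapy,"
    "ods:Selective_ultraviolet_phototherapy, ods:Wait_and_see,"
    "ods:Radiotherapy, ods:Brachytherapy, ods:Interstitial_brachytherapy,"
    "ods:Other_brachytherapy, ods:OtherHigh-voltageRadiotherapy,"
    "ods:High-voltage_radiotherapy_n.n.bez.,"
    "ods:Other_high-voltage_radiotherapy, ods:Whole-body_irradiation,"
    "ods:Teletherapy, ods:OtherTeletherapy, ods:Teletherapy_n.n.bez.,"
    "ods:Teletherapy_with_linear_accelerator, ods:StemCellTransplantation,"
    "ods:AllogeneicSCT, ods:AutologousSCT, ods:SurgicalTreatment,"
    "ods:Therapy))}."
    "{{?s ods:hasDiagnosis ?a0.{?a0 rdf:type ?ta0 FILTER (?ta0 IN (ods:Diagnosis))} }."
    "{?a0 ods:hasPathologicalStructure ?a01.{?a01 rdf:type ?ta01 FILTER "
    "(?ta01 IN (ods:Colorectal_cancer))} }."
    "{?s ods:hasPatient ?a1. {?a1 rdf:type ?ta1 FILTER (?ta1 IN (ods:Patient))} }."
    "{?a1 ods:age ?a12. FILTER (?a12 >= 60)} }} group by ?t"
)

_TOKEN = re.compile(
    r"<[^>]*>|\?\w+|'(?:[^'\\]|\\.)*'|[A-Za-z][\w:.\-]*|\d+(?:\.\d+)?"
    r"|>=|<=|!=|[{}(),.=]|\S"
)


def tokens(query: str) -> list[str]:
    out = _TOKEN.findall(query)
    # the namespace may be written with or without its fragment separator
    return [t[:-2] + ">" if t.startswith("<") and t.endswith("#>") else t
            for t in out]


def filter_model() -> QueryModel:
    return QueryModel("Patient", [
        Link("hasDiagnosis", "Diagnosis",
             [Link("hasPathologicalStructure", "Colorectal_cancer")]),
        Filter("gender", "=", "M"),
        Filter("age", ">=", 50),
        Filter("age", "<=", 70),
        Link("hasTherapy", "Chemotherapy"),
    ])


def dashboard_model() -> QueryModel:
    return QueryModel("Therapy", [
        Link("hasDiagnosis", "Diagnosis",
             [Link("hasPathologicalStructure", "Colorectal_cancer")]),
        Link("hasPatient", "Patient", [Filter("age", ">=", 60)]),
    ], aggregation=Aggregation())


class TestEmissionFidelity:
    def test_filter_query_matches_reference_tokens(self, onto):
        got = tokens(build_query(filter_model(), onto, dialect="display"))
        assert got == tokens(REFERENCE_FILTER_QUERY)

    def test_dashboard_query_matches_reference_tokens(self, onto):
        got = tokens(build_query(dashboard_model(), onto, dialect="display"))
        assert got == tokens(REFERENCE_DASHBOARD_QUERY)

    def test_minimal_query_shape(self, onto):
        q = build_query(QueryModel("Patient", []), onto, dialect="display")
        assert q.endswith(
            "SELECT DISTINCT ?s WHERE {{?s rdf:type ?t FILTER (?t IN (ods:Patient))}}")

    def test_emission_is_byte_deterministic(self, onto):
        for dialect in ("display", "standard"):
            a = build_query(dashboard_model(), onto, dialect=dialect)
            b = build_query(dashboard_model(), onto, dialect=dialect)
            assert a == b


class TestValidation:
    def test_domain_violation_rejected(self, onto):
        model = QueryModel("Patient", [Filter("karnofsky", ">=", 70)])
        with pytest.raises(QueryValidationError, match="does not apply"):
            build_query(model, onto)

    def test_range_violation_rejected(self, onto):
        model = QueryModel("Patient", [Link("hasDiagnosis", "Chemotherapy")])
        with pytest.raises(QueryValidationError, match="range"):
            build_query(model, onto)

    def test_string_literal_on_numeric_property_rejected(self, onto):
        model = QueryModel("Patient", [Filter("age", ">=", "old")])
        with pytest.raises(QueryValidationError, match="numeric"):
            build_query(model, onto)


class TestRunQuery:
    def test_filter_model_matches_oracle(self, registry60, store60, onto):
        oracle = RowOracle(registry60, onto)
        got = {r["s"] for r in run_query(filter_model(), store60)}
        assert got == oracle.evaluate(filter_model())

    def test_aggregation_matches_oracle(self, registry60, store60, onto):
        oracle = RowOracle(registry60, onto)
        got = {str(r["t"]): int(r["agg"]) for r in run_query(dashboard_model(), store60)}
        assert got == oracle.evaluate_grouped(dashboard_model())

    def test_class_absent_from_store_yields_empty_table(self, store60):
        model = QueryModel("Patient", [Link("hasTherapy", "RadioiodineTherapy")])
        assert run_query(model, store60) == []

    def test_closure_equals_union_over_member_classes(self, store60, onto):
        """Inlining the subclass closure is equivalent to querying each
        member class separately and taking the union."""
        from oncoreg.ontology import local_name, subclass_closure
        whole = {r["s"] for r in run_query(QueryModel("Radiotherapy", []), store60)}
        union = set()
        for cls in subclass_closure(onto, "Radiotherapy"):
            q = (f"PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>\n"
                 f"SELECT ?s WHERE {{?s rdf:type <{cls}>}}")
            union |= {r["s"] for r in store60.execute_sparql(q)}
        assert whole == union


class TestTemplates:
    def test_round_trip_reproduces_sparql(self, onto, tmp_path):
        path = tmp_path / "t.json"
        save_template(dashboard_model(), path)
        reloaded = load_template(path)
        assert build_query(reloaded, onto) == build_query(dashboard_model(), onto)

    def test_parameter_slots_instantiate(self, onto, tmp_path):
        model = QueryModel("Patient", [Filter("age", ">=", Param("age_min"))])
        path = tmp_path / "param.json"
        save_template(model, path)
        q60 = build_query(load_template(path, {"age_min": 60}), onto)
        q70 = build_query(load_template(path, {"age_min": 70}), onto)
        assert q60.replace("60", "70") == q70

    def test_unbound_parameter_rejected_at_emission(self, onto, tmp_path):
        model = QueryModel("Patient", [Filter("age", ">=", Param("age_min"))])
        path = tmp_path / "param.json"
        save_template(model, path)
        with pytest.raises(QueryValidationError, match="age_min"):
            build_query(load_template(path), onto)

    def test_invalid_json_rejected(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(QueryValidationError):
            load_template(path)

    def test_shipped_dashboard_template_runs(self, store60):
        ref = importlib.resources.files("oncoreg.data") / "template_over70_by_type.json"
        model = load_template(ref)
        assert model.aggregation is not None
        result = dashboard_result([model], store60)
        assert result[0]["label"] == "Patients over 70 by cancer type"
        assert all(v >= 0 for _, v in result[0]["rows"])


class TestDefinedClasses:
    def test_membership_matches_oracle(self, registry60, store60, onto):
        oracle = RowOracle(registry60, onto)
        query = QueryModel("Patient", [
            Link("hasDiagnosis", "Diagnosis",
                 [Link("hasPathologicalStructure", "Colorectal_cancer")])])
        members = register_defined_class(
            DefinedClass("Patient_with_colorectal_cancer", query), store60)
        assert members == frozenset(oracle.evaluate(query))

    def test_no_match_yields_empty_set(self, store60):
        query = QueryModel("Patient", [Filter("age", ">", 200)])
        members = register_defined_class(DefinedClass("Methuselah", query), store60)
        assert members == frozenset()

    def test_membership_recomputed_after_store_growth(self, onto):
        from oncoreg.rdf_store import transform
        from util import build_registry, diagnosis, patient
        registry = build_registry(patients=[patient()], diagnoses=[diagnosis()])
        store = transform(registry, ontology=onto)
        query = QueryModel("Patient", [
            Link("hasDiagnosis", "Diagnosis",
                 [Link("hasPathologicalStructure", "Colorectal_cancer")])])
        before = register_defined_class(DefinedClass("Colorectal_patients", query), store)
        bigger = build_registry(
            patients=[patient(), patient(pid="p000002")],
            diagnoses=[diagnosis(), diagnosis(did="d000002", pid="p000002")])
        store.graph += transform(bigger, ontology=onto).graph
        after = defined_class_members(store, "Colorectal_patients")
        assert len(after) == len(before) + 1

    def test_name_collision_with_ontology_rejected(self, store60):
        with pytest.raises(QueryValidationError, match="collides"):
            register_defined_class(
                DefinedClass("Patient", QueryModel("Patient", [])), store60)

    def test_aggregating_query_rejected(self):
        with pytest.raises(QueryValidationError, match="aggregate"):
            DefinedClass("Counts", dashboard_model())


class TestDashboards:
    def test_non_aggregation_model_rejected(self, store60):
        with pytest.raises(QueryValidationError, match="aggregate"):
            dashboard_result([QueryModel("Patient", [])], store60)

    def test_counts_over_disjoint_groups_conserve_total(self, store60):
        """Every therapy has exactly one asserted class, so the group counts
        of a by-type dashboard must sum to the Therapy closure count."""
        model = QueryModel("Therapy", [], aggregation=Aggregation(),
                           name="therapies by type")
        [result] = dashboard_result([model], store60)
        assert sum(v for _, v in result["rows"]) == store60.count_class("Therapy")

    def test_age_range_dashboards_one_query_per_range(self, store60, onto):
        ranges = [(50, 59), (60, 69), (70, 79)]
        models = []
        for lo, hi in ranges:
            models.append(QueryModel("Therapy", [
                Link("hasDiagnosis", "Diagnosis",
                     [Link("hasPathologicalStructure", "Colorectal_cancer")]),
                Link("hasPatient", "Patient",
                     [Filter("age", ">=", lo), Filter("age", "<=", hi)]),
            ], aggregation=Aggregation(), name=f"{lo}-{hi}"))
        results = dashboard_result(models, store60)
        assert [r["label"] for r in results] == ["50-59", "60-69", "70-79"]
        for r in results:
            for key, value in r["rows"]:
                assert value >= 1


class TestOracleEquivalenceSample:
    def test_random_models_match_oracle(self, registry60, store60, onto):
        """A quick randomized cross-check (the full 100-model equivalence on
        the 500-patient store runs with the acceptance suite)."""
        from oracles import random_model
        rng = np.random.default_rng(7)
        oracle = RowOracle(registry60, onto)
        for _ in range(15):
            model = random_model(rng)
            if model.aggregation is not None:
                got = {str(r["t"]): int(r["agg"]) for r in run_query(model, store60)}
                assert got == oracle.evaluate_grouped(model)
            else:
                got = {r["s"] for r in run_query(model, store60)}
                assert got == oracle.evaluate(model)
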