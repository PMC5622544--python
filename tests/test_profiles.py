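"""Semantic profiles, month-normalised timelines and group matrices."""

import pytest

from oncoreg.errors import DataError, QueryValidationError, UnknownEntityError
from oncoreg.profiles import (
    PropertySelection,
    aggregate_timelines,
    build_timeline,
    extract_profile,
    refilter_matrix,
)
from oncoreg.query import QueryModel, run_query
from oncoreg.rdf_store import individual_iri, transform
from util import build_registry, condition, course, diagnosis, patient, therapy


def iri(onto, table, key):
    return individual_iri(onto.namespace, table, key)


@pytest.fixture()
def pharynx_store(onto):
    """One pharynx-cancer patient with staged therapies, courses and a
    declining Karnofsky series."""
    registry = build_registry(
        patients=[patient(gender="F", age=62)],
        diagnoses=[diagnosis(code="C14", pathology="Pharynx_cancer", anatomy="Pharynx")],
        therapies=[
            therapy(start="2010-01-15", end="2010-03-10", cls="Teletherapy"),
            therapy(tid="t000002", start="2010-04-01", end="2010-04-20",
                    cls="Chemotherapy"),
        ],
        courses=[
            course(order=1, date="2010-01-01", kind="Stable_disease"),
            course(cid="k000002", order=2, date="2010-05-07", kind="Progression"),
            course(cid="k000003", order=3, date="2010-09-07", kind="Partial_remission"),
        ],
        conditions=[
            condition(ref="2010-01-01", karnofsky=90),
            condition(cid="c000002", ref="2010-05-07", karnofsky=80),
            condition(cid="c000003", ref="2010-09-07", karnofsky=80),
        ],
    )
    return transform(registry, ontology=onto)


class TestExtractProfile:
    def test_single_hop_selection(self, pharynx_store, onto):
        sel = PropertySelection(
            {"gender"}, {"hasDiagnosis": PropertySelection({"icd10_code"})})
        profile = extract_profile(pharynx_store, iri(onto, "patients", "p000001"), sel)
        assert profile.values == {"gender": ["F"]}
        [dx] = profile.links["hasDiagnosis"]
        assert dx.values == {"icd10_code": ["C14"]}

    def test_empty_object_selection_keeps_datatype_only(self, pharynx_store, onto):
        sel = PropertySelection({"gender", "age"})
        profile = extract_profile(pharynx_store, iri(onto, "patients", "p000001"), sel)
        assert profile.links == {}
        assert set(profile.values) == {"gender", "age"}

    def test_mutual_links_terminate_and_omit_backlink(self, pharynx_store, onto):
        # patient <-> diagnosis are mutually linked (hasDiagnosis/hasPatient)
        nested = PropertySelection(
            set(), {"hasPatient": PropertySelection({"gender"})})
        sel = PropertySelection(set(), {"hasDiagnosis": nested}, max_depth=5)
        profile = extract_profile(pharynx_store, iri(onto, "patients", "p000001"), sel)
        [dx] = profile.links["hasDiagnosis"]
        assert "hasPatient" not in dx.links  # the back-link is not followed

    def test_depth_bound_truncates(self, pharynx_store, onto):
        nested = PropertySelection(set(), {"hasPatient": PropertySelection({"gender"})})
        sel = PropertySelection(set(), {"hasDiagnosis": nested}, max_depth=1)
        profile = extract_profile(pharynx_store, iri(onto, "patients", "p000001"), sel)
        assert profile.links == {}

    def test_unknown_subject_rejected(self, pharynx_store):
        with pytest.raises(UnknownEntityError):
            extract_profile(pharynx_store, "urn:nobody", PropertySelection())


class TestBuildTimeline:
    def test_therapy_months_are_calendar_overlaps(self, pharynx_store, onto):
        tl = build_timeline(pharynx_store, iri(onto, "patients", "p000001"))
        [dx] = tl.diagnoses
        teletherapy_months = {m for m, c in dx.months.items()
                              if "Teletherapy" in c.therapies}
        assert teletherapy_months == {0, 1, 2}  # Jan 15 .. Mar 10 from Jan 1
        chemo_months = {m for m, c in dx.months.items() if "Chemotherapy" in c.therapies}
        assert chemo_months == {3}

    def test_course_and_karnofsky_series(self, pharynx_store, onto):
        tl = build_timeline(pharynx_store, iri(onto, "patients", "p000001"))
        [dx] = tl.diagnoses
        assert dx.pathology == "Pharynx_cancer"
        assert dx.months[0].course == "Stable_disease"
        assert dx.months[4].course == "Progression"
        assert dx.months[8].course == "Partial_remission"
        assert dx.months[0].karnofsky == 90
        assert dx.months[4].karnofsky == 80
        assert dx.last_encounter.isoformat() == "2010-09-07"

    def test_patient_without_therapies_has_course_only_months(self, onto):
        registry = build_registry(
            patients=[patient()], diagnoses=[diagnosis()],
            courses=[course(order=1, date="2010-01-01"),
                     course(cid="k000002", order=2, kind="Progression",
                            date="2010-03-01")],
        )
        store = transform(registry, ontology=onto)
        tl = build_timeline(store, iri(onto, "patients", "p000001"))
        [dx] = tl.diagnoses
        assert all(not c.therapies for c in dx.months.values())
        assert dx.months[2].course == "Progression"

    def test_diagnosis_without_date_is_data_error(self, onto):
        registry = build_registry(patients=[patient()],
                                  diagnoses=[diagnosis(date="")])
        store = transform(registry, ontology=onto)
        with pytest.raises(DataError, match="no date"):
            build_timeline(store, iri(onto, "patients", "p000001"))

    def test_non_patient_subject_rejected(self, pharynx_store, onto):
        with pytest.raises(UnknownEntityError):
            build_timeline(pharynx_store, iri(onto, "diagnoses", "d000001"))


class TestAggregateTimelines:
    def test_single_patient_matrix_is_indicator(self, pharynx_store, onto):
        p = iri(onto, "patients", "p000001")
        matrix = aggregate_timelines(pharynx_store, [p])
        tl = build_timeline(pharynx_store, p).diagnoses[0]
        for (month, category), count in matrix.cells.items():
            assert count == 1
            assert category in tl.categories_at(month)
        for month in tl.months:
            for category in tl.categories_at(month):
                assert matrix.count(month, category) == 1

    def test_cells_equal_per_patient_oracle_sums(self, store200):
        group = [r["s"] for r in run_query(QueryModel("Patient", []), store200)][:80]
        matrix = aggregate_timelines(store200, group, "Colorectal_cancer")
        from oncoreg.profiles import _matching_timeline
        expected: dict[tuple[int, str], int] = {}
        for p in sorted(matrix.group):
            tl = _matching_timeline(build_timeline(store200, p), store200,
                                    "Colorectal_cancer")
            for m in tl.months:
                for cat in tl.categories_at(m):
                    expected[(m, cat)] = expected.get((m, cat), 0) + 1
        assert matrix.cells == expected

    def test_cell_counts_bounded_by_group_size(self, store200):
        group = [r["s"] for r in run_query(QueryModel("Patient", []), store200)][:50]
        matrix = aggregate_timelines(store200, group)
        assert all(v <= len(matrix.group) for v in matrix.cells.values())

    def test_empty_group_rejected(self, store200):
        with pytest.raises(QueryValidationError, match="empty"):
            aggregate_timelines(store200, [])


class TestRefilterMatrix:
    @pytest.fixture()
    def matrix(self, store200):
        group = [r["s"] for r in run_query(QueryModel("Patient", []), store200)][:80]
        return aggregate_timelines(store200, group)

    def test_first_therapy_condition_selects_exact_subgroup(self, matrix, store200):
        refiltered = refilter_matrix(matrix, ("first", "Chemotherapy"))
        from oncoreg.profiles import _matching_timeline
        expected = set()
        for p in matrix.group:
            tl = _matching_timeline(build_timeline(store200, p), store200, None)
            m = tl.first_therapy_month
            if m is not None and "Chemotherapy" in tl.months[m].therapies:
                expected.add(p)
        assert set(refiltered.group) == expected

    def test_condition_satisfied_by_all_is_identity(self, matrix):
        # every simulated diagnosis opens with a course event at month 0
        categories = {c for (m, c) in matrix.cells if m == 0}
        always = next(c for c in categories
                      if matrix.count(0, c) == len(matrix.group))
        refiltered = refilter_matrix(matrix, (0, always))
        assert refiltered.cells == matrix.cells
        assert refiltered.group == matrix.group

    def test_monotonicity(self, matrix):
        refiltered = refilter_matrix(matrix, (1, "Teletherapy"))
        for key, value in refiltered.cells.items():
            assert value <= matrix.cells.get(key, 0) or matrix.cells.get(key, 0) == 0
        assert all(refiltered.cells[k] <= matrix.cells[k] for k in refiltered.cells)

    def test_successive_refilters_equal_conjunction(self, matrix):
        one_two = refilter_matrix(refilter_matrix(matrix, (0, "Chemotherapy")),
                                  (1, "Chemotherapy"))
        two_one = refilter_matrix(refilter_matrix(matrix, (1, "Chemotherapy")),
                                  (0, "Chemotherapy"))
        assert one_two.group == two_one.group
        assert one_two.cells == two_one.cells

    def test_unsatisfiable_condition_flags_empty(self, matrix):
        refiltered = refilter_matrix(matrix, (0, "RadioiodineTherapy"))
        assert refiltered.empty
        assert refiltered.cells == {}

    def test_long_export_shape(self, matrix):
        frame = matrix.to_frame()
        assert list(frame.columns) == ["month", "category", "count"]
        assert frame["count"].sum() == sum(matrix.cells.values())
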