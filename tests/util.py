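"""Hand-built miniature registries for targeted fixtures."""

import pandas as pd

from oncoreg.registry import TABLE_COLUMNS, Registry


def build_registry(patients=(), conditions=(), diagnoses=(), therapies=(), courses=()):
    """Construct a Registry from row dicts, filling absent columns with ''."""
    frames = {}
    for name, rows in (("patients", patients), ("conditions", conditions),
                       ("diagnoses", diagnoses), ("therapies", therapies),
                       ("courses", courses)):
        columns = TABLE_COLUMNS[name]
        data = [{c: str(r.get(c, "")) for c in columns} for r in rows]
        frames[name] = pd.DataFrame(data, columns=columns).astype(object)
    return Registry(**frames)


def patient(pid="p000001", gender="M", birth="1950-06-15", age=59):
    return {"patient_id": pid, "gender": gender, "birth_date": birth, "age": age}


def diagnosis(did="d000001", pid="p000001", code="C20", date="2010-01-01",
              pathology="Colorectal_cancer", anatomy="Colon"):
    return {"diagnosis_id": did, "patient_id": pid, "icd10_code": code,
            "grading": "G2", "tnm_t": "T2", "tnm_n": "N0", "tnm_m": "M0",
            "date": date, "pathological_structure": pathology,
            "anatomical_structure": anatomy, "tumor_type": "Carcinoma"}


def therapy(tid="t000001", did="d000001", cls="Chemotherapy",
            start="2010-01-15", end="2010-03-10", medication="FOLFOX"):
    return {"therapy_id": tid, "diagnosis_id": did, "therapy_class": cls,
            "medication": medication, "start_date": start, "end_date": end}


def course(cid="k000001", did="d000001", kind="Stable_disease", order=1,
           date="2010-01-01"):
    return {"course_id": cid, "diagnosis_id": did, "course_kind": kind,
            "stage": "T2N0M0", "order": order, "date": date}


def condition(cid="c000001", pid="p000001", ref="2010-01-01", age=59,
              karnofsky=90):
    return {"condition_id": cid, "patient_id": pid, "ref_date": ref,
            "age": age, "weight_kg": 80.0, "height_cm": 175.0,
            "karnofsky": karnofsky, "asa": 2, "menopause_status": ""}
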