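# Declarative mapping from registry CSV tables to the ontology.
# Each table maps to a class (optionally refined per row by class_column,
# e.g. a therapy row is typed with its specific therapy subclass), columns
# map to datatype properties, and key columns map to object-property links
# (with inverses).  `chains` follow a foreign key through an intermediate
# table (therapy -> diagnosis -> patient).  `typed_individuals` mint a
# helper individual typed by the column's value (e.g. the pathological
# structure of a diagnosis).

namespace: "http://www.imib.es/ontologies/disease-times#"

tables:
  patients:
    class: Patient
    key: patient_id
    datatype:
      gender: gender
      birth_date: birth_date
      age: age
  conditions:
    class: Patient_condition
    key: condition_id
    datatype:
      ref_date: ref_date
      age: age
      weight_kg: weight_kg
      height_cm: height_cm
      karnofsky: karnofsky
      asa: asa
      menopause_status: menopause_status
    links:
      - {column: patient_id, table: patients, property: hasPatient, inverse: hasPatientCondition}
  diagnoses:
    class: Diagnosis
    key: diagnosis_id
    datatype:
      icd10_code: icd10_code
      grading: grading
      tnm_t: tnm_t
      tnm_n: tnm_n
      tnm_m: tnm_m
      date: date
      tumor_type: tumor_type
    links:
      - {column: patient_id, table: patients, property: hasPatient, inverse: hasDiagnosis}
    typed_individuals:
      - {column: pathological_structure, property: hasPathologicalStructure, prefix: pathology}
      - {column: anatomical_structure, property: hasAnatomicalStructure, prefix: anatomy}
  therapies:
    class: Therapy
    class_column: therapy_class
    key: therapy_id
    datatype:
      medication: medication
      start_date: start_date
      end_date: end_date
    links:
      - {column: diagnosis_id, table: diagnoses, property: hasDiagnosis, inverse: hasTherapy}
    chains:
      - {via_table: diagnoses, via_column: diagnosis_id, column: patient_id,
         table: patients, property: hasPatient, inverse: hasTherapy}
  courses:
    class: Disease_course
    class_column: course_kind
    key: course_id
    datatype:
      stage: stage
      order: order
      date: date
    links:
      - {column: diagnosis_id, table: diagnoses, property: hasDiagnosis, inverse: hasDiseaseCourse}
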