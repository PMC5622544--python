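# oncoreg

A semantically-enabled cancer-registry toolkit: simulate a stratified
registry cohort, lift the tabular registry into an ontology-typed RDF store,
query it through an ontology-driven SPARQL compiler, and analyse it with
semantic patient profiles, month-normalised disease timelines,
hypergeometric term enrichment and a treatment-sequence recommender.

## The problem

Institutional and regional cancer registries record diagnoses (ICD-10, TNM
staging, grading), therapies and the course of the disease for every
patient. Locked into heterogeneous relational schemas, these data are hard
to explore with user-defined, cross-cutting questions — *male patients aged
50–70 with colorectal cancer who received chemotherapy* — and hard to link
to external vocabularies. Representing the registry as RDF individuals
typed by a domain ontology makes such questions expressible as SPARQL over
a shared semantic model, and makes patient histories comparable across
groups. `oncoreg` is a desk-scale, fully self-contained implementation of
that idea for methodologists: every analysis runs on synthetic data
generated by the package itself, so the whole pipeline is reproducible from
a seed.

## What is inside

| Module | Role |
| --- | --- |
| `oncoreg.ontology` | Minimal cancer-registry ontology (Turtle, ~110 classes): Patient, Patient_condition, Diagnosis, Therapy (40-class taxonomy), Disease_course kinds, cancer pathologies, an ICD-10 subset; subclass-closure computation. |
| `oncoreg.simulate` | Stratified cohort simulator: gender × 5-year age bands, cumulative diagnosis/therapy probability stacks, monthly disease-course Markov chain, controlled multi-diagnosis fraction. |
| `oncoreg.registry` | The five CSV tables (patients, conditions, diagnoses, therapies, courses) with referential validation. |
| `oncoreg.rdf_store` | Declarative mapping rules → RDF individuals (one per row, most-specific type), structural domain/range validation, Turtle/N-Triples persistence, SPARQL execution (rdflib). |
| `oncoreg.query` | Ontology-driven search: a query AST compiled to SPARQL with subclass closures inlined in `FILTER (?t IN (...))`, deterministic variable naming, aggregation with group-by, JSON templates with parameter slots, virtual defined classes, dashboards. |
| `oncoreg.profiles` | Semantic profiles `SP(i) = S(d) ∪ S(SP(o))` with cycle guard; per-patient month-indexed timelines; group timeline matrices with conditional re-filtering. |
| `oncoreg.enrichment` | Upper-tail hypergeometric enrichment `P(X ≥ k)` of ICD-10 annotations across patient groups, computed in log space. |
| `oncoreg.recommend` | Treatment-sequence tree per period with empirical conditional probabilities and dynamic re-ranking. |
| `oncoreg.cli` | `oncoreg simulate / transform / validate / query / timeline / timeline-group / enrich / recommend`. |

## The core statistics

**Cohort simulation.** For a stratum *s* (gender × 5-year age band) the
diagnosis distribution is a cumulative probability stack: a uniform draw
*u* selects the category whose interval `[c_{i-1}, c_i)` contains *u*. In
the shipped configuration the 60–64 band uses breast 0.23, lung 0.17,
prostate 0.17, colorectal 0.08 (so colorectal occupies `[0.57, 0.65)`), and
colorectal first-line therapy uses teletherapy 0.44, chemotherapy 0.44,
surgical treatment 0.12. Disease evolution is a monthly Markov chain over
course kinds (stable disease, remission, progression, recurrence, death)
with death absorbing.

**Enrichment.** For a code with *M* annotated diagnoses in a registry of
*N* diagnoses, a group with *n* diagnoses of which *k* carry the code gets

    P = P(X ≥ k),   X ~ Hypergeometric(N, M, n)

computed as a reverse log-sum-exp over the log-pmf (log-gamma binomials),
so `P(X ≥ 0) = 1` exactly and registry-scale counts cannot overflow.

**Recommendation.** For a cohort sharing a profile, the node at therapy
path `(t₁, …, t_p)` holds `#{first p therapies = t₁…t_p} / #{first p−1 =
t₁…t_{p−1}}` plus an explicit *no further therapy* leaf; children
probabilities sum to one and supports are conserved root→leaf. Repeated
therapies (cycles) are unrolled over periods up to a bound.

## Worked example

```python
from oncoreg import (Aggregation, Filter, Link, QueryModel,
                     build_treatment_tree, dashboard_result, recommend_next,
                     run_query, transform)
from oncoreg.simulate import load_sim_config, simulate_cohort

stack = load_sim_config()                       # shipped probability stacks
registry, report = simulate_cohort(stack, 500, seed=7)
print(report["n_patients"], report["multi_diagnosis_fraction"])
# 500 0.094

store = transform(registry)                     # ontology-typed RDF
print(len(store.graph))
# 71379

# male patients aged 50-70 with colorectal cancer who received chemotherapy
model = QueryModel("Patient", [
    Link("hasDiagnosis", "Diagnosis",
         [Link("hasPathologicalStructure", "Colorectal_cancer")]),
    Filter("gender", "=", "M"),
    Filter("age", ">=", 50), Filter("age", "<=", 70),
    Link("hasTherapy", "Chemotherapy"),
])
print(len(run_query(model, store)))
# 15

# dashboard: therapies applied to colorectal patients aged 60+
dash = dashboard_result([QueryModel("Therapy", [
    Link("hasDiagnosis", "Diagnosis",
         [Link("hasPathologicalStructure", "Colorectal_cancer")]),
    Link("hasPatient", "Patient", [Filter("age", ">=", 60)]),
], aggregation=Aggregation(), name="colorectal therapies, 60+")], store)
print(dash[0]["rows"])
# [('Chemotherapy', 26.0), ('SurgicalTreatment', 11.0), ('Teletherapy', 39.0)]

# next-treatment ranking after chemotherapy, over the colorectal cohort
cohort = [r["s"] for r in run_query(QueryModel("Patient", [
    Link("hasDiagnosis", "Diagnosis",
         [Link("hasPathologicalStructure", "Colorectal_cancer")])]), store)]
tree = build_treatment_tree(store, cohort)
print(recommend_next(tree, ["Chemotherapy"]).ranking)
# [('No_further_therapy', 0.458...), ('Teletherapy', 0.375),
#  ('Chemotherapy', 0.125), ('SurgicalTreatment', 0.0416...)]
```

The counts are patients (or therapies) matching each selection; the
recommendation probabilities are the empirical conditional frequencies of
the continuation therapies among cohort members whose history starts with
chemotherapy.

The same pipeline from a shell:

```sh
oncoreg simulate --n 500 --seed 7 --out registry/
oncoreg transform --registry registry/ --out store.ttl
oncoreg query --template templates/cohort.json --store store.ttl --out hits.json
```

## Limitations

The synthetic cohort is calibrated to a handful of published stratum
probabilities plus realistic defaults; it is not a statistical portrait of
any real registry (see `docs/methods.md` for what it does and does not
emulate). The SPARQL engine is rdflib's — suitable for desk-scale stores
(≲ a few hundred thousand triples), not a triple-store server.
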