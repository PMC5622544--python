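# Methods

This note records the models, conventions and numerical choices behind
`oncoreg`, and what the synthetic data can and cannot support.

## Cohort simulator

**Model.** Patients are generated per stratum (gender × 5-year age band,
last band 85+ open-ended). Each stratum carries an ordered list of
(diagnosis, weight) pairs interpreted as a cumulative probability stack: a
uniform draw selects the category whose half-open interval `[c_{i-1}, c_i)`
contains it. Each (stratum, diagnosis) carries an analogous first-line
therapy stack, each diagnosis an ICD-10 code stack and a monthly
disease-course transition table.

**Shipped configuration.** The 60–64 band uses the published calibration
probabilities (breast 0.23, lung 0.17, prostate 0.17, colorectal 0.08;
colorectal therapy: teletherapy 0.44, chemotherapy 0.44, surgery 0.12).
With the stack ordered breast → lung → prostate → colorectal, colorectal
occupies `[0.57, 0.65)`; a width-0.07 interval sometimes quoted for it is
inconsistent with the weight 0.08 and is not used. All other numbers
(diagnosis mixes of other bands, therapy mixes of other cancers, code
distributions, transition tables, stratum weights) are fixed, realistic
desk-scale defaults chosen once — they are the study conditions of this
package, not estimates of any real registry. The same diagnosis table
serves both genders within a band, mirroring how the calibration
probabilities are stated; gender-specific incidence (e.g. no male breast
cancer) is deliberately not modelled.

**Parameters.**

| Parameter | Default | Meaning |
| --- | --- | --- |
| `multidx_fraction` | 0.10 | Probability of a second diagnosis, per stratum. The second is drawn without replacement and dated 6–36 months after the first. |
| `therapy_continue_prob` | 0.5 | Geometric stopping rule for the number of therapies per diagnosis (memoryless "one or more therapies"), capped at `max_therapies` = 6. Therapies occupy consecutive calendar months (duration 1–3 months each). |
| `course_model.max_months` | 60 | Monthly Markov iteration horizon; an event row is emitted on every state change; Death is absorbing and must self-loop with weight 1. |
| `index_date` | 2010-01-01 | Birth dates are back-computed so integer age at the index date is uniform inside the stratum; the diagnosis date falls within a year of it. |
| `karnofsky_start` | 90 | Karnofsky decays 10 points per Progression event (floor 10, 0 at Death); a patient-condition row accompanies every course event, which yields the per-month Karnofsky series of the timeline view. |

Weight lists must sum to 1 within 1% (they are renormalised inside that
tolerance, rejected outside it); negative weights, unknown therapy classes,
unknown course kinds and age-band gaps are configuration errors.

**Randomness.** One `numpy` generator seeded once is threaded through every
draw in a fixed order, so identical (config, n, seed) reproduce
byte-identical CSV files.

**What the generator does not emulate.** Real registries have
gender- and age-specific incidence, correlated therapy sequences driven by
guidelines and staging, informative censoring, missing and inconsistent
records, and secular trends. Passing distribution-recovery tests therefore
demonstrates the correctness of the sampling machinery and of everything
downstream of it — not epidemiological realism.

## Ontology

Self-contained Turtle, ~110 classes, OWL constructs restricted to
`subClassOf`, `domain`/`range` and annotations, so no reasoner is needed.
The therapy taxonomy (40 classes under `Therapy`) is modelled so that a
pre-order depth-first traversal with lexicographic sibling order reproduces
the canonical enumeration used in the platform's published type filters.
External alignments (SIO, OBI) are annotations only. Some datatype
properties (`age`, `date`) are reused across classes; multiple `rdfs:domain`
triples are treated as *any-of* alternatives by the validators, a pragmatic
reading appropriate for a draft registry ontology. `subclass_closure`
returns the root first, then descendants in DFS-lexicographic order; the
query emitter moves the root to the end of the filter list, matching the
canonical query shape.

## Tabular → RDF transformation

Declarative mapping rules (YAML) map each CSV table to a class, columns to
datatype properties, and key columns to object-property links with
inverses; a chain rule follows therapy → diagnosis → patient so that
therapies link to both their diagnosis and their patient, and patients
link back (`hasTherapy`/`hasPatient`/`hasDiagnosis` are all asserted — the
published query shapes navigate in both directions). Rows with a
`class_column` (therapy class, course kind) are typed with that specific
subclass; every individual carries exactly one asserted type. Pathological
and anatomical structures become helper individuals
(`individual/pathology/<diagnosis-key>`) typed by the column value.
IRIs are deterministic: `<namespace-base>/individual/<table>/<key>`.

Instead of description-logic consistency checking, the transform validates
structurally: every emitted object triple must satisfy some declared
(domain, range) pair of its property, and no individual may be untyped.
Dangling foreign keys fail with the offending row named.

## Query compilation

A `QueryModel` is a root class plus an ordered list of constraints (object
hops with nested constraints, datatype filters) and optional aggregation.
Variable naming is deterministic and mirrors the platform's convention:
root `?s` (type `?t`); children of the root numbered 0, 1, … in insertion
order (`?a0`, `?a1`, filters included); children of a node whose suffix
ends in digit d numbered from d+1 (`?a0` → `?a01`, `?a1` → `?a12`).
Type constraints expand client-side into `FILTER (?t IN (<closure>))` —
descendants first, queried class last — keeping the store entailment-free.

Two dialects are emitted from one model:

* `display` — the platform's canonical shape: nested group graph patterns
  and the Virtuoso-style aggregate select list
  (`SELECT count(DISTINCT ?s), ?t … group by ?t`). Byte-deterministic;
  this is the shape the emission-fidelity tests check, token-by-token.
* `standard` — valid SPARQL 1.1, executed by rdflib: a single flattened
  basic graph pattern (the model is purely conjunctive, so flattening
  preserves semantics) with root datatype filters emitted first. The
  ordering is a selectivity heuristic: rdflib evaluates patterns in the
  order given, and binding `?s` through a cheap datatype pattern before the
  unconstrained `rdf:type` pattern cuts evaluation time by an order of
  magnitude. Aggregates use `(COUNT(DISTINCT ?s) AS ?agg)`. Local names
  ending in `.` (e.g. `Teletherapy_n.n.bez.`) are emitted as full IRIs
  because SPARQL prefixed names may not end with a dot.

String comparisons coerce through `str()` (`str(?a1) = 'M'`); dates are
compared as ISO-8601 strings, which is order-consistent. Operators:
`=, ≠, <, ≤, >, ≥`. Templates are JSON (schema `oncoreg-query/1`) with
`{"param": name}` literal placeholders bound at load time. Defined classes
are virtual: registering one stores its query and recomputes membership on
demand, so membership tracks store updates without asserting triples.

## Profiles and timelines

Profile extraction follows the selection recursively: datatype values at
each node, then profiles of objects reached through selected object
properties. Termination is guaranteed by a path-based visited set (an IRI
already on the current root-to-leaf path is never revisited, so a mutual
patient↔diagnosis link is traversed once and the back-link omitted) plus a
depth bound (default 4).

Timelines use calendar-month arithmetic: month index =
`(y2−y1)·12 + (m2−m1)` from the diagnosis date, 0-based. A therapy
contributes to every month its `[start, end]` span overlaps, partial months
included. Course events are sorted by (order, date); if two events share a
month the higher order wins, giving one course kind per month. The date of
last encounter is the maximum date over the patient's therapies, courses
and conditions. The group matrix counts patients per (month, category)
where categories are therapy classes and course kinds; a patient counts
once per category per month. Re-filtering keeps the patients whose
timeline shows the category at the given month (or whose first therapy
month includes the given therapy class) and recomputes the matrix; an
unsatisfiable condition returns a zero matrix flagged `empty` rather than
an error. Group membership comes from any query result, so selection and
aggregation stay decoupled.

## Enrichment

The statistic is the standard upper-tail hypergeometric: population = total
diagnoses in the registry, successes = diagnoses annotated with the code,
draws = diagnoses in the group. The log-pmf is computed with log-gamma
binomials and accumulated with a reverse `logaddexp`, preserving relative
precision in the far tail; `P(X ≥ 0)` is exactly 1 and `k > min(M, n)`
yields exactly 0. A formulation occasionally quoted with the *number of
distinct codes* as population and `C(N, i)` in the denominator is
dimensionally inconsistent with this statistic; it is available behind
`as_printed=True` for comparison only. No multiple-testing correction is
applied by default (an optional Benjamini–Hochberg column exists) —
matching the analysis design this reproduces. Counts are derived from a
single SPARQL projection of (diagnosis, patient, code, group value) rows.

## Recommendation

The "Bayesian network over treatments by period" is realised as the
empirical sequence tree: cycles that repeated therapies would create are
unrolled over periods (month or quarter buckets of therapy start relative
to diagnosis; one therapy per bucket, earliest start wins), bounded by
`max_period` (default 24) instead of requiring the user to declare
cycle-generating characteristics. No structure learning and no smoothing
by default. Re-ranking after choosing a treatment uses the chosen node's
children, which provably equals rebuilding the tree on the prefix
sub-cohort (covered by a test).

## Numerical and determinism choices

* Cumulative stack boundaries are rounded to 12 decimals so decimal weight
  lists hit their nominal boundaries exactly (0.23 + 0.17 + 0.17 → 0.57).
* The categorical sampler is strict about `u ∈ [0, 1)` and guards the top
  boundary against floating-point spill.
* Closure order, variable naming, IRI minting, template serialisation and
  SPARQL emission are all deterministic; the store digest is a SHA-256 of
  sorted N-Triples.
* Ties in recommendation rankings break lexicographically.

## Problem sizes

The test suite exercises cohorts of 60–500 patients for store-level
checks, 1,000 for transformation count conservation, 2,000 for recommender
recovery and 20,000 (restricted to one stratum) for simulator distribution
recovery; the hypergeometric implementation is checked exhaustively against
exact integer enumeration for all populations up to 60. These sizes give
3-standard-error windows tight enough to detect miscalibration while
keeping every run desk-scale.

## Known limitations

* rdflib's SPARQL evaluator limits practical store size; the flattened
  dialect mitigates but does not remove this.
* Variable suffix naming concatenates digits, so models with more than ten
  constraints under one node could collide suffixes; practical models stay
  far below that.
* The simulator's gender-agnostic diagnosis tables admit clinically
  impossible combinations (male breast cancer) — accepted for symmetry
  with the published calibration format.
* Defined classes are registered per in-memory store instance and are not
  persisted with the graph.
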