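"""Treatment recommendation from a sequence tree of therapy histories.

For a cohort of patients sharing some features, the therapy classes of each
patient's earliest diagnosis are ordered by period (month or quarter of
their start relative to the diagnosis, one therapy per period, earliest
start winning a tie) into a sequence.  These sequences populate a tree:
the node at path (t1, ..., tp) holds the empirical conditional probability
that a patient whose first p-1 therapies were t1..t(p-1) continues with tp,
plus an explicit "no further therapy" leaf, so children probabilities sum
to one and support counts are conserved from the root to the leaves.

Repeated application of the same therapy — a cycle in the underlying
patient graph — is simply unrolled over periods, bounded by ``max_period``.
After a treatment is chosen, the next recommendation is the chosen node's
own children, which equals rebuilding the tree on the sub-cohort with that
treatment prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from rdflib import RDF, URIRef

from .dates import month_index, parse_date
from .errors import QueryValidationError
from .ontology import local_name
from .profiles import build_timeline
from .rdf_store import SemanticStore

NO_FURTHER = "No_further_therapy"

_PERIOD_MONTHS = {"month": 1, "quarter": 3}


@dataclass
class TreeNode:
    therapy: str | None           # None at the root
    support: int                  # cohort patients reaching this node
    probability: float            # conditional on the parent path
    children: dict[str, "TreeNode"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "therapy": self.therapy, "support": self.support,
            "probability": self.probability,
            "children": {k: c.to_dict() for k, c in sorted(self.children.items())},
        }


@dataclass
class TreatmentTree:
    root: TreeNode
    period: str
    max_period: int
    cohort_size: int

    def node_at(self, path: list[str]) -> TreeNode | None:
        node = self.root
        for step in path:
            if step not in node.children:
                return None
            node = node.children[step]
        return node

    def to_json(self) -> str:
        return json.dumps({
            "period": self.period, "max_period": self.max_period,
            "cohort_size": self.cohort_size, "root": self.root.to_dict(),
        }, indent=2)


def therapy_sequence(store: SemanticStore, patient: str,
                     period: str = "month", max_period: int = 24) -> list[str]:
    """Therapy classes of the patient's earliest diagnosis, one per period."""
    months = _PERIOD_MONTHS[period]
    timeline = build_timeline(store, patient)
    if not timeline.diagnoses:
        return []
    tl = timeline.diagnoses[0]
    # bucket -> (start date, therapy class); earliest start wins the bucket
    onto = store.ontology
    buckets: dict[int, tuple] = {}
    for tx in store.graph.objects(URIRef(tl.diagnosis), URIRef(onto.iri("hasTherapy"))):
        start = None
        for o in store.graph.objects(tx, URIRef(onto.iri("start_date"))):
            start = parse_date(o.toPython())
        ttype = None
        for o in store.graph.objects(tx, RDF.type):
            ttype = str(o)
        if start is None or ttype is None:
            continue
        bucket = month_index(start, tl.date) // months
        key = (start, str(tx))
        if bucket not in buckets or key < buckets[bucket][0]:
            buckets[bucket] = (key, local_name(ttype, onto.namespace))
    return [buckets[b][1] for b in sorted(buckets)][:max_period]


def build_treatment_tree(store: SemanticStore, cohort,
                         period: str = "month",
                         max_period: int = 24) -> TreatmentTree:
    """Build the sequence tree for an iterable of cohort patient IRIs."""
    if period not in _PERIOD_MONTHS:
        raise QueryValidationError(f"unknown period granularity {period!r}")
    patients = sorted(set(map(str, cohort)))
    if not patients:
        raise QueryValidationError("cannot build a treatment tree for an empty cohort")
    sequences = [therapy_sequence(store, p, period, max_period) for p in patients]
    root = TreeNode(therapy=None, support=len(sequences), probability=1.0)
    _grow(root, sequences, depth=0, max_period=max_period)
    return TreatmentTree(root=root, period=period, max_period=max_period,
                         cohort_size=len(patients))


def _grow(node: TreeNode, sequences: list[list[str]], depth: int, max_period: int) -> None:
    total = len(sequences)
    if total == 0:
        return
    by_next: dict[str, list[list[str]]] = {}
    ended = 0
    for seq in sequences:
        if depth >= len(seq) or depth >= max_period:
            ended += 1
        else:
            by_next.setdefault(seq[depth], []).append(seq)
    for therapy in sorted(by_next):
        subs = by_next[therapy]
        child = TreeNode(therapy=therapy, support=len(subs),
                         probability=len(subs) / total)
        node.children[therapy] = child
        _grow(child, subs, depth + 1, max_period)
    if ended:
        node.children[NO_FURTHER] = TreeNode(
            therapy=NO_FURTHER, support=ended, probability=ended / total
        )


@dataclass
class Recommendation:
    ranking: list[tuple[str, float]]
    exact_path: bool           # False when a nearest-prefix fallback was used
    used_path: list[str]


def recommend_next(tree: TreatmentTree, observed: list[str]) -> Recommendation:
    """Rank the continuations of an observed therapy path.

    Probabilities are the empirical conditional frequencies at the path's
    node; ties break lexicographically.  If the path does not occur in the
    cohort, the longest prefix that does is used and flagged.
    """
    path = list(observed)
    node = tree.node_at(path)
    exact = node is not None
    while node is None:
        path = path[:-1]
        node = tree.node_at(path)
    if not node.children:  # full-depth leaf
        ranking = [(NO_FURTHER, 1.0)]
    else:
        ranking = sorted(
            ((t, c.probability) for t, c in node.children.items()),
            key=lambda kv: (-kv[1], kv[0]),
        )
    return Recommendation(ranking=ranking, exact_path=exact, used_path=path)
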