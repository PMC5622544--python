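"""Hypergeometric term enrichment of ICD-10 annotations across patient groups.

For a code with M annotated diagnoses in a registry of ``population``
diagnoses, and a group of interest containing n diagnoses of which k carry
the code, the enrichment p-value is the upper tail of the hypergeometric
distribution, P(X >= k) — the chance of drawing at least k annotated
diagnoses in n draws without replacement.  Computation is done in log space
(log-gamma binomials) so registry-scale counts cannot overflow.

An ``as_printed`` mode evaluates, for comparison, the literal textbook-style
formula sometimes quoted with N equal to the number of distinct codes and
C(N, i) in the denominator; that expression is dimensionally inconsistent
with the standard statistic and is not used for analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .query import QueryModel, run_query
from .rdf_store import SemanticStore


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one (code, group) test.

    population: total diagnoses in the registry (the urn size);
    M: diagnoses annotated with the code; n: diagnoses in the group;
    k: group diagnoses annotated with the code; total_codes: number of
    distinct codes in use (only the as-printed formula consumes it).
    """

    population: int
    M: int
    n: int
    k: int
    total_codes: int | None = None

    def __post_init__(self):
        if min(self.population, self.M, self.n, self.k) < 0:
            raise ValueError("enrichment counts must be non-negative")
        if self.M > self.population or self.n > self.population:
            raise ValueError("M and n cannot exceed the population")


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail_grid(population: int, M: int, n: int) -> np.ndarray:
    """Upper-tail probabilities P(X >= k) for every k in 0..min(M, n).

    Computed as a reverse log-sum-exp over the log-pmf, so the smallest
    tails keep full relative precision; the k = 0 entry is exactly 1.
    """
    if M > population or n > population:
        raise ValueError("M and n cannot exceed the population")
    kmax = min(M, n)
    i = np.arange(kmax + 1)
    with np.errstate(invalid="ignore"):
        logpmf = (
            _log_binom(M, i) + _log_binom(population - M, n - i) - _log_binom(population, n)
        )
    # combinations outside the support (n - i > population - M) are impossible
    logpmf = np.where(n - i <= population - M, logpmf, -np.inf)
    logtail = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    tails = np.exp(np.minimum(logtail, 0.0))
    tails[0] = 1.0
    return tails


def hypergeom_tail(inp: EnrichmentInput, as_printed: bool = False) -> float:
    """P(X >= k): the enrichment p-value for one (code, group) test.

    Returns exactly 1 for k = 0 and exactly 0 for k > min(M, n).  With
    ``as_printed=True`` the literal code-count formula is evaluated instead
    (requires ``total_codes``).
    """
    if as_printed:
        return _tail_as_printed(inp)
    if inp.k == 0:
        return 1.0
    if inp.k > min(inp.M, inp.n):
        return 0.0
    return float(hypergeom_tail_grid(inp.population, inp.M, inp.n)[inp.k])


def _tail_as_printed(inp: EnrichmentInput) -> float:
    if inp.total_codes is None:
        raise ValueError("the as-printed formula needs total_codes")
    N, M, n, k = inp.total_codes, inp.M, inp.n, inp.k
    acc = 0.0
    for i in range(k):
        if i > M or n - i < 0 or n - i > N - M or i > N:
            continue
        acc += math.comb(M, i) * math.comb(N - M, n - i) / math.comb(N, i)
    return 1.0 - acc


# ---------------------------------------------------------------------------
# group enrichment over a semantic store


_DIAGNOSIS_ROWS = """
PREFIX ods: <{ns}>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
SELECT ?d ?p ?code ?g WHERE {{
?d rdf:type ?t . FILTER (?t IN (ods:Diagnosis))
?d ods:hasPatient ?p .
?d ods:icd10_code ?code .
?p ods:{group_prop} ?g .
}}
"""


def enrich_groups(store: SemanticStore, cohort: QueryModel | None,
                  group_prop: str = "gender",
                  codes: list[str] | None = None,
                  groups: list[str] | None = None,
                  bh_correction: bool = False) -> pd.DataFrame:
    """Per-(code, group) hypergeometric enrichment table.

    The cohort query (root class Patient) selects the diagnoses under test
    via their patients; ``group_prop`` (e.g. ``gender``) partitions them.
    M is counted against the whole registry, n and k inside each group.
    An empty group yields p = 1 rows flagged in the ``empty_group`` column.
    """
    rows = store.execute_sparql(
        _DIAGNOSIS_ROWS.format(ns=store.ontology.namespace, group_prop=group_prop)
    )
    frame = pd.DataFrame(rows, columns=["d", "p", "code", "g"])
    population = len(frame)
    m_by_code = frame.groupby("code").size().to_dict()

    if cohort is not None:
        members = {str(r["s"]) for r in run_query(cohort, store)}
        cohort_frame = frame[frame["p"].isin(members)]
    else:
        cohort_frame = frame
    if groups is None:
        groups = sorted(cohort_frame["g"].unique())
    if codes is None:
        codes = sorted(cohort_frame["code"].unique())

    out = []
    for group_value in groups:
        in_group = cohort_frame[cohort_frame["g"] == group_value]
        n = len(in_group)
        k_by_code = in_group.groupby("code").size().to_dict()
        for code in codes:
            M = int(m_by_code.get(code, 0))
            k = int(k_by_code.get(code, 0))
            inp = EnrichmentInput(population=population, M=M, n=n, k=k,
                                  total_codes=len(m_by_code))
            out.append({
                "code": code, "group": str(group_value),
                "population": population, "M": M, "n": n, "k": k,
                "p_value": 1.0 if n == 0 else hypergeom_tail(inp),
                "empty_group": n == 0,
            })
    table = pd.DataFrame(out)
    if bh_correction and len(table):
        table["p_adjusted"] = _benjamini_hochberg(table["p_value"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


def pivot_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Shape a two-group table as code x per-group p-value columns, with the
    group sizes in the column headers."""
    sizes = table.groupby("group")["n"].first().to_dict()
    wide = table.pivot(index="code", columns="group", values="p_value")
    wide.columns = [f"P-value {g} ({sizes[g]})" for g in wide.columns]
    return wide.reset_index()
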