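"""Stratified cohort simulator.

Generates a synthetic cancer registry from stacked probability
distributions: patients are drawn per gender x 5-year age stratum, each
stratum carries a cumulative diagnosis-weight stack, each diagnosis a
first-line therapy stack, and the disease evolution is a monthly Markov
chain over course kinds with Death absorbing.  A configurable fraction of
patients receives a second diagnosis.

All randomness flows through one seeded :class:`numpy.random.Generator`, so
identical (config, n, seed) yields a byte-identical registry.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dates import add_months
from .errors import ConfigError
from .ontology import OntologyModel, load_ontology, local_name, subclass_closure
from .registry import Registry, TABLE_COLUMNS

import pandas as pd

_MEDICATIONS = {
    "Chemotherapy": ["FOLFOX", "FOLFIRI", "Cisplatin", "Doxorubicin"],
    "Immunotherapy": ["Nivolumab", "Ipilimumab"],
    "Anti-hormonal_anti-estrogens": ["Tamoxifen"],
    "Anti-hormonal_anti-androgens": ["Bicalutamide"],
}
_GRADING = [("G1", 0.2), ("G2", 0.4), ("G3", 0.3), ("G4", 0.1)]
_TNM_T = [("T1", 0.3), ("T2", 0.35), ("T3", 0.25), ("T4", 0.1)]
_TNM_N = [("N0", 0.55), ("N1", 0.3), ("N2", 0.15)]
_TNM_M = [("M0", 0.8), ("M1", 0.2)]


@dataclass(frozen=True)
class Stratum:
    """Gender x 5-year age band; the last band is open-ended (85+)."""

    gender: str
    age_lo: int
    age_hi: int | None  # None = open-ended

    @property
    def band(self) -> str:
        return f"{self.age_lo}+" if self.age_hi is None else f"{self.age_lo}-{self.age_hi}"


def parse_band(band: str) -> tuple[int, int | None]:
    band = str(band).strip()
    if band.endswith("+"):
        return int(band[:-1]), None
    lo, hi = band.split("-")
    return int(lo), int(hi)


def cumulative(weights: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Turn an ordered (category, weight) list into cumulative upper bounds.

    Boundaries are rounded to 12 decimals so that stacks of decimal weights
    sit exactly at their nominal cumulative values (0.23 + 0.17 + 0.17 gives
    the boundary 0.57, not 0.5700000000000001)."""
    bounds, acc = [], 0.0
    for cat, w in weights:
        acc = round(acc + w, 12)
        bounds.append((cat, acc))
    if bounds:
        bounds[-1] = (bounds[-1][0], 1.0)  # close the stack exactly
    return bounds


def sample_categorical(cum_weights: list[tuple[str, float]], u: float) -> str:
    """Category whose half-open cumulative interval [lo, hi) contains *u*."""
    if not 0.0 <= u < 1.0:
        raise ValueError(f"uniform draw outside [0, 1): {u}")
    bounds = [b for _, b in cum_weights]
    idx = bisect_right(bounds, u)
    if idx >= len(cum_weights):  # numerical guard at the top boundary
        idx = len(cum_weights) - 1
    return cum_weights[idx][0]


@dataclass
class DistributionStack:
    """All probability tables driving the simulation, already validated."""

    age_bands: list[str]
    stratum_gender: list[tuple[str, float]]
    stratum_band: list[tuple[str, float]]
    multidx_fraction: dict[str, float]
    diagnosis_weights: dict[str, list[tuple[str, float]]]   # band (or 'default')
    therapy_weights: dict[str, dict[str, list[tuple[str, float]]]]
    icd10_codes: dict[str, list[tuple[str, float]]]
    anatomical_structures: dict[str, str]
    transitions: dict[str, dict[str, list[tuple[str, float]]]]
    initial_state: str
    absorbing: set[str]
    max_months: int
    therapy_continue_prob: float
    max_therapies: int
    index_date: dt.date
    condition_params: dict
    _cum: dict = field(default_factory=dict, repr=False)

    def strata(self) -> list[Stratum]:
        return [
            Stratum(g, *parse_band(b)) for g in ("M", "F") for b in self.age_bands
        ]

    def stratum_for_band(self, band: str, gender: str = "M") -> Stratum:
        if band not in self.age_bands:
            raise ConfigError(f"unknown age band: {band}")
        return Stratum(gender, *parse_band(band))

    # cumulative stacks, cached by table identity
    def cum(self, key, weights) -> list[tuple[str, float]]:
        if key not in self._cum:
            self._cum[key] = cumulative(weights)
        return self._cum[key]

    def diagnosis_stack(self, band: str) -> list[tuple[str, float]]:
        table = self.diagnosis_weights.get(band, self.diagnosis_weights["default"])
        return self.cum(("dx", band in self.diagnosis_weights and band or "default"), table)

    def therapy_stack(self, band: str, diagnosis: str) -> list[tuple[str, float]]:
        per_band = self.therapy_weights.get(band, self.therapy_weights["default"])
        if diagnosis not in per_band:
            per_band = self.therapy_weights["default"]
        return self.cum(("tx", band in self.therapy_weights and band or "default", diagnosis),
                        per_band[diagnosis])

    def transition_stack(self, diagnosis: str, state: str) -> list[tuple[str, float]]:
        table = self.transitions.get(diagnosis, self.transitions["default"])
        if state not in table:
            raise ConfigError(f"no transition row for course state {state}")
        return self.cum(("course", diagnosis in self.transitions and diagnosis or "default", state),
                        table[state])


def _normalise(name: str, weights: dict) -> list[tuple[str, float]]:
    items = [(str(k), float(v)) for k, v in weights.items()]
    if any(w < 0 for _, w in items):
        raise ConfigError(f"negative weight in {name}")
    total = sum(w for _, w in items)
    if not items or abs(total - 1.0) > 0.01:
        raise ConfigError(f"weights of {name} sum to {total:.4f}, expected 1 within 1%")
    return [(k, w / total) for k, w in items]


def load_sim_config(path=None, ontology: OntologyModel | None = None) -> DistributionStack:
    """Load and validate a simulation config (the shipped one by default).

    Weight tables are renormalised when within 1% of summing to one and
    rejected otherwise; therapy classes and course kinds are checked against
    the ontology; age bands must partition [0, inf) in the listed order.
    """
    if path is None:
        ref = importlib.resources.files("oncoreg.data") / "sim_config.yaml"
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if ontology is None:
        ontology = load_ontology()

    try:
        age_bands = [str(b) for b in raw["age_bands"]]
        _check_band_partition(age_bands)

        stratum_gender = _normalise("stratum_weights.gender", raw["stratum_weights"]["gender"])
        stratum_band = _normalise("stratum_weights.age_bands", raw["stratum_weights"]["age_bands"])
        if {b for b, _ in stratum_band} != set(age_bands):
            raise ConfigError("stratum_weights.age_bands must cover exactly the declared bands")

        diagnosis_weights = {
            band: _normalise(f"diagnosis_weights[{band}]", table)
            for band, table in raw["diagnosis_weights"].items()
        }
        if "default" not in diagnosis_weights:
            raise ConfigError("diagnosis_weights requires a 'default' table")

        therapy_names = {
            local_name(c, ontology.namespace)
            for c in subclass_closure(ontology, "Therapy")
        }
        therapy_weights: dict[str, dict[str, list[tuple[str, float]]]] = {}
        for band, per_dx in raw["therapy_weights"].items():
            therapy_weights[band] = {}
            for dx, table in per_dx.items():
                norm = _normalise(f"therapy_weights[{band}][{dx}]", table)
                unknown = [t for t, _ in norm if t not in therapy_names]
                if unknown:
                    raise ConfigError(
                        f"therapy classes not in the ontology Therapy subtree: {unknown}"
                    )
                therapy_weights[band][dx] = norm
        if "default" not in therapy_weights:
            raise ConfigError("therapy_weights requires a 'default' table")

        course_names = {
            local_name(c, ontology.namespace)
            for c in subclass_closure(ontology, "Disease_course")
        }
        cm = raw["course_model"]
        transitions: dict[str, dict[str, list[tuple[str, float]]]] = {}
        for dx, table in cm["transitions"].items():
            transitions[dx] = {}
            for state, row in table.items():
                norm = _normalise(f"course_model.transitions[{dx}][{state}]", row)
                unknown = [s for s in [state] + [t for t, _ in norm] if s not in course_names]
                if unknown:
                    raise ConfigError(f"course kinds not in the ontology: {sorted(set(unknown))}")
                transitions[dx][state] = norm
        absorbing = set(map(str, cm.get("absorbing", [])))
        for state in absorbing:
            row = transitions["default"].get(state, [])
            if row != [(state, 1.0)]:
                raise ConfigError(f"absorbing state {state} must self-loop with weight 1")

        stack = DistributionStack(
            age_bands=age_bands,
            stratum_gender=stratum_gender,
            stratum_band=stratum_band,
            multidx_fraction={str(k): float(v) for k, v in raw["multidx_fraction"].items()},
            diagnosis_weights=diagnosis_weights,
            therapy_weights=therapy_weights,
            icd10_codes={
                dx: _normalise(f"icd10_codes[{dx}]", tab)
                for dx, tab in raw["icd10_codes"].items()
            },
            anatomical_structures={k: str(v) for k, v in raw["anatomical_structures"].items()},
            transitions=transitions,
            initial_state=str(cm["initial_state"]),
            absorbing=absorbing,
            max_months=int(cm.get("max_months", 60)),
            therapy_continue_prob=float(raw.get("therapy_continue_prob", 0.5)),
            max_therapies=int(raw.get("max_therapies", 6)),
            index_date=dt.date.fromisoformat(str(raw.get("index_date", "2010-01-01"))),
            condition_params=raw.get("patient_condition", {}),
        )
    except KeyError as exc:
        raise ConfigError(f"simulation config is missing section {exc}") from exc
    return stack


def _check_band_partition(bands: list[str]) -> None:
    expected_lo = 0
    for i, band in enumerate(bands):
        lo, hi = parse_band(band)
        if lo != expected_lo:
            raise ConfigError(f"age-band gap before {band!r} (expected start {expected_lo})")
        last = i == len(bands) - 1
        if last:
            if hi is not None:
                raise ConfigError("last age band must be open-ended (e.g. '85+')")
        else:
            if hi is None or hi < lo:
                raise ConfigError(f"malformed age band {band!r}")
            expected_lo = hi + 1


class _Ids:
    def __init__(self):
        self.counts = dict.fromkeys(("p", "c", "d", "t", "k"), 0)

    def next(self, prefix: str) -> str:
        self.counts[prefix] += 1
        return f"{prefix}{self.counts[prefix]:06d}"


def simulate_patient(stack: DistributionStack, stratum: Stratum,
                     rng: np.random.Generator, _ids: _Ids | None = None) -> dict[str, list]:
    """Simulate one patient; returns row dicts keyed by table name."""
    ids = _ids or _Ids()
    rows = {name: [] for name in TABLE_COLUMNS}

    age = int(rng.integers(stratum.age_lo,
                           (stratum.age_hi if stratum.age_hi is not None else stratum.age_lo + 9) + 1))
    idx = stack.index_date
    b_hi = idx.replace(year=idx.year - age)
    b_lo = idx.replace(year=idx.year - age - 1) + dt.timedelta(days=1)
    birth = b_lo + dt.timedelta(days=int(rng.integers(0, (b_hi - b_lo).days + 1)))

    patient_id = ids.next("p")
    rows["patients"].append({
        "patient_id": patient_id, "gender": stratum.gender,
        "birth_date": birth.isoformat(), "age": age,
    })

    p_multi = stack.multidx_fraction.get(stratum.band, stack.multidx_fraction["default"])
    n_dx = 2 if rng.random() < p_multi else 1

    dx_stack = stack.diagnosis_stack(stratum.band)
    first_dx: str | None = None
    dx_date = idx + dt.timedelta(days=int(rng.integers(0, 365)))
    cond = stack.condition_params
    karnofsky = int(cond.get("karnofsky_start", 90))
    w_mu, w_sd = cond.get("weight_kg", {}).get(stratum.gender, (75.0, 12.0))
    h_mu, h_sd = cond.get("height_cm", {}).get(stratum.gender, (170.0, 8.0))
    weight = round(max(35.0, rng.normal(w_mu, w_sd)), 1)
    height = round(max(120.0, rng.normal(h_mu, h_sd)), 1)
    asa = sample_categorical(
        stack.cum(("asa",), _normalise("asa_weights", cond.get("asa_weights", {2: 1.0}))),
        rng.random())
    menopause = ""
    if stratum.gender == "F":
        menopause = ("Postmenopausal" if age >= int(cond.get("menopause_age", 50))
                     else "Premenopausal")

    for j in range(n_dx):
        if j == 0:
            diagnosis = sample_categorical(dx_stack, rng.random())
            first_dx = diagnosis
        else:
            remaining = [(c, w) for (c, w) in _stack_weights(dx_stack) if c != first_dx]
            if remaining:
                diagnosis = sample_categorical(cumulative(_renorm(remaining)), rng.random())
            else:
                diagnosis = first_dx
            dx_date = add_months(dx_date, int(rng.integers(6, 37)))

        diagnosis_id = ids.next("d")
        code = sample_categorical(stack.cum(("icd", diagnosis), stack.icd10_codes[diagnosis]),
                                  rng.random())
        rows["diagnoses"].append({
            "diagnosis_id": diagnosis_id, "patient_id": patient_id,
            "icd10_code": code,
            "grading": sample_categorical(stack.cum(("g",), _GRADING), rng.random()),
            "tnm_t": sample_categorical(stack.cum(("t",), _TNM_T), rng.random()),
            "tnm_n": sample_categorical(stack.cum(("n",), _TNM_N), rng.random()),
            "tnm_m": sample_categorical(stack.cum(("m",), _TNM_M), rng.random()),
            "date": dx_date.isoformat(),
            "pathological_structure": diagnosis,
            "anatomical_structure": stack.anatomical_structures.get(diagnosis, ""),
            "tumor_type": "Melanoma" if diagnosis == "Melanoma" else "Carcinoma",
        })

        # therapies: geometric count, laid out in consecutive calendar months
        n_tx, month_offset = 1, 0
        while n_tx < stack.max_therapies and rng.random() < stack.therapy_continue_prob:
            n_tx += 1
        tx_stack = stack.therapy_stack(stratum.band, diagnosis)
        for _ in range(n_tx):
            tx_class = sample_categorical(tx_stack, rng.random())
            duration = int(rng.integers(1, 4))
            start = add_months(dx_date, month_offset)
            end = add_months(start, duration - 1)
            meds = _MEDICATIONS.get(tx_class)
            rows["therapies"].append({
                "therapy_id": ids.next("t"), "diagnosis_id": diagnosis_id,
                "therapy_class": tx_class,
                "medication": meds[int(rng.integers(0, len(meds)))] if meds else "",
                "start_date": start.isoformat(), "end_date": end.isoformat(),
            })
            month_offset += duration

        # monthly course chain; an event row whenever the state changes
        state = stack.initial_state
        order = 1
        events = [(0, state)]
        for month in range(1, stack.max_months + 1):
            nxt = sample_categorical(stack.transition_stack(diagnosis, state), rng.random())
            if nxt != state:
                events.append((month, nxt))
                state = nxt
            if state in stack.absorbing:
                break

        stage = f"{rows['diagnoses'][-1]['tnm_t']}{rows['diagnoses'][-1]['tnm_n']}{rows['diagnoses'][-1]['tnm_m']}"
        for month, kind in events:
            rows["courses"].append({
                "course_id": ids.next("k"), "diagnosis_id": diagnosis_id,
                "course_kind": kind, "stage": stage, "order": order,
                "date": add_months(dx_date, month).isoformat(),
            })
            order += 1
            if kind == "Progression":
                karnofsky = max(10, karnofsky - 10)
            elif kind == "Death":
                karnofsky = 0
            rows["conditions"].append({
                "condition_id": ids.next("c"), "patient_id": patient_id,
                "ref_date": add_months(dx_date, month).isoformat(),
                "age": age + month // 12, "weight_kg": weight, "height_cm": height,
                "karnofsky": karnofsky, "asa": asa, "menopause_status": menopause,
            })
    return rows


def _stack_weights(cum_stack: list[tuple[str, float]]) -> list[tuple[str, float]]:
    out, prev = [], 0.0
    for cat, bound in cum_stack:
        out.append((cat, bound - prev))
        prev = bound
    return out


def _renorm(items: list[tuple[str, float]]) -> list[tuple[str, float]]:
    total = sum(w for _, w in items)
    return [(c, w / total) for c, w in items]


def simulate_cohort(stack: DistributionStack, n: int, seed: int,
                    band: str | None = None) -> tuple[Registry, dict]:
    """Simulate *n* patients; returns the registry and a summary report.

    With ``band`` given (e.g. ``"60-64"``), all patients fall in that age
    band and only gender is drawn; otherwise both gender and band come from
    the configured stratum weights.
    """
    if n <= 0:
        raise ValueError("patient count must be >= 1")
    rng = np.random.default_rng(seed)
    ids = _Ids()
    all_rows: dict[str, list] = {name: [] for name in TABLE_COLUMNS}
    gender_cum = cumulative(stack.stratum_gender)
    band_cum = cumulative(stack.stratum_band)
    bands_of_patient: list[str] = []

    for _ in range(n):
        gender = sample_categorical(gender_cum, rng.random())
        b = band if band is not None else sample_categorical(band_cum, rng.random())
        bands_of_patient.append(b)
        rows = simulate_patient(stack, stack.stratum_for_band(b, gender), rng, ids)
        for name in all_rows:
            all_rows[name].extend(rows[name])

    registry = Registry(**{
        name: pd.DataFrame(all_rows[name], columns=TABLE_COLUMNS[name]).astype(object)
        for name in TABLE_COLUMNS
    })
    return registry, summarise(registry, stack, bands_of_patient)


def summarise(registry: Registry, stack: DistributionStack,
              bands: list[str] | None = None) -> dict:
    """Per-stratum empirical diagnosis and first-therapy frequencies."""
    patients = registry.patients
    if bands is None:
        bands = [_band_of(int(a), stack.age_bands) for a in patients["age"]]
    band_of_patient = dict(zip(patients["patient_id"], bands))

    primary = registry.diagnoses.drop_duplicates("patient_id", keep="first")
    primary_ids = set(primary["diagnosis_id"])
    first_tx = registry.therapies.drop_duplicates("diagnosis_id", keep="first")
    first_tx = first_tx[first_tx["diagnosis_id"].isin(primary_ids)]
    dx_of = dict(zip(primary["diagnosis_id"], primary["pathological_structure"]))
    pat_of = dict(zip(primary["diagnosis_id"], primary["patient_id"]))

    report: dict = {"n_patients": len(patients), "strata": {}}
    by_band: dict[str, dict] = {}
    for _, row in primary.iterrows():
        b = band_of_patient[row["patient_id"]]
        by_band.setdefault(b, {"n": 0, "diagnoses": {}})
        by_band[b]["n"] += 1
        dxs = by_band[b]["diagnoses"]
        dxs[row["pathological_structure"]] = dxs.get(row["pathological_structure"], 0) + 1
    for _, row in first_tx.iterrows():
        b = band_of_patient[pat_of[row["diagnosis_id"]]]
        tx = by_band[b].setdefault("first_therapy", {}).setdefault(dx_of[row["diagnosis_id"]], {})
        tx[row["therapy_class"]] = tx.get(row["therapy_class"], 0) + 1

    for b, info in by_band.items():
        entry = {
            "n": info["n"],
            "diagnosis_freq": {k: v / info["n"] for k, v in sorted(info["diagnoses"].items())},
            "first_therapy_freq": {},
        }
        for dx, counts in info.get("first_therapy", {}).items():
            total = sum(counts.values())
            entry["first_therapy_freq"][dx] = {k: v / total for k, v in sorted(counts.items())}
        report["strata"][b] = entry

    n_multi = int((registry.diagnoses.groupby("patient_id").size() > 1).sum())
    report["multi_diagnosis_fraction"] = n_multi / max(len(patients), 1)
    return report


def _band_of(age: int, bands: list[str]) -> str:
    for b in bands:
        lo, hi = parse_band(b)
        if age >= lo and (hi is None or age <= hi):
            return b
    raise ConfigError(f"age {age} falls outside all bands")
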