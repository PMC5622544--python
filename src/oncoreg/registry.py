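"""Tabular registry container: five relational-style tables with CSV I/O.

A registry is the relational view of an institutional cancer registry:
patients, patient conditions (time-stamped health state), diagnoses,
therapies and disease courses, linked by foreign keys.  This container is
what the simulator produces and what the RDF transformation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DataError, ReferentialIntegrityError

PATIENT_COLUMNS = ["patient_id", "gender", "birth_date", "age"]
CONDITION_COLUMNS = [
    "condition_id", "patient_id", "ref_date", "age", "weight_kg", "height_cm",
    "karnofsky", "asa", "menopause_status",
]
DIAGNOSIS_COLUMNS = [
    "diagnosis_id", "patient_id", "icd10_code", "grading", "tnm_t", "tnm_n",
    "tnm_m", "date", "pathological_structure", "anatomical_structure", "tumor_type",
]
THERAPY_COLUMNS = [
    "therapy_id", "diagnosis_id", "therapy_class", "medication", "start_date", "end_date",
]
COURSE_COLUMNS = ["course_id", "diagnosis_id", "course_kind", "stage", "order", "date"]

TABLE_COLUMNS = {
    "patients": PATIENT_COLUMNS,
    "conditions": CONDITION_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "therapies": THERAPY_COLUMNS,
    "courses": COURSE_COLUMNS,
}


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class Registry:
    """Five tables of a cancer registry, keyed as in :data:`TABLE_COLUMNS`."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty(PATIENT_COLUMNS))
    conditions: pd.DataFrame = field(default_factory=lambda: _empty(CONDITION_COLUMNS))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty(DIAGNOSIS_COLUMNS))
    therapies: pd.DataFrame = field(default_factory=lambda: _empty(THERAPY_COLUMNS))
    courses: pd.DataFrame = field(default_factory=lambda: _empty(COURSE_COLUMNS))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "conditions": self.conditions,
            "diagnoses": self.diagnoses,
            "therapies": self.therapies,
            "courses": self.courses,
        }

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, directory) -> "Registry":
        directory = Path(directory)
        frames = {}
        for name, columns in TABLE_COLUMNS.items():
            path = directory / f"{name}.csv"
            if not path.exists():
                raise DataError(f"missing registry table: {path}")
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
            missing = [c for c in columns if c not in frame.columns]
            if missing:
                raise DataError(f"{path} lacks columns: {', '.join(missing)}")
            frames[name] = frame[columns]
        return cls(**frames)

    # -- consistency -------------------------------------------------------

    def validate(self) -> None:
        """Check keys, foreign keys, date ordering and course numbering.

        Raises :class:`ReferentialIntegrityError` or :class:`DataError`
        naming the first offending row.
        """
        for name, key in (
            ("patients", "patient_id"), ("conditions", "condition_id"),
            ("diagnoses", "diagnosis_id"), ("therapies", "therapy_id"),
            ("courses", "course_id"),
        ):
            frame = self.tables()[name]
            dup = frame[key][frame[key].duplicated()]
            if not dup.empty:
                raise DataError(f"duplicate {key} in {name}: {dup.iloc[0]}")

        patient_ids = set(self.patients["patient_id"])
        diagnosis_ids = set(self.diagnoses["diagnosis_id"])
        for name, key, universe in (
            ("conditions", "patient_id", patient_ids),
            ("diagnoses", "patient_id", patient_ids),
            ("therapies", "diagnosis_id", diagnosis_ids),
            ("courses", "diagnosis_id", diagnosis_ids),
        ):
            frame = self.tables()[name]
            bad = frame[~frame[key].isin(universe)]
            if not bad.empty:
                row = bad.iloc[0]
                raise ReferentialIntegrityError(
                    f"{name} row {row.iloc[0]} references unknown {key} {row[key]!r}"
                )

        bad = self.therapies[self.therapies["start_date"] > self.therapies["end_date"]]
        if not bad.empty:
            raise DataError(f"therapy {bad.iloc[0]['therapy_id']} ends before it starts")

        birth = dict(zip(self.patients["patient_id"], self.patients["birth_date"]))
        early = self.diagnoses[
            self.diagnoses.apply(lambda r: r["date"] < birth[r["patient_id"]], axis=1)
        ] if len(self.diagnoses) else self.diagnoses
        if len(early):
            raise DataError(
                f"diagnosis {early.iloc[0]['diagnosis_id']} predates patient birth"
            )

        for diagnosis_id, group in self.courses.groupby("diagnosis_id"):
            orders = sorted(int(o) for o in group["order"])
            if orders != list(range(1, len(orders) + 1)):
                raise DataError(f"course order for {diagnosis_id} is not 1..K consecutive")
            by_order = group.assign(_o=group["order"].astype(int)).sort_values("_o")
            dates = list(by_order["date"])
            if dates != sorted(dates):
                raise DataError(f"courses of {diagnosis_id} are not date-sorted by order")
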