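"""Core EMR record types and their JSON Lines serialization.

A cohort is a collection of :class:`PatientRecord`; each record holds
demographics plus a time-ordered list of consultations, where every
consultation carries zero or more ICPC codes and a short free-text note.
This is both the output format of the synthetic generator and the reader
format for any real consultation-level data a user supplies.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

GENDERS = ("female", "male", "other")

#: ICPC code of the outcome (colon/rectum malignancy); a prefix match on the
#: first three characters of any consultation code defines a case.
CASE_PREFIX = "D75"

#: The eleven symptom/feature ICPC codes used by the tabular model, in the
#: fixed feature order: constipation, diarrhoea, changed bowel habit,
#: abdominal pain, abdominal bloating, rectal blood loss, weight loss,
#: loss of appetite, anaemia (two codes) and thrombophlebitis.
TRACKED_ICPC = ("D12", "D11", "D18", "D01", "D25", "D16",
                "T08", "T03", "B80", "B82", "K94")

_CODE_RE = re.compile(r"^[A-Z]\d\d")


@dataclass(slots=True)
class Consultation:
    """One dated GP contact: ICPC codes plus a raw free-text note."""

    date: dt.date
    icpc_codes: list[str]
    note_text: str


@dataclass(slots=True)
class PatientRecord:
    """Demographics and the time-ordered consultation history of one patient."""

    patient_id: str
    birth_date: dt.date
    gender: str
    consultations: list[Consultation]

    def last_visit(self) -> dt.date:
        if not self.consultations:
            raise ValueError(f"patient {self.patient_id} has no consultations")
        return self.consultations[-1].date


def is_valid_code(code: str) -> bool:
    """True iff the first three characters match the letter-digit-digit ICPC shape."""
    return bool(_CODE_RE.match(code))


def record_to_dict(rec: PatientRecord) -> dict:
    return {
        "patient_id": rec.patient_id,
        "birth_date": rec.birth_date.isoformat(),
        "gender": rec.gender,
        "consultations": [
            {"date": c.date.isoformat(), "icpc": list(c.icpc_codes), "text": c.note_text}
            for c in rec.consultations
        ],
    }


def record_from_dict(d: dict) -> PatientRecord:
    return PatientRecord(
        patient_id=str(d["patient_id"]),
        birth_date=dt.date.fromisoformat(d["birth_date"]),
        gender=d["gender"],
        consultations=[
            Consultation(dt.date.fromisoformat(c["date"]), list(c["icpc"]), c["text"])
            for c in d["consultations"]
        ],
    )


def write_cohort_jsonl(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec), ensure_ascii=False))
            fh.write("\n")


def read_cohort_jsonl(path) -> Iterator[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield record_from_dict(json.loads(line))
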