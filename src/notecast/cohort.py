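"""Cohort construction: labelling, observation windows, inclusion, splitting.

The outcome anchor is the date of the first consultation carrying an ICPC
code whose first three characters are ``D75`` (colon/rectum malignancy);
patients without such a code are anchored at their last GP contact.  The
observation window is the two years of record ending five months before the
anchor — the five-month gap removes the consultations in which the GP was
plausibly already working up the diagnosis (suspicion bias).  The window is
half-open on the right: ``[anchor - 880 d, anchor - 150 d)``.

Calendar arithmetic uses fixed-length units throughout the package: one
month = 30 days and one year = 365 days, which makes window boundaries
reproducible regardless of calendar alignment.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import CASE_PREFIX, TRACKED_ICPC, Consultation, PatientRecord

MONTH_DAYS = 30
YEAR_DAYS = 365
EXCLUSION_DAYS = 5 * MONTH_DAYS   # gap between window end and the anchor
WINDOW_DAYS = 2 * YEAR_DAYS       # observation window length
MIN_AGE_YEARS = 30.0              # inclusion gate: age at anchor must exceed this

PARTS = ("train", "validation", "test")
_DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)

# Characters preserved by note cleaning; everything else becomes a space.
_DISALLOWED = re.compile(r"[^a-zA-Z0-9+\-/\\]+")


class EmptyRecordError(ValueError):
    """Raised when a patient has no consultations and cannot be labelled."""


def clean_note(raw: str) -> str:
    """Minimal syntactic cleaning of a free-text note.

    Replaces every character outside ``a-z A-Z 0-9 + - / \\`` with a space,
    collapses runs of spaces, strips the ends and lowercases.  The rule is
    applied character-wise so that ordinary punctuated words survive with
    their alphabetic core intact; downstream tokenization is split-on-space.
    Deliberately keeps abbreviations, digits and typos — in short clinical
    notes these carry signal.
    """
    return " ".join(_DISALLOWED.sub(" ", raw).split()).lower()


def label_patient(record: PatientRecord) -> tuple[int, dt.date]:
    """Label one patient and return ``(label, anchor_date)``.

    Label 1 with the date of the earliest consultation carrying a code with
    prefix ``D75``; otherwise label 0 anchored at the last consultation.
    """
    if not record.consultations:
        raise EmptyRecordError(record.patient_id)
    for cons in record.consultations:  # consultations are date-ordered
        if any(code.startswith(CASE_PREFIX) for code in cons.icpc_codes):
            return 1, cons.date
    return 0, record.consultations[-1].date


@dataclass(slots=True)
class LabelledWindow:
    """A patient's label, anchor, and the consultations inside the window."""

    patient_id: str
    label: int
    anchor_date: dt.date
    window_start: dt.date
    window_end: dt.date
    consultations: list[Consultation]
    age_at_anchor: float


def extract_window(record: PatientRecord, label: int, anchor_date: dt.date) -> LabelledWindow:
    """Retain the consultations with date in ``[anchor-880d, anchor-150d)``."""
    window_end = anchor_date - dt.timedelta(days=EXCLUSION_DAYS)
    window_start = window_end - dt.timedelta(days=WINDOW_DAYS)
    kept = [c for c in record.consultations if window_start <= c.date < window_end]
    age = (anchor_date - record.birth_date).days / YEAR_DAYS
    return LabelledWindow(
        patient_id=record.patient_id,
        label=label,
        anchor_date=anchor_date,
        window_start=window_start,
        window_end=window_end,
        consultations=kept,
        age_at_anchor=age,
    )


def include_patient(window: LabelledWindow) -> bool:
    """Inclusion rule: over 30 at the anchor, and some usable window content.

    Usable content is at least one non-empty cleaned note or one occurrence
    of a tracked ICPC feature code; patients with neither carry no
    information for any of the models.
    """
    if window.age_at_anchor <= MIN_AGE_YEARS:
        return False
    for cons in window.consultations:
        if clean_note(cons.note_text):
            return True
        if any(code[:3] in TRACKED_ICPC for code in cons.icpc_codes):
            return True
    return False


def prepare_cohort(
    records,
) -> tuple[list[LabelledWindow], list[PatientRecord], int]:
    """Label, window and filter a cohort.

    Returns ``(included_windows, under_age_records, n_excluded_no_data)``.
    Patients at or under the age gate are returned separately: they never
    enter prediction, but their notes augment the embedding-training corpus.
    """
    windows: list[LabelledWindow] = []
    under_age: list[PatientRecord] = []
    n_no_data = 0
    for rec in records:
        try:
            label, anchor = label_patient(rec)
        except EmptyRecordError:
            n_no_data += 1
            continue
        win = extract_window(rec, label, anchor)
        if win.age_at_anchor <= MIN_AGE_YEARS:
            under_age.append(rec)
        elif include_patient(win):
            windows.append(win)
        else:
            n_no_data += 1
    return windows, under_age, n_no_data


@dataclass
class SplitAssignment:
    """Stratified train/validation/test assignment, 60/20/20 by default."""

    assignment: dict[str, str]
    seed: int

    def part(self, name: str) -> list[str]:
        return [pid for pid, p in self.assignment.items() if p == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignment), "part": list(self.assignment.values())}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "SplitAssignment":
        return cls(dict(zip(frame["patient_id"].astype(str), frame["part"])), seed)


def _allocate(n: int, fractions) -> list[int]:
    """Largest-remainder allocation of n items to len(fractions) parts."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def split_data(
    windows: list[LabelledWindow],
    seed: int,
    fractions=_DEFAULT_FRACTIONS,
) -> SplitAssignment:
    """Random label-stratified split, deterministic given the seed.

    Within each label class the patients are shuffled and allocated to the
    three parts by largest-remainder rounding, so class prevalence in every
    part is within one patient of exact stratification.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in (0, 1):
        ids = sorted(w.patient_id for w in windows if w.label == label)
        if len(ids) < 5:
            raise ValueError(
                f"cannot stratify: label {label} has only {len(ids)} patients (need >= 5)"
            )
        rng.shuffle(ids)
        sizes = _allocate(len(ids), fractions)
        pos = 0
        for part, size in zip(PARTS, sizes):
            for pid in ids[pos : pos + size]:
                assignment[pid] = part
            pos += size
    return SplitAssignment(assignment, seed)


# ---------------------------------------------------------------------------
# serialization

def window_to_dict(w: LabelledWindow) -> dict:
    return {
        "patient_id": w.patient_id,
        "label": w.label,
        "anchor_date": w.anchor_date.isoformat(),
        "window_start": w.window_start.isoformat(),
        "window_end": w.window_end.isoformat(),
        "age_at_anchor": w.age_at_anchor,
        "consultations": [
            {"date": c.date.isoformat(), "icpc": list(c.icpc_codes), "text": c.note_text}
            for c in w.consultations
        ],
    }


def window_from_dict(d: dict) -> LabelledWindow:
    return LabelledWindow(
        patient_id=str(d["patient_id"]),
        label=int(d["label"]),
        anchor_date=dt.date.fromisoformat(d["anchor_date"]),
        window_start=dt.date.fromisoformat(d["window_start"]),
        window_end=dt.date.fromisoformat(d["window_end"]),
        consultations=[
            Consultation(dt.date.fromisoformat(c["date"]), list(c["icpc"]), c["text"])
            for c in d["consultations"]
        ],
        age_at_anchor=float(d["age_at_anchor"]),
    )


def write_windows_jsonl(windows, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in windows:
            fh.write(json.dumps(window_to_dict(w), ensure_ascii=False))
            fh.write("\n")


def read_windows_jsonl(path) -> list[LabelledWindow]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(window_from_dict(json.loads(line)))
    return out
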