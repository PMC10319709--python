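"""Patient representations: aggregated text vectors and tabular features.

Each included patient becomes two blocks:

* ``Text_p`` — the elementwise aggregate (mean by default) of the target
  vectors of all in-vocabulary tokens pooled from the cleaned notes in the
  patient's window.  Out-of-vocabulary tokens are skipped; a patient with
  no in-vocabulary tokens keeps a zero vector rather than being excluded,
  so cohort composition stays identical across the three models.
* ``Aux_p`` — a fixed-order length-15 vector: normalised age, a three-way
  gender one-hot (female, male, other), and the normalised occurrence
  counts of the eleven tracked ICPC codes (prefix match on the first three
  characters, duplicates counted multiply).

Normalisation statistics (z-score by default, min-max available) are fit on
the training split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LabelledWindow, clean_note
from .embed import EmbeddingMatrix, apply_bigrams
from .records import GENDERS, TRACKED_ICPC

log = logging.getLogger(__name__)

AGGREGATORS = {"mean": np.mean, "sum": np.sum, "max": np.max, "min": np.min}

#: gender missing from a record is not expected; the one-hot order is fixed
GENDER_INDEX = {g: i for i, g in enumerate(GENDERS)}

TAB_DIM = 1 + len(GENDERS) + len(TRACKED_ICPC)  # age + one-hot + 11 counts = 15


@dataclass(slots=True)
class PatientFeatures:
    patient_id: str
    label: int
    text_vector: np.ndarray
    tab_vector: np.ndarray
    n_tokens_in_vocab: int


def count_tracked_codes(window: LabelledWindow) -> np.ndarray:
    """Occurrence counts of the 11 tracked ICPC codes over window consultations."""
    counts = np.zeros(len(TRACKED_ICPC), dtype=float)
    idx = {c: i for i, c in enumerate(TRACKED_ICPC)}
    for cons in window.consultations:
        for code in cons.icpc_codes:
            i = idx.get(code[:3])
            if i is not None:
                counts[i] += 1.0
    return counts


def window_gender(window: LabelledWindow, gender_by_id: dict) -> str:
    return gender_by_id[window.patient_id]


@dataclass
class TabularStats:
    """Training-split normalisation statistics for age + 11 code counts."""

    mean: np.ndarray
    sd: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray


def fit_tabular_stats(train_windows) -> TabularStats:
    raw = np.array(
        [[w.age_at_anchor, *count_tracked_codes(w)] for w in train_windows], dtype=float
    )
    if raw.size == 0:
        raise ValueError("no training windows to fit normalisation statistics on")
    return TabularStats(
        mean=raw.mean(axis=0),
        sd=raw.std(axis=0),
        minimum=raw.min(axis=0),
        maximum=raw.max(axis=0),
    )


def tabular_features(
    window: LabelledWindow,
    gender: str,
    stats: TabularStats,
    scaling: str = "zscore",
) -> np.ndarray:
    """Aux_p: [normalised age, gender one-hot, 11 normalised ICPC counts]."""
    raw = np.concatenate([[window.age_at_anchor], count_tracked_codes(window)])
    if scaling == "zscore":
        sd = stats.sd
        degenerate = sd == 0
        if np.any(degenerate):
            log.warning("zero-variance tabular feature(s) mapped to 0: %s",
                        np.nonzero(degenerate)[0].tolist())
        scaled = np.where(degenerate, 0.0, (raw - stats.mean) / np.where(degenerate, 1.0, sd))
    elif scaling == "minmax":
        span = stats.maximum - stats.minimum
        degenerate = span == 0
        scaled = np.where(
            degenerate, 0.0, (raw - stats.minimum) / np.where(degenerate, 1.0, span)
        )
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    onehot = np.zeros(len(GENDERS))
    onehot[GENDER_INDEX[gender]] = 1.0
    return np.concatenate([scaled[:1], onehot, scaled[1:]])


def embed_patient(
    window: LabelledWindow,
    emb: EmbeddingMatrix,
    aggregator: str = "mean",
) -> tuple[np.ndarray, int]:
    """Text_p: aggregate of in-vocabulary token vectors pooled over all notes.

    Returns ``(vector, n_tokens_in_vocab)``; a window with zero
    in-vocabulary tokens yields the zero vector.  The same bigram merges
    used at embedding-training time are applied to the window's tokens
    first, so phrased tokens hit their learned vectors.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    toks: list[str] = []
    for cons in window.consultations:
        toks.extend(clean_note(cons.note_text).split())
    toks = apply_bigrams(toks, emb.bigrams)
    idx = [emb.index[t] for t in toks if t in emb.index]
    if not idx:
        return np.zeros(emb.d), 0
    vectors = emb.W[np.asarray(idx)]
    return AGGREGATORS[aggregator](vectors, axis=0), len(idx)


def build_features(
    windows,
    emb: EmbeddingMatrix,
    stats: TabularStats,
    gender_by_id: dict,
    aggregator: str = "mean",
    scaling: str = "zscore",
) -> list[PatientFeatures]:
    feats = []
    for w in windows:
        text, n_in_vocab = embed_patient(w, emb, aggregator)
        tab = tabular_features(w, gender_by_id[w.patient_id], stats, scaling)
        feats.append(PatientFeatures(w.patient_id, w.label, text, tab, n_in_vocab))
    return feats


def features_to_frame(feats) -> pd.DataFrame:
    """Persistable wide table: patient_id, label, tab_1..tab_15, txt_1..txt_d."""
    d = len(feats[0].text_vector) if feats else 0
    cols = (
        ["patient_id", "label"]
        + [f"tab_{i+1}" for i in range(TAB_DIM)]
        + [f"txt_{i+1}" for i in range(d)]
    )
    rows = [
        [f.patient_id, f.label, *f.tab_vector.tolist(), *f.text_vector.tolist()]
        for f in feats
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_features(frame: pd.DataFrame) -> list[PatientFeatures]:
    tab_cols = [c for c in frame.columns if c.startswith("tab_")]
    txt_cols = [c for c in frame.columns if c.startswith("txt_")]
    out = []
    for _, row in frame.iterrows():
        out.append(
            PatientFeatures(
                str(row["patient_id"]),
                int(row["label"]),
                row[txt_cols].to_numpy(dtype=float),
                row[tab_cols].to_numpy(dtype=float),
                n_tokens_in_vocab=-1,
            )
        )
    return out
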