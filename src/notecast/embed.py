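"""Offline word embeddings: vocabulary, bigram phrasing, subsampling, SGNS.

Embeddings are learned offline — on the cleaned notes of the training-split
windows plus the notes of patients below the age gate — and are frozen for
the downstream prediction task.  Training is skip-gram with negative
sampling (SGNS): for every retained centre token w and context token c
within a per-position dynamic window, one stochastic gradient step on

    L = -log s(W_w . C_c) - sum_{i=1..k} log s(-W_w . C_{n_i})

with negatives n_i drawn from the unigram^(3/4) distribution and s the
logistic function.  Frequent tokens are removed before windowing with keep
probability min(1, sqrt(t/f)), which shrinks effective context distances
exactly as the canonical implementation does.  Adjacent high-association
pairs are merged into single "a_b" tokens in one phrasing pass before
subsampling.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .cohort import clean_note

__all__ = [
    "Vocabulary",
    "EmbeddingMatrix",
    "build_vocabulary",
    "bigram_score",
    "detect_bigrams",
    "apply_bigrams",
    "keep_probability",
    "sgns_pair_loss_and_grad",
    "train_sgns",
    "build_training_corpus",
    "save_embeddings",
    "load_embeddings",
]


# --- vocabulary -------------------------------------------------------------

@dataclass
class Vocabulary:
    """Min-count-filtered token inventory with raw corpus counts.

    ``total`` is the corpus token count *before* filtering, so
    ``counts/total`` are true corpus frequencies f(w).
    """

    tokens: list[str]
    counts: np.ndarray
    total: int
    min_count: int = 3
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def frequencies(self) -> np.ndarray:
        return self.counts / self.total


def build_vocabulary(corpus, min_count: int = 3) -> Vocabulary:
    """Count tokens, then drop those with count < min_count.

    The low default threshold deliberately keeps rare misspelling variants,
    which are abundant in GP notes and can carry signal.
    """
    counter: Counter = Counter()
    total = 0
    for note in corpus:
        counter.update(note)
        total += len(note)
    if total == 0:
        raise ValueError("empty corpus")
    kept = sorted(
        ((t, c) for t, c in counter.items() if c >= min_count),
        key=lambda tc: (-tc[1], tc[0]),
    )
    tokens = [t for t, _ in kept]
    counts = np.array([c for _, c in kept], dtype=np.int64)
    return Vocabulary(tokens, counts, total, min_count)


# --- bigram phrasing --------------------------------------------------------

def bigram_score(count_ab: int, count_a: int, count_b: int, total: int, delta: float) -> float:
    """Discounted association score of an adjacent pair."""
    return (count_ab - delta) * total / (count_a * count_b)


def detect_bigrams(corpus, delta: float = 5.0, threshold: float = 10.0):
    """One phrasing pass: merge adjacent pairs scoring above the threshold.

    Returns ``(merged_corpus, bigrams)`` where ``bigrams`` is a frozenset of
    (a, b) pairs.  Merging is greedy left-to-right without overlap, and the
    merged token is spelled ``a_b``.
    """
    uni: Counter = Counter()
    pairs: Counter = Counter()
    total = 0
    for note in corpus:
        uni.update(note)
        total += len(note)
        pairs.update(zip(note, note[1:]))
    bigrams = frozenset(
        pair
        for pair, cab in pairs.items()
        if bigram_score(cab, uni[pair[0]], uni[pair[1]], total, delta) > threshold
    )
    return [apply_bigrams(note, bigrams) for note in corpus], bigrams


def apply_bigrams(tokens, bigrams) -> list[str]:
    """Greedy non-overlapping merge of detected pairs in one token list."""
    if not bigrams:
        return list(tokens)
    out = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and (tokens[i], tokens[i + 1]) in bigrams:
            out.append(tokens[i] + "_" + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


# --- subsampling ------------------------------------------------------------

def keep_probability(f, t: float = 1e-5):
    """Keep probability min(1, sqrt(t/f)) for a token of corpus frequency f.

    Tokens with f <= t are always kept; above the threshold the discard
    probability grows with frequency while the frequency ranking is
    preserved.  Accepts scalars or arrays.
    """
    f_arr = np.asarray(f, dtype=float)
    if t <= 0:
        raise ValueError("subsampling threshold t must be > 0")
    if np.any(f_arr <= 0) or np.any(f_arr > 1):
        raise ValueError("corpus frequency must be in (0, 1]")
    out = np.minimum(1.0, np.sqrt(t / f_arr))
    return float(out) if np.isscalar(f) else out


# --- SGNS -------------------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def sgns_pair_loss_and_grad(w, c_pos, c_negs):
    """Loss and analytic gradients for one (centre, context, negatives) step.

    Returns ``(loss, grad_w, grad_c_pos, grad_c_negs)``; the reference
    single-pair form of the objective, used for gradient verification.
    """
    w = np.asarray(w, float)
    c_pos = np.asarray(c_pos, float)
    c_negs = np.atleast_2d(np.asarray(c_negs, float))
    pos = float(w @ c_pos)
    negs = c_negs @ w
    loss = float(np.logaddexp(0.0, -pos) + np.logaddexp(0.0, negs).sum())
    g_pos = _sigmoid(pos) - 1.0
    g_negs = _sigmoid(negs)
    grad_w = g_pos * c_pos + g_negs @ c_negs
    grad_c_pos = g_pos * w
    grad_c_negs = g_negs[:, None] * w[None, :]
    return loss, grad_w, grad_c_pos, grad_c_negs


@dataclass
class EmbeddingMatrix:
    """Trained target (W) and context (C) vectors over a vocabulary."""

    tokens: list[str]
    W: np.ndarray
    C: np.ndarray
    params: dict
    bigrams: frozenset = frozenset()
    epoch_losses: list = field(default_factory=list)
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def vector(self, token: str):
        i = self.index.get(token)
        return None if i is None else self.W[i]


def train_sgns(
    corpus,
    d: int = 300,
    window: int = 5,
    k_neg: int = 5,
    t: float = 1e-5,
    min_count: int = 3,
    epochs: int = 5,
    lr0: float = 0.025,
    lr_min: float = 1e-4,
    batch_size: int = 256,
    seed: int = 0,
    vocab: Vocabulary | None = None,
    bigrams: frozenset = frozenset(),
) -> EmbeddingMatrix:
    """Train skip-gram negative-sampling embeddings on a phrased corpus.

    Per epoch: tokens are re-subsampled, the context radius of each centre
    position is drawn uniformly from 1..window, and gradient steps are taken
    over shuffled mini-batches of pairs with a linearly decaying learning
    rate.  Deterministic given the seed.  The average per-pair loss of every
    epoch is recorded in ``epoch_losses``.
    """
    if vocab is None:
        vocab = build_vocabulary(corpus, min_count)
    V = len(vocab)
    if V < 2:
        raise ValueError(f"vocabulary has {V} tokens; need at least 2")

    note_ids = []
    for note in corpus:
        ids = [vocab.index[tok] for tok in note if tok in vocab.index]
        if ids:
            note_ids.append(np.asarray(ids, dtype=np.int64))
    flat = np.concatenate(note_ids) if note_ids else np.empty(0, dtype=np.int64)
    sent = np.repeat(np.arange(len(note_ids)), [len(a) for a in note_ids])

    keep = np.minimum(1.0, np.sqrt(t / vocab.frequencies()))
    neg_w = vocab.counts.astype(float) ** 0.75
    neg_cdf = np.cumsum(neg_w / neg_w.sum())

    rng = np.random.default_rng(seed)
    W = (rng.random((V, d)) - 0.5) / d
    C = np.zeros((V, d))
    losses: list[float] = []

    for epoch in range(epochs):
        mask = rng.random(flat.size) < keep[flat]
        toks = flat[mask]
        sids = sent[mask]
        centers_parts = []
        contexts_parts = []
        if toks.size >= 2:
            radii = rng.integers(1, window + 1, toks.size)
            for off in range(1, window + 1):
                if toks.size <= off:
                    break
                same = sids[:-off] == sids[off:]
                fwd = same & (radii[:-off] >= off)   # centre i, context i+off
                bwd = same & (radii[off:] >= off)    # centre i+off, context i
                centers_parts.append(toks[:-off][fwd])
                contexts_parts.append(toks[off:][fwd])
                centers_parts.append(toks[off:][bwd])
                contexts_parts.append(toks[:-off][bwd])
        if centers_parts:
            centers = np.concatenate(centers_parts)
            contexts = np.concatenate(contexts_parts)
        else:
            losses.append(float("nan"))
            continue
        order = rng.permutation(centers.size)
        centers = centers[order]
        contexts = contexts[order]

        total_loss = 0.0
        n_pairs = centers.size
        for b0 in range(0, n_pairs, batch_size):
            progress = (epoch + b0 / n_pairs) / epochs
            lr = lr0 + (lr_min - lr0) * progress
            wi = centers[b0 : b0 + batch_size]
            ci = contexts[b0 : b0 + batch_size]
            B = wi.size
            ni = np.searchsorted(neg_cdf, rng.random((B, k_neg)), side="right")
            Wb = W[wi]
            Cp = C[ci]
            Cn = C[ni]
            pos = np.einsum("bd,bd->b", Wb, Cp)
            neg = np.einsum("bd,bkd->bk", Wb, Cn)
            total_loss += float(np.logaddexp(0.0, -pos).sum() + np.logaddexp(0.0, neg).sum())
            g_pos = _sigmoid(pos) - 1.0
            g_neg = _sigmoid(neg)
            grad_W = g_pos[:, None] * Cp + np.einsum("bk,bkd->bd", g_neg, Cn)
            np.add.at(W, wi, -lr * grad_W)
            np.add.at(C, ci, -lr * (g_pos[:, None] * Wb))
            np.add.at(C, ni.ravel(), (-lr * (g_neg[..., None] * Wb[:, None, :])).reshape(-1, d))
        losses.append(total_loss / n_pairs)

    params = {
        "d": d, "window": window, "k_neg": k_neg, "t": t, "min_count": min_count,
        "epochs": epochs, "lr0": lr0, "lr_min": lr_min, "batch_size": batch_size,
        "seed": seed,
    }
    return EmbeddingMatrix(list(vocab.tokens), W, C, params, bigrams, losses)


# --- corpus assembly --------------------------------------------------------

def build_training_corpus(windows, split, under_age_records=()) -> list[list[str]]:
    """Cleaned notes of training-split windows plus under-age patients' notes.

    Validation- and test-split notes never enter embedding training; the
    under-age pool (patients excluded from prediction by the age gate)
    enlarges the corpus without any leakage risk.
    """
    train_ids = {pid for pid, part in split.assignment.items() if part == "train"}
    corpus: list[list[str]] = []
    for w in windows:
        if w.patient_id in train_ids:
            for cons in w.consultations:
                toks = clean_note(cons.note_text).split()
                if toks:
                    corpus.append(toks)
    for rec in under_age_records:
        for cons in rec.consultations:
            toks = clean_note(cons.note_text).split()
            if toks:
                corpus.append(toks)
    return corpus


# --- persistence ------------------------------------------------------------

def save_embeddings(emb: EmbeddingMatrix, path, matrix_path=None) -> None:
    """Write 'token v1 ... vd' lines plus a JSON sidecar of hyperparameters."""
    with open(path, "w", encoding="utf-8") as fh:
        for tok, row in zip(emb.tokens, emb.W):
            fh.write(tok + " " + " ".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "params": emb.params,
        "bigrams": sorted(list(p) for p in emb.bigrams),
        "epoch_losses": [float(x) for x in emb.epoch_losses],
    }
    with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
    if matrix_path is not None:
        np.save(matrix_path, emb.W)


def load_embeddings(path) -> EmbeddingMatrix:
    tokens: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    W = np.asarray(rows, dtype=float)
    try:
        with open(str(path) + ".meta.json", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        params = sidecar.get("params", {})
        bigrams = frozenset(tuple(p) for p in sidecar.get("bigrams", []))
        losses = sidecar.get("epoch_losses", [])
    except FileNotFoundError:
        params, bigrams, losses = {}, frozenset(), []
    return EmbeddingMatrix(tokens, W, np.zeros_like(W), params, bigrams, losses)
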