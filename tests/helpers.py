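"""Independent brute-force oracles used to verify the evaluation metrics.

Everything here is deliberately naive — O(n^2) pair counting and explicit
threshold enumeration — and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def auroc_brute(scores, labels) -> float:
    """Pair counting over all positive-negative pairs, ties worth one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_points_brute(scores, labels):
    """(threshold, precision, recall) at every distinct threshold, by counting."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    points = []
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int(((y == 1) & pred).sum())
        points.append((thr, tp / int(pred.sum()), tp / n_pos))
    return points


def auprc_brute(scores, labels) -> float:
    """Step-wise area: precision at each threshold times the recall increment."""
    area = 0.0
    prev_recall = 0.0
    for _, precision, recall in pr_points_brute(scores, labels):
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def best_specificity_at_sensitivity_brute(scores, labels, min_sens: float) -> float:
    """Max specificity over every candidate threshold meeting the constraint."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    best = None
    for thr in [np.inf] + sorted(set(s), reverse=True):
        sens = float(np.mean(pos >= thr))
        if sens >= min_sens:
            spec = float(np.mean(neg < thr))
            best = spec if best is None else max(best, spec)
    return best
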