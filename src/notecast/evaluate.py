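"""Evaluation protocol: discrimination, PR analysis, constrained specificity,
Brier scores, LOWESS calibration, and paired percentile-bootstrap comparison.

All interval estimates come from resampling the fixed test set with
replacement (1000 replicates by default): each metric is reported as the
replicate median with a 95% interval from the 2.5th and 97.5th percentiles.
Model pairs are compared on per-replicate AUROC differences computed on the
*same* resample indices (paired bootstrap); a pair differs significantly at
p < 0.05 when 0 falls outside the percentile interval of the differences.

The decision threshold for specificity is the most stringent one that still
reaches the required sensitivity (0.95 by default), recomputed inside every
bootstrap replicate — which is what makes the specificity intervals wide on
rare outcomes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)

__all__ = [
    "auroc",
    "PRCurve",
    "pr_curve_and_auprc",
    "threshold_for_sensitivity",
    "specificity_at",
    "brier",
    "brier_skill",
    "CalibrationCurve",
    "calibration_curve",
    "MetricSummary",
    "ComparisonResult",
    "bootstrap_evaluate",
    "plot_pr_curves",
    "plot_calibration_curves",
]


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Mann-Whitney formulation with ties counted one half; invariant under
    any strictly increasing transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos, n_neg = _check_classes(y)
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class PRCurve:
    """Precision and recall at every distinct score threshold (descending)."""

    thresholds: np.ndarray
    precisions: np.ndarray
    recalls: np.ndarray
    auprc: float
    #: (threshold, precision, recall) at caller-supplied decision thresholds
    annotations: list = field(default_factory=list)


def pr_curve_and_auprc(scores, labels, annotate_thresholds=()) -> PRCurve:
    """PR curve over all distinct thresholds; area by the step-wise rule.

    The area sums precision at each threshold weighted by the recall
    increment (average precision); no interpolation between points, which
    is biased in PR space.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("at least one positive required for a PR curve")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    pred_pos = np.arange(1, s.size + 1)
    # indices of the last occurrence of each distinct score
    last = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    thresholds = s_sorted[last]
    precisions = tp[last] / pred_pos[last]
    recalls = tp[last] / n_pos
    rec_prev = np.concatenate([[0.0], recalls[:-1]])
    area = float(np.sum((recalls - rec_prev) * precisions))
    curve = PRCurve(thresholds, precisions, recalls, area)
    for thr in annotate_thresholds:
        mask = s >= thr
        n_pred = int(mask.sum())
        tp_at = int((y[mask] == 1).sum())
        prec = tp_at / n_pred if n_pred else float("nan")
        curve.annotations.append((float(thr), prec, tp_at / n_pos))
    return curve


def threshold_for_sensitivity(scores, labels, min_sens: float = 0.95) -> float:
    """Largest threshold tau (positive iff score >= tau) with sensitivity >= min_sens.

    Maximises specificity subject to the sensitivity constraint; with
    ``min_sens=0`` the constraint is vacuous and tau sits above the maximum
    score.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_classes(y)
    pos_sorted = np.sort(s[y == 1])
    n_pos = pos_sorted.size
    candidates = np.concatenate([[np.inf], np.unique(s)[::-1]])
    # sensitivity at tau = fraction of positives with score >= tau
    sens = (n_pos - np.searchsorted(pos_sorted, candidates, side="left")) / n_pos
    ok = np.nonzero(sens >= min_sens)[0]
    return float(candidates[ok[0]])


def specificity_at(scores, labels, threshold: float) -> float:
    """True-negative rate when predicting positive iff score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    neg = s[y == 0]
    if neg.size == 0:
        raise ValueError("no negatives")
    return float(np.mean(neg < threshold))


def brier(probabilities, labels) -> float:
    """Mean squared error of the predicted probabilities."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=float)
    return float(np.mean((p - y) ** 2))


def brier_skill(model_brier: float, reference_brier: float) -> float:
    """Skill 1 - B_model/B_ref versus a non-informative reference.

    Standard references: the constant-prevalence predictor and the
    constant-zero ("no cancer") predictor.  1 is maximal improvement, 0 is
    none, negative is worse than the reference.
    """
    if reference_brier <= 0:
        raise ValueError("reference Brier score must be > 0")
    return 1.0 - model_brier / reference_brier


@dataclass
class CalibrationCurve:
    """LOWESS-smoothed observed rate against predicted probability."""

    predicted: np.ndarray
    observed: np.ndarray
    percentile_99: float


def calibration_curve(probabilities, labels, lowess_fraction: float = 0.6) -> CalibrationCurve:
    """Locally weighted linear smoothing of outcomes against predictions.

    The empirical 99th percentile of the predictions is recorded as the
    display cutoff: with a rare outcome, everything above it is estimated
    from a handful of patients and is expected to look uncalibrated.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size < 50:
        raise ValueError("need at least 50 observations for a calibration curve")
    if p.max() == p.min():
        # constant predictor: the curve degenerates to one point
        return CalibrationCurve(
            predicted=np.sort(p),
            observed=np.full(p.size, y.mean()),
            percentile_99=float(np.percentile(p, 99)),
        )
    # it=0: robustness reweighting would treat the rare 1s of a binary
    # outcome as outliers and collapse the smooth towards 0.  delta keeps
    # the smoother near-linear in n without visible change.
    delta = 0.001 * (p.max() - p.min())
    sm = lowess(y, p, frac=lowess_fraction, it=0, delta=delta, return_sorted=True)
    return CalibrationCurve(
        predicted=sm[:, 0],
        observed=np.clip(sm[:, 1], 0.0, 1.0),
        percentile_99=float(np.percentile(p, 99)),
    )


@dataclass
class MetricSummary:
    metric: str
    point: float
    median: float
    ci_low: float
    ci_high: float


@dataclass
class ComparisonResult:
    pair: tuple
    differences: np.ndarray
    median_diff: float
    ci_low: float
    ci_high: float
    significant: bool


_METRICS = ("auroc", "auprc", "specificity", "brier")


def _replicate_metrics(s: np.ndarray, y: np.ndarray, min_sens: float) -> tuple:
    a = auroc(s, y)
    ap = pr_curve_and_auprc(s, y).auprc
    tau = threshold_for_sensitivity(s, y, min_sens)
    sp = specificity_at(s, y, tau)
    return a, ap, sp, brier(np.clip(s, 0.0, 1.0), y)


def bootstrap_evaluate(
    scores_by_model: dict,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    min_sens: float = 0.95,
):
    """Paired percentile bootstrap of the full metric panel.

    Draws ``n_boot`` resamples of patient indices (with replacement, size =
    test n); the same index vector is applied to every model within a
    replicate.  Resamples holding a single outcome class are redrawn so the
    replicate count stays fixed.  Returns
    ``(summaries, comparisons)``: per-model :class:`MetricSummary` for
    AUROC, AUPRC, specificity at the sensitivity constraint, and Brier
    score; and a :class:`ComparisonResult` of AUROC differences per model
    pair.  Deterministic given the seed.
    """
    y = np.asarray(labels)
    n = y.size
    _check_classes(y)
    models = {name: np.asarray(s, dtype=float) for name, s in scores_by_model.items()}
    for name, s in models.items():
        if s.size != n:
            raise ValueError(f"scores for {name!r} have length {s.size}, expected {n}")

    rng = np.random.default_rng(seed)
    per_rep = {name: np.empty((n_boot, len(_METRICS))) for name in models}
    n_redrawn = 0
    for rep in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            ys = y[idx]
            if 0 < ys.sum() < n:
                break
            n_redrawn += 1
        for name, s in models.items():
            per_rep[name][rep] = _replicate_metrics(s[idx], ys, min_sens)
    if n_redrawn:
        log.info("redrew %d single-class bootstrap resamples", n_redrawn)

    summaries: dict = {}
    for name, s in models.items():
        point = _replicate_metrics(s, y, min_sens)
        summaries[name] = {
            metric: MetricSummary(
                metric=metric,
                point=float(point[j]),
                median=float(np.median(per_rep[name][:, j])),
                ci_low=float(np.percentile(per_rep[name][:, j], 2.5)),
                ci_high=float(np.percentile(per_rep[name][:, j], 97.5)),
            )
            for j, metric in enumerate(_METRICS)
        }

    comparisons: dict = {}
    for a, b in itertools.combinations(models, 2):
        diffs = per_rep[a][:, 0] - per_rep[b][:, 0]
        lo = float(np.percentile(diffs, 2.5))
        hi = float(np.percentile(diffs, 97.5))
        comparisons[(a, b)] = ComparisonResult(
            pair=(a, b),
            differences=diffs,
            median_diff=float(np.median(diffs)),
            ci_low=lo,
            ci_high=hi,
            significant=bool(lo > 0.0 or hi < 0.0),
        )
    return summaries, comparisons


# --- plotting ---------------------------------------------------------------

def plot_pr_curves(scores_by_model, labels, path, annotate_thresholds=(0.01, 0.02, 0.05)):
    """PR curves per model with labelled decision-threshold dots."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111)
    for name, s in scores_by_model.items():
        curve = pr_curve_and_auprc(s, labels, annotate_thresholds)
        ax.plot(curve.recalls, curve.precisions, label=f"{name} (AUPRC={curve.auprc:.3f})")
        for thr, prec, rec in curve.annotations:
            if np.isfinite(prec):
                ax.plot(rec, prec, "o", ms=4, color="black")
                ax.annotate(f"{thr:g}", (rec, prec), fontsize=7,
                            textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("Recall (sensitivity)")
    ax.set_ylabel("Precision (PPV)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)


def plot_calibration_curves(scores_by_model, labels, path, lowess_fraction: float = 0.6):
    """LOWESS calibration curves with the 99th-percentile display marker."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111)
    for name, s in scores_by_model.items():
        curve = calibration_curve(s, labels, lowess_fraction)
        (line,) = ax.plot(curve.predicted, curve.observed, label=name)
        ax.axvline(curve.percentile_99, ls=":", lw=0.8, color=line.get_color())
    lim = ax.get_xlim()
    ax.plot(lim, lim, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Smoothed observed rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
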