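"""The three logistic risk models: Tab, Txt and TabTxt.

All three are a single sigmoid output over a feature block — structured
features only (Tab, 15 inputs), the aggregated text embedding only (Txt, d
inputs), or their concatenation (TabTxt, 15+d).  Training minimises mean
binary cross-entropy with Adam over shuffled mini-batches, with early
stopping on validation loss; the weights from the best validation epoch are
returned.  The embeddings feeding the Txt block are frozen: only the
logistic layer is trained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .represent import PatientFeatures, TAB_DIM

KINDS = ("Tab", "Txt", "TabTxt")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def assemble_inputs(kind: str, feats: list[PatientFeatures]) -> np.ndarray:
    """Stack the feature block(s) the given model kind consumes."""
    if kind == "Tab":
        return np.array([f.tab_vector for f in feats], dtype=float)
    if kind == "Txt":
        return np.array([f.text_vector for f in feats], dtype=float)
    if kind == "TabTxt":
        return np.array(
            [np.concatenate([f.tab_vector, f.text_vector]) for f in feats], dtype=float
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {KINDS}")


def labels_of(feats: list[PatientFeatures]) -> np.ndarray:
    return np.array([f.label for f in feats], dtype=float)


@dataclass
class RiskModel:
    kind: str
    weights: np.ndarray
    intercept: float
    metadata: dict = field(default_factory=dict)


def _bce(z: np.ndarray, y: np.ndarray, w=None, l2: float = 0.0) -> float:
    # mean BCE via log-sum-exp: y*softplus(-z) + (1-y)*softplus(z)
    loss = float(np.mean(y * np.logaddexp(0.0, -z) + (1.0 - y) * np.logaddexp(0.0, z)))
    if l2 and w is not None:
        loss += 0.5 * l2 * float(w @ w)
    return loss


def train_lr(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    kind: str = "Tab",
    max_epochs: int = 300,
    batch_size: int = 64,
    patience: int = 30,
    lr: float = 1e-3,
    betas: tuple = (0.9, 0.999),
    eps: float = 1e-8,
    l2: float = 0.0,
    standardize: bool = True,
    seed: int = 0,
) -> RiskModel:
    """Fit the logistic layer by mini-batch Adam with early stopping.

    Stops when validation loss has not improved for ``patience`` epochs or
    at ``max_epochs``; the returned weights are those of the best
    validation epoch.  Deterministic given the seed.

    ``standardize`` preconditions the optimisation: input columns are
    z-scored on training statistics before fitting and the transform is
    folded back into the returned weights, so the model still operates on
    raw features.  Without it, Adam and any L2 penalty treat the
    small-scale text-embedding block and the unit-scale tabular block on
    grossly unequal footing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if len(np.unique(y)) < 2 or len(np.unique(np.asarray(y_val))) < 2:
        raise ValueError("training and validation sets must each contain both classes")
    if standardize:
        col_mean = X.mean(axis=0)
        col_sd = X.std(axis=0)
        col_sd[col_sd == 0] = 1.0
        X = (X - col_mean) / col_sd
        X_val = (X_val - col_mean) / col_sd
    n, dim = X.shape
    rng = np.random.default_rng(seed)

    w = np.zeros(dim)
    b = 0.0
    m = np.zeros(dim + 1)
    v = np.zeros(dim + 1)
    b1, b2 = betas
    step = 0

    def val_loss(wv, bv):
        return _bce(X_val @ wv + bv, np.asarray(y_val, dtype=float), wv, l2)

    best = (np.inf, w.copy(), b, 0)
    stale = 0
    epochs_run = 0
    for epoch in range(1, max_epochs + 1):
        epochs_run = epoch
        perm = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = perm[lo : lo + batch_size]
            Xb, yb = X[idx], y[idx]
            p = _sigmoid(Xb @ w + b)
            resid = (p - yb) / len(idx)
            g = np.concatenate([Xb.T @ resid + l2 * w, [resid.sum()]])
            step += 1
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** step)
            vh = v / (1 - b2 ** step)
            upd = lr * mh / (np.sqrt(vh) + eps)
            w -= upd[:-1]
            b -= upd[-1]
        vl = val_loss(w, b)
        if vl < best[0] - 1e-12:
            best = (vl, w.copy(), b, epoch)
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    vl_best, w_best, b_best, best_epoch = best
    if standardize:
        # fold the z-score transform back: w.(x-m)/s + b == (w/s).x + (b - w.m/s)
        w_best = w_best / col_sd
        b_best = b_best - float(w_best @ col_mean)
    return RiskModel(
        kind=kind,
        weights=w_best,
        intercept=float(b_best),
        metadata={
            "epochs_run": epochs_run,
            "early_stop_epoch": best_epoch,
            "final_val_loss": float(vl_best),
            "seed": seed,
            "batch_size": batch_size,
            "max_epochs": max_epochs,
            "patience": patience,
            "lr": lr,
            "l2": l2,
        },
    )


def predict(model: RiskModel, X: np.ndarray) -> np.ndarray:
    """Risk probabilities sigma(w.x + b) for a matrix or a single vector."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match model dimension "
            f"{model.weights.shape[0]}"
        )
    p = _sigmoid(X @ model.weights + model.intercept)
    return float(p[0]) if single else p


def save_model(model: RiskModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "kind": model.kind,
                "weights": model.weights.tolist(),
                "intercept": model.intercept,
                "metadata": model.metadata,
            },
            fh,
            indent=1,
        )


def load_model(path) -> RiskModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return RiskModel(d["kind"], np.asarray(d["weights"], float), float(d["intercept"]),
                     d.get("metadata", {}))
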