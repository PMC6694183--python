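"""Two-class linear discriminant analysis on selected gene sets.

Equal-covariance Gaussian LDA: the discriminant direction is
``w ∝ S⁻¹(μ_high − μ_low)`` with S the pooled within-class covariance,
normalized so that ``w' S w = 1`` (unit norm under the pooled-covariance
metric). When S is singular or ill-conditioned — common here, where the
number of selected genes can approach the number of animals — a diagonal
shrinkage ``S ← (1−γ)S + γ diag(S)`` is applied with the smallest γ from
a fixed grid that makes S well conditioned; the intensity is logged.

Accuracies are reported two ways: resubstitution (training data through
its own model — the figure comparable to published density-plot
accuracies) and leave-one-out (refit per fold), which is the honest
out-of-sample estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SHRINKAGE_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.5, 0.9)
_COND_MAX = 1e8


@dataclass
class LDAModel:
    columns: list[str]
    classes: tuple[str, str]  # (negative, positive) = (low, high)
    means: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    shrinkage: float
    priors: dict[str, float]
    direction: np.ndarray  # LD1, w'Sw = 1
    threshold: float


@dataclass
class ClassificationReport:
    scores: pd.DataFrame  # animal, ld1, true, predicted
    resubstitution_accuracy: float  # percent
    loo_accuracy: float | None  # percent; None when not computed
    confusion: pd.DataFrame


def _shrink(S: np.ndarray) -> tuple[np.ndarray, float]:
    diag = np.diag(np.diag(S))
    for gamma in _SHRINKAGE_GRID:
        Sg = (1 - gamma) * S + gamma * diag
        ev = np.linalg.eigvalsh(Sg)
        if ev.min() > 0 and ev.max() / ev.min() < _COND_MAX:
            if gamma > 0:
                logger.info("LDA pooled covariance shrunk with intensity %.2f", gamma)
            return Sg, gamma
    # last resort: heavy ridge toward the diagonal
    Sg = 0.1 * S + 0.9 * diag + 1e-12 * np.eye(len(S))
    return Sg, 0.9


def fit_lda(X, labels, columns: list[str] | None = None,
            priors: dict[str, float] | None = None) -> LDAModel:
    """Fit two-class LDA with pooled within-class covariance."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    neg, pos = classes[0], classes[1]
    if "low" in classes and "high" in classes:
        neg, pos = "low", "high"
    n, k = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(k)]
    if k >= n:
        logger.debug("LDA with %d features >= %d animals; expect shrinkage", k, n)
    means, scatter, counts = {}, np.zeros((k, k)), {}
    for c in (neg, pos):
        Xi = X[labels == c]
        if len(Xi) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        means[c] = Xi.mean(axis=0)
        scatter += (Xi - means[c]).T @ (Xi - means[c])
        counts[c] = len(Xi)
    S = scatter / (n - 2)
    S, gamma = _shrink(S)
    if priors is None:
        priors = {c: counts[c] / n for c in (neg, pos)}
    v = np.linalg.solve(S, means[pos] - means[neg])
    norm = np.sqrt(v @ S @ v)
    w = v / norm
    # decision: w'x > threshold -> positive class
    threshold = float(0.5 * w @ (means[pos] + means[neg])
                      - np.log(priors[pos] / priors[neg]) / (w @ (means[pos] - means[neg])))
    return LDAModel(columns=list(columns), classes=(neg, pos), means=means,
                    pooled_cov=S, shrinkage=gamma, priors=priors,
                    direction=w, threshold=threshold)


def classify(model: LDAModel, X, labels=None, animal_ids=None,
             loo: bool = True) -> ClassificationReport:
    """Score and classify animals; report resubstitution and LOO accuracy.

    LOO accuracy (refit per held-out animal) is computed only when the
    provided ``X``/``labels`` are the training data.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.columns):
        raise ValueError(f"feature mismatch: model has {len(model.columns)} columns, "
                         f"X has {X.shape[1]}")
    neg, pos = model.classes
    ld1 = X @ model.direction
    pred = np.where(ld1 > model.threshold, pos, neg)
    n = len(X)
    if animal_ids is None:
        animal_ids = [f"a{i}" for i in range(n)]
    scores = pd.DataFrame({"animal_id": animal_ids, "ld1": ld1, "predicted": pred})
    resub = np.nan
    loo_acc = None
    confusion = pd.DataFrame()
    if labels is not None:
        labels = np.asarray(labels)
        scores["true"] = labels
        resub = 100.0 * (pred == labels).mean()
        confusion = pd.crosstab(pd.Series(labels, name="true"),
                                pd.Series(pred, name="predicted"))
        if loo:
            hits = 0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                try:
                    m = fit_lda(X[mask], labels[mask], columns=model.columns)
                except ValueError:
                    continue
                p_i = pos if X[i] @ m.direction > m.threshold else neg
                # fold model may order classes identically by construction
                hits += int(p_i == labels[i])
            loo_acc = 100.0 * hits / n
    return ClassificationReport(scores=scores,
                                resubstitution_accuracy=float(resub),
                                loo_accuracy=loo_acc, confusion=confusion)
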