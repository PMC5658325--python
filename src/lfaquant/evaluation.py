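"""Diagnostic-performance statistics for the assay against a reference method.

Subjects carry a reference concentration (e.g. LC/MS-MS) and an assay
readout; dichotomizing the reference at a clinical cutoff (50 or 30 nmol/L)
turns quantification into a binary classification problem whose
discrimination is summarized by the ROC curve and its area.

The AUC is estimated nonparametrically as the Mann-Whitney two-sample
statistic with ties counted half,

    AUC = (1 / (m * n)) * sum_i sum_j [ 1{x_i > y_j} + 0.5 * 1{x_i = y_j} ],

over the m positive-class and n negative-class scores.  Its variance comes
from DeLong's structural-components estimator: with
V10_i = mean_j psi(x_i, y_j) and V01_j = mean_i psi(x_i, y_j),

    var(AUC) = S10 / m + S01 / n,

where S10, S01 are the sample variances of the components.  A stratified
bootstrap is provided alongside, since resampling is the other common way
to attach an interval to the AUC; both are labeled in reports.

Score orientation: by convention here, a larger score indicates the
positive (below-cutoff, deficient) class — e.g. the raw T/C ratio, or the
negated predicted concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import InputError, UndefinedROCError

__all__ = [
    "RocResult",
    "AccuracyResult",
    "roc_curve",
    "auc_delong",
    "auc_bootstrap",
    "diagnostic_accuracy",
    "rmse",
    "binormal_scores",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RocResult:
    """ROC summary: AUC with variance/CI and the empirical curve vertices."""

    auc: float
    variance: float | None
    ci_95: tuple[float, float] | None
    n_pos: int
    n_neg: int
    curve: np.ndarray | None = None  # rows of (FPR, TPR), tie-grouped
    method: str = "delong"
    bootstrap_iterations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class AccuracyResult:
    """Diagnostic accuracy: correctly classified subjects over all subjects."""

    n_correct: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_correct / self.n_total

    @property
    def exact(self) -> Fraction:
        return Fraction(self.n_correct, self.n_total)

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InputError("scores and labels must be 1-D arrays of equal length")
    if len(scores) == 0:
        raise InputError("empty cohort")
    if labels.all() or not labels.any():
        raise UndefinedROCError("ROC requires both a positive and a negative class")
    return scores, labels


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Empirical ROC by sweeping every distinct score threshold.

    Ties are grouped (one vertex per distinct score), so tied blocks appear
    as diagonal segments and the trapezoidal area equals the tie-corrected
    Mann-Whitney AUC.  The curve runs from (0, 0) to (1, 1); larger scores
    indicate the positive class.
    """
    scores, labels = _validate(scores, labels)
    m = int(labels.sum())
    n = len(labels) - m
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # group ties: keep the last index of each distinct-score block
    block_end = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([block_end, [len(s_sorted) - 1]])
    tp = np.cumsum(l_sorted)[idx]
    fp = np.cumsum(~l_sorted)[idx]
    tpr = np.concatenate([[0.0], tp / m])
    fpr = np.concatenate([[0.0], fp / n])
    curve = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, variance=None, ci_95=None, n_pos=m, n_neg=n,
                     curve=curve, method="empirical")


def _mw_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values V10 (per positive) and V01 (per negative)."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def auc_delong(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """AUC with DeLong variance and normal-approximation 95% CI.

    The point estimate is the tie-corrected Mann-Whitney statistic; the
    variance uses the structural components (sample variances of the
    per-subject placement values).  The CI is truncated to [0, 1].  With
    fewer than two subjects in either class the variance is undefined and
    reported as None.
    """
    scores, labels = _validate(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    v10, v01 = _mw_components(pos, neg)
    auc = float(v10.mean())
    variance = ci = None
    if len(pos) >= 2 and len(neg) >= 2:
        variance = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
        half = Z_95 * np.sqrt(variance)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    curve = roc_curve(scores, labels).curve
    return RocResult(auc=auc, variance=variance, ci_95=ci, n_pos=len(pos),
                     n_neg=len(neg), curve=curve, method="delong")


def _batch_auc(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Tie-corrected AUC for each row of stacked (B, m) pos and (B, n) neg."""
    m, n = pos.shape[1], neg.shape[1]
    combined = np.concatenate([pos, neg], axis=1)
    ranks = rankdata(combined, axis=1)  # average ranks handle ties
    r_pos = ranks[:, :m].sum(axis=1)
    return (r_pos - m * (m + 1) / 2) / (m * n)


def auc_bootstrap(
    scores: Sequence[float],
    labels: Sequence[bool],
    iterations: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Stratified-bootstrap AUC: mean over resamples and percentile 95% CI.

    Subjects are resampled with replacement within each class, preserving
    the class sizes.  Reproducible under a fixed seed.
    """
    scores, labels = _validate(scores, labels)
    if iterations < 1:
        raise InputError("iterations must be >= 1")
    pos, neg = scores[labels], scores[~labels]
    rng = np.random.default_rng(seed)
    aucs = np.empty(iterations)
    chunk = 50_000
    for start in range(0, iterations, chunk):
        b = min(chunk, iterations - start)
        p = rng.choice(pos, size=(b, len(pos)), replace=True)
        q = rng.choice(neg, size=(b, len(neg)), replace=True)
        aucs[start : start + b] = _batch_auc(p, q)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(
        auc=float(aucs.mean()),
        variance=float(aucs.var(ddof=1)) if iterations > 1 else None,
        ci_95=(float(lo), float(hi)),
        n_pos=len(pos),
        n_neg=len(neg),
        curve=None,
        method="bootstrap",
        bootstrap_iterations=iterations,
        seed=seed,
    )


def diagnostic_accuracy(reference_labels: Sequence, predicted_labels: Sequence) -> AccuracyResult:
    """Proportion of correctly classified subjects among all subjects."""
    ref = list(reference_labels)
    pred = list(predicted_labels)
    if len(ref) != len(pred):
        raise InputError("label lists must have equal length")
    if not ref:
        raise InputError("empty label lists")
    correct = sum(r == p for r, p in zip(ref, pred))
    return AccuracyResult(n_correct=correct, n_total=len(ref))


def rmse(reference_conc: Sequence[float], predicted_conc: Sequence[float]) -> float:
    """Root mean square error, in nmol/L."""
    ref = np.asarray(reference_conc, dtype=float)
    pred = np.asarray(predicted_conc, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise InputError("concentration vectors must be 1-D and equal length")
    if len(ref) == 0:
        raise InputError("empty concentration vectors")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def binormal_scores(
    auc: float, n_pos: int, n_neg: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic scores with a known generative AUC (equal-variance binormal).

    Under the binormal model with unit variances, AUC = Phi(dmu / sqrt(2)),
    so positives are drawn from N(sqrt(2) * Phi^-1(auc), 1) and negatives
    from N(0, 1).  Returns ``(scores, labels)`` for ROC validation studies.
    """
    if not (0 < auc < 1):
        raise InputError("generative AUC must lie in (0, 1)")
    dmu = np.sqrt(2.0) * norm.ppf(auc)
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(dmu, 1.0, n_pos), rng.normal(0.0, 1.0, n_neg)])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return scores, labels
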