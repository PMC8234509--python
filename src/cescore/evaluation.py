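"""Agreement and diagnostic-performance statistics.

Implements the evaluation machinery for frame-level score agreement and
case-level adequacy classification:

* Top-1 accuracy and Cohen's kappa ``K = (Po - Pe) / (1 - Pe)`` from a
  5x5 confusion matrix (rows: reference/clinician score, columns:
  predicted/algorithm score), with the misclassification mass split into
  under-estimation (predicted < reference) and over-estimation.
* Mean score of a per-score count distribution.
* One-way group comparison (means, SDs, 95 % CIs, F test) of case-level
  scores across clinical grades.
* An empirical ROC over final cleansing scores for the adequate /
  inadequate decision, trapezoidal AUC, and a Youden-index cut-off
  reported as the midpoint between the two adjacent distinct scores
  straddling the optimal threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "AgreementResult",
    "GroupStats",
    "GroupComparison",
    "RocResult",
    "mean_score_from_distribution",
    "top1_accuracy",
    "cohen_kappa",
    "compare_groups",
    "roc_analysis",
    "format_p",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 score confusion counts; rows = reference, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (5, 5):
            raise ValueError(f"confusion matrix must be 5x5, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("confusion matrix must contain at least one pair")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_pairs(
        cls, reference: Sequence[int], predicted: Sequence[int]
    ) -> "ConfusionMatrix":
        ref = np.asarray(reference, dtype=int)
        pred = np.asarray(predicted, dtype=int)
        if ref.shape != pred.shape:
            raise ValueError("reference and predicted must have equal length")
        if np.any((ref < 1) | (ref > 5) | (pred < 1) | (pred > 5)):
            raise ValueError("scores must lie in 1..5")
        counts = np.zeros((5, 5), dtype=np.int64)
        np.add.at(counts, (ref - 1, pred - 1), 1)
        return cls(counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AgreementResult:
    """Frame-level agreement summary between algorithm and reference."""

    top1: float
    kappa: float
    po: float
    pe: float
    misclassification: float
    underestimation: float
    overestimation: float


def mean_score_from_distribution(counts: Sequence[int]) -> float:
    """Mean score of a per-score count vector (scores 1..5)."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (5,):
        raise ValueError("expected 5 per-score counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("counts must not all be zero")
    return float((np.arange(1, 6) * c).sum() / total)


def top1_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of concordant pairs: trace / total."""
    return float(np.trace(cm.counts) / cm.total)


def cohen_kappa(cm: ConfusionMatrix) -> AgreementResult:
    """Chance-corrected agreement K = (Po - Pe) / (1 - Pe).

    Po is the observed agreement (trace / total); Pe sums, per score,
    the product of the row and column marginal proportions.  The
    under-estimation rate is the probability mass strictly below the
    diagonal (predicted < reference); over-estimation is the mass above.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    po = np.trace(c) / total
    row = c.sum(axis=1) / total
    col = c.sum(axis=0) / total
    pe = float((row * col).sum())
    if abs(1.0 - pe) < 1e-12:
        raise ZeroDivisionError(
            "kappa undefined: chance agreement Pe = 1 (degenerate marginals)"
        )
    kappa = (po - pe) / (1.0 - pe)
    under = float(np.tril(c, k=-1).sum() / total)
    over = float(np.triu(c, k=1).sum() / total)
    return AgreementResult(
        top1=float(po),
        kappa=float(kappa),
        po=float(po),
        pe=pe,
        misclassification=float(1.0 - po),
        underestimation=under,
        overestimation=over,
    )


@dataclass(frozen=True)
class GroupStats:
    """Per-group descriptive statistics of case-level scores."""

    n: int
    mean: float
    sd: float | None
    ci95: tuple[float, float] | None


@dataclass(frozen=True)
class GroupComparison:
    groups: Mapping[str, GroupStats]
    f_statistic: float
    p_value: float


def compare_groups(scores_by_grade: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Group means/SDs/95% CIs and a one-way F test across grades.

    Groups with fewer than two cases report an undefined SD/CI (None).
    """
    nonempty = {k: np.asarray(v, dtype=float) for k, v in scores_by_grade.items() if len(v) > 0}
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    stats_by_group: dict[str, GroupStats] = {}
    for name, vals in nonempty.items():
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
            ci = (mean - half, mean + half)
        else:
            sd = None
            ci = None
        stats_by_group[name] = GroupStats(n=n, mean=mean, sd=sd, ci95=ci)
    f_stat, p = stats.f_oneway(*nonempty.values())
    if not np.isfinite(f_stat):  # identical constant groups
        f_stat, p = 0.0, 1.0
    return GroupComparison(
        groups=stats_by_group, f_statistic=float(f_stat), p_value=float(p)
    )


def format_p(p: float) -> str:
    """p to 3 decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC of the final cleansing score for adequacy."""

    thresholds: np.ndarray  # descending candidate thresholds
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float


def roc_analysis(
    case_scores: Sequence[tuple[float, bool]] | None = None,
    *,
    scores: Sequence[float] | None = None,
    adequate: Sequence[bool] | None = None,
) -> RocResult:
    """ROC over final cleansing scores for the adequate/inadequate call.

    The decision rule is ``adequate when final_score >= threshold``;
    every distinct observed score is a candidate threshold.  The AUC is
    computed by the trapezoidal rule (equal to the Mann-Whitney
    concordant-pair statistic).  The operating cut-off maximises
    Youden's J = sensitivity + specificity - 1 (ties broken toward the
    lower threshold) and is reported as the midpoint between the chosen
    threshold and the next lower distinct score.
    """
    if case_scores is not None:
        scores = [s for s, _ in case_scores]
        adequate = [a for _, a in case_scores]
    s = np.asarray(scores, dtype=float)
    y = np.asarray(adequate, dtype=bool)
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and labels must be non-empty and equal length")
    if y.all() or not y.any():
        raise ValueError("both adequate and inadequate cases are required")

    thresholds = np.unique(s)[::-1]  # descending
    pos = s[y]
    neg = s[~y]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    # ROC polyline from (0,0) through the threshold operating points
    fpr = np.concatenate([[0.0], 1.0 - spec])
    tpr = np.concatenate([[0.0], sens])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    j = sens + spec - 1.0
    best_j = j.max()
    # candidates in descending threshold order; lowest threshold wins ties
    best_idx = max(np.flatnonzero(np.isclose(j, best_j, atol=1e-12)))
    t_star = thresholds[best_idx]
    lower = thresholds[thresholds < t_star]
    cutoff = float((t_star + lower.max()) / 2.0) if lower.size else float(t_star)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=cutoff,
        cutoff_sensitivity=float(sens[best_idx]),
        cutoff_specificity=float(spec[best_idx]),
    )
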