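"""Diagnostic-accuracy statistics for continuous and ordinal scores.

Implements the evaluation toolbox of a diagnostic accuracy study:
empirical ROC curves with trapezoidal AUC, DeLong (and bootstrap) 95%
confidence intervals, Youden-index cutoff selection, confusion matrices
with sensitivity/specificity, Mann–Whitney U and Fisher's exact group
comparisons, and the one-way random-effects intraclass correlation
ICC(1) for interrater reliability.

Positivity convention throughout: a score is test-positive when it is
**greater than or equal to** the cutoff.

The AUC is computed twice on every call — by trapezoidal integration of
the empirical ROC and by the Mann–Whitney pair statistic (ties counted
half) — and the two are asserted to agree to 1e-12.  This redundancy is
deliberate: the equality is an exact theorem for the empirical ROC, so
any disagreement flags an implementation defect immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateRocError,
    UndefinedIccError,
    UndefinedMetricError,
    UndefinedVarianceError,
)

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "IccResult",
    "empirical_roc",
    "auc_ci95",
    "bootstrap_auc_ci95",
    "youden_cutoff",
    "confusion_at_cutoff",
    "sensitivity_pct",
    "specificity_pct",
    "round_half_up_pct",
    "mann_whitney_u",
    "fisher_exact",
    "icc_oneway",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at a fixed cutoff (positivity: score >= cutoff)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: thresholds with (sensitivity, specificity) pairs.

    ``thresholds`` ascend and end with an ``inf`` sentinel (nothing is
    test-positive above the maximal observed score); sensitivity is
    non-increasing and specificity non-decreasing along them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    youden_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class IccResult:
    """One-way random-effects ICC(1) with its qualitative band."""

    value: float
    band: str
    ms_between: float
    ms_within: float


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or (~y).all():
        raise DegenerateRocError("both classes must be present")
    return s, y


def _auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    # rank formulation of the Mann-Whitney pair statistic, ties half
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def empirical_roc(scores, labels, ci_method: str = "delong", seed: int | None = None) -> RocCurve:
    """Empirical ROC curve over all observed score values.

    Thresholds are the unique observed scores plus an infinite sentinel.
    The AUC is the trapezoidal area under the (FPR, TPR) polygon,
    cross-checked against the pair-counting statistic; the 95% CI uses
    DeLong's variance estimate by default (``ci_method="bootstrap"``
    for a stratified percentile bootstrap, seedable).
    """
    s, y = _validate_scores_labels(scores, labels)
    pos, neg = s[y], s[~y]
    thresholds = np.concatenate([np.unique(s), [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    # ROC path follows descending thresholds: (0,0) at the sentinel up to
    # (1,1) at the minimal score; score ties yield diagonal segments.
    fpr = 1.0 - spec
    auc_trap = float(np.trapezoid(sens[::-1], fpr[::-1]))
    auc_pairs = _auc_pair_counting(pos, neg)
    assert abs(auc_trap - auc_pairs) <= 1e-12, (
        f"trapezoidal AUC {auc_trap!r} != pair-counting AUC {auc_pairs!r}"
    )

    if ci_method == "delong":
        try:
            ci = auc_ci95(s, y)
        except UndefinedVarianceError:
            ci = (0.0, 1.0)  # uninformative: a class has a single subject
    elif ci_method == "bootstrap":
        ci = bootstrap_auc_ci95(s, y, seed=seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    j = sens + spec - 1.0
    best = _youden_index(thresholds, j)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_trap,
        auc_ci95=ci,
        youden_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def _delong_placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    neg_sorted = np.sort(neg)
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / len(neg)
    pos_sorted = np.sort(pos)
    gt = len(pos) - np.searchsorted(pos_sorted, neg, side="right")
    ge = len(pos) - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (gt + 0.5 * (ge - gt)) / len(pos)
    return v10, v01


def auc_ci95(scores, labels) -> tuple[float, float]:
    """DeLong 95% confidence interval for the AUC, clipped to [0, 1]."""
    s, y = _validate_scores_labels(scores, labels)
    pos, neg = s[y], s[~y]
    if len(pos) < 2 or len(neg) < 2:
        raise UndefinedVarianceError(
            "DeLong variance needs at least two subjects in each class"
        )
    v10, v01 = _delong_placements(pos, neg)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    half = stats.norm.ppf(0.975) * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def bootstrap_auc_ci95(scores, labels, n_boot: int = 2000, seed: int | None = None) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI for the AUC."""
    s, y = _validate_scores_labels(scores, labels)
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        aucs[b] = _auc_pair_counting(bp, bn)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return (float(lo), float(hi))


def _youden_index(thresholds: np.ndarray, j: np.ndarray) -> int:
    # J values that tie mathematically can differ in the last ulp when
    # computed from different count ratios; treat near-ties as exact.
    return int(np.flatnonzero(j >= j.max() - 1e-12)[0])


def youden_cutoff(roc: RocCurve) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest threshold, which maximizes
    sensitivity among J-optimal cutoffs (the screening-oriented rule).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = _youden_index(roc.thresholds, j)
    return float(roc.thresholds[best]), float(j[best])


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionMatrix:
    """Confusion matrix at a fixed cutoff (positive iff score >= cutoff)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff!r}")
    pred = s >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def sensitivity_pct(cm: ConfusionMatrix) -> float:
    """Sensitivity in percent, full precision (100·TP/(TP+FN))."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity_pct(cm: ConfusionMatrix) -> float:
    """Specificity in percent, full precision (100·TN/(TN+FP))."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def round_half_up_pct(value: float) -> int:
    """Reporting variant: round a percentage half-up to an integer."""
    return int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample *a*, p).

    Uses exact enumeration when the pooled sample has at most 12
    observations and no ties, and otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= 12 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table.

    Probability-mass definition: sum of hypergeometric probabilities of
    all tables (with the observed margins) no more likely than the
    observed one.  A zero margin makes every permissible table
    identical, so p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


_ICC_BANDS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"))


def icc_band(value: float) -> str:
    """Qualitative reliability band: <0.4 poor, then fair/good/excellent."""
    for cut, name in _ICC_BANDS:
        if value >= cut:
            return name
    return "poor"


def icc_oneway(ratings) -> IccResult:
    """One-way random-effects intraclass correlation ICC(1).

    ``ratings`` is a subjects × raters grid with no missing cells.
    From the one-way ANOVA decomposition over subjects,
    ``ICC(1) = (MSB - MSW) / (MSB + (k - 1) · MSW)`` with k raters.
    Raises when the ratings carry no variance at all (ICC undefined).
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters grid, at least 2x2")
    if not np.all(np.isfinite(r)):
        raise ValueError("ratings must not contain missing cells")
    n, k = r.shape
    grand = r.mean()
    subject_means = r.mean(axis=1)
    ss_between = k * np.sum((subject_means - grand) ** 2)
    ss_within = np.sum((r - subject_means[:, None]) ** 2)
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    if ms_between == 0.0 and ms_within == 0.0:
        raise UndefinedIccError("ratings have zero total variance")
    value = float((ms_between - ms_within) / (ms_between + (k - 1) * ms_within))
    return IccResult(
        value=value,
        band=icc_band(value),
        ms_between=float(ms_between),
        ms_within=float(ms_within),
    )
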