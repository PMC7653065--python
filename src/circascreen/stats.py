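"""Group-comparison statistics and ROC machinery.

Thin, explicit wrappers over scipy / statsmodels / scikit-learn with the
conventions used throughout the screen: pooled-variance two-tailed t-tests
(from raw vectors or printed summary statistics), the standard two-sided
Fisher exact test, Benjamini-Hochberg step-up adjustment, Pearson r with a
Fisher-z interval, and ROC/AUC with a Youden-index optimal cutoff and an
explicit direction tag (a short phase-to-wake interval indicates the
positive class, so that score is "low-positive").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PearsonResult",
    "RocResult",
    "pooled_t_test",
    "fisher_exact_2x2",
    "bh_adjust",
    "pearson_r",
    "roc_auc",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample mean, SD (n−1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_values(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def pooled_t_test(
    g1: GroupSummary | Sequence[float], g2: GroupSummary | Sequence[float]
) -> TTestResult:
    """Unpaired two-tailed Student's t-test with pooled variance.

    Accepts either raw value vectors or (mean, SD, n) summaries, so printed
    group statistics can be re-tested directly. df = n1 + n2 − 2. Zero
    pooled variance with unequal means is reported as p = 0 with a
    degenerate flag.
    """
    if not isinstance(g1, GroupSummary):
        g1 = GroupSummary.from_values(g1)
    if not isinstance(g2, GroupSummary):
        g2 = GroupSummary.from_values(g2)
    df = g1.n + g2.n - 2
    if g1.sd == 0.0 and g2.sd == 0.0:
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(t=float("inf") if g1.mean > g2.mean else float("-inf"),
                           df=df, p=0.0, degenerate=True)
    t, p = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return TTestResult(t=float(t), df=df, p=float(p))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Standard two-sided Fisher exact p for a 2×2 count table.

    Two-sidedness by the point-probability rule: the sum of hypergeometric
    outcome probabilities no larger than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci95: tuple[float, float]
    p: float
    n: int

    @property
    def moderate_positive(self) -> bool:
        """Mirrors the reporting convention of calling r > 0.3 'moderate'."""
        return self.r > 0.3


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation with two-sided p and 95% Fisher-z interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    lo, hi = res.confidence_interval(0.95)
    return PearsonResult(r=float(res.statistic), ci95=(float(lo), float(hi)),
                         p=float(res.pvalue), n=int(x.size))


@dataclass(frozen=True)
class RocResult:
    """ROC curve, AUC and Youden-optimal cutoff on the original score scale."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    optimal_cutoff: float
    direction: str


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], direction: str = "high"
) -> RocResult:
    """ROC analysis with an explicit positivity direction.

    direction="high": larger scores indicate the positive class (e.g. the
    work/free wake-time gap GUf − GUw); direction="low": smaller scores do
    (e.g. GUw − P3PT). AUC equals the pairwise concordance probability with
    half credit for ties; the optimal cutoff maximizes Youden's
    J = sensitivity + specificity − 1 (ties resolve to the first, most
    conservative threshold scikit-learn emits).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if direction not in ("high", "low"):
        raise ValueError(f"unknown direction {direction!r}")
    s = scores if direction == "high" else -scores
    fpr, tpr, thr = roc_curve(labels, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    k = int(np.argmax(j))
    cutoff = float(thr[k]) if direction == "high" else float(-thr[k])
    return RocResult(
        auc=auc,
        thresholds=thr if direction == "high" else -thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        optimal_cutoff=cutoff,
        direction=direction,
    )
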