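"""Binary classification performance measures and statistical tests.

The association scan scores each SNP task with the Matthews correlation
coefficient (MCC) and the macro F1 score, both robust to class imbalance;
significance of a task is later assessed with a one-sided two-sample t-test
comparing repeated real-label retrains against permuted-label retrains.
This module also carries the closed-form Gaussian Kullback-Leibler
divergence and Spearman correlation used by the univariate simulation study.

Conventions for degenerate confusion matrices (any zero marginal sum) are
part of the contract: MCC is defined as 0 and a per-class F1 with undefined
precision or recall is defined as 0, so that a classifier collapsing onto a
single class still yields finite scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of true positives/negatives and false positives/negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricPair:
    """The two scan metrics: MCC in [-1, 1] and macro F1 in [0, 1]."""

    mcc: float
    macro_f1: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample t-test.

    ``degenerate`` marks the convention case where both samples are constant
    with equal means (p fixed at 1.0).
    """

    statistic: float
    p_value: float
    df: float
    sided: str
    degenerate: bool = False


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.int64)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tabulate a binary confusion matrix; class 1 is the positive class."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),
    defined as 0 when any marginal sum is zero.
    """
    if c.total < 1:
        raise ValueError("confusion counts must cover at least one item")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_from_labels(y_true, y_pred) -> float:
    return mcc(confusion_counts(y_true, y_pred))


def _f1(precision_num: float, precision_den: float, recall_num: float, recall_den: float) -> float:
    # Zero precision/recall denominator -> F1 = 0 by convention.
    if precision_den == 0 or recall_den == 0:
        return 0.0
    p = precision_num / precision_den
    r = recall_num / recall_den
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def macro_f1_from_counts(c: ConfusionCounts) -> float:
    """Unweighted mean of the per-class F1 scores for both label designations."""
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    f1_pos = _f1(tp, tp + fp, tp, tp + fn)
    f1_neg = _f1(tn, tn + fn, tn, tn + fp)
    return (f1_pos + f1_neg) / 2.0


def macro_f1(y_true, y_pred) -> float:
    """Macro F1 from binary label vectors (both classes always averaged)."""
    return macro_f1_from_counts(confusion_counts(y_true, y_pred))


def metric_pair(y_true, y_pred) -> MetricPair:
    c = confusion_counts(y_true, y_pred)
    return MetricPair(mcc=mcc(c), macro_f1=macro_f1_from_counts(c))


def gaussian_kld(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """KL divergence KLD(N(mu1, sd1^2) || N(mu2, sd2^2)).

    For unit variances this reduces to the mean-shift form (mu1-mu2)^2 / 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (
        math.log(sd2 / sd1)
        + (sd1**2 + (mu1 - mu2) ** 2) / (2.0 * sd2**2)
        - 0.5
    )


def two_sample_t(
    x,
    y,
    sided: str = "one",
    direction: str = "greater",
    equal_var: bool = False,
) -> TestResult:
    """Two-sample t-test (Welch by default; pooled variance optional).

    One-sided "greater" tests mean(x) > mean(y). When both samples have zero
    variance and equal means the statistic is undefined; by convention the
    result is p = 1.0 with the degenerate flag set.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each sample needs at least 2 observations")

    if xa.var(ddof=1) == 0.0 and ya.var(ddof=1) == 0.0:
        if xa.mean() == ya.mean():
            df = float(xa.size + ya.size - 2)
            return TestResult(0.0, 1.0, df, sided, degenerate=True)
        # Constant but separated samples: infinitely strong evidence one way.
        sign = 1.0 if xa.mean() > ya.mean() else -1.0
        stat = sign * math.inf
        if sided == "two":
            p = np.nextafter(0.0, 1.0)
        else:
            want_pos = direction == "greater"
            p = np.nextafter(0.0, 1.0) if (sign > 0) == want_pos else 1.0
        return TestResult(stat, float(p), float(xa.size + ya.size - 2), sided)

    alternative = "two-sided" if sided == "two" else direction
    res = stats.ttest_ind(xa, ya, equal_var=equal_var, alternative=alternative)
    p = float(min(max(res.pvalue, np.nextafter(0.0, 1.0)), 1.0))
    return TestResult(float(res.statistic), p, float(res.df), sided)


def spearman_corr(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN when either vector is constant (correlation undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return float("nan")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)
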