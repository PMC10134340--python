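"""Diagnostic-test and trial statistics.

Confusion-matrix metrics (accuracy, sensitivity, specificity, PPV, NPV),
ROC AUC, Pearson chi-square tests on 2x2 tables, and pooled-variance
two-sample t tests from summary statistics.  Malignant is the positive
class throughout.

For a binary (single-threshold) classifier the ROC curve has one interior
vertex, so its area reduces to (sensitivity + specificity) / 2; that
identity is what ``diagnostic_metrics`` reports as AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


@dataclass
class ConfusionMatrix:
    """2x2 counts with malignant as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")
        if self.total < 1:
            raise ValueError("total count must be >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(calls, truth) -> ConfusionMatrix:
    """Standard 2x2 counts from binary call/truth lists (1/True = malignant)."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    if calls.size < 1:
        raise ValueError("need at least one case")
    return ConfusionMatrix(
        tp=int(np.sum(calls & truth)),
        fp=int(np.sum(calls & ~truth)),
        tn=int(np.sum(~calls & ~truth)),
        fn=int(np.sum(~calls & truth)),
    )


@dataclass
class DiagnosticMetrics:
    """Proportions in [0, 1]; metrics with a zero denominator are NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Presentation form: percentages to one decimal, AUC to three."""
        out = {
            k: round(100.0 * getattr(self, k), decimals)
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        }
        out["auc"] = round(self.auc, 3)
        return out


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Accuracy, sensitivity, specificity, PPV, NPV and binary AUC.

    All values are unrounded proportions; rounding happens only at
    presentation (:meth:`DiagnosticMetrics.as_percent`).
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return DiagnosticMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        auc=(sens + spec) / 2.0,
    )


def roc_auc(scores, truth) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties ½.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(truth, scores))


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]], 1 df.

    Uncorrected by default: chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    With ``correction`` the Yates continuity correction subtracts N/2 from
    |ad - bc| (clamped at 0).  Returns ``(statistic, p_value)``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    if n < 1:
        raise ValueError("total count must be >= 1")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("chi-square undefined with a zero marginal total")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / np.prod([float(m) for m in margins])
    return float(stat), float(sps.chi2.sf(stat, df=1))


def t_test_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance (classic Student) two-sample t test from summaries.

    Returns ``(t, two-sided p)`` with n1 + n2 - 2 degrees of freedom.  With
    both SDs zero: equal means give (0, 1); different means are degenerate
    and raise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("degenerate: zero variance in both groups, unequal means")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), float(p)
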