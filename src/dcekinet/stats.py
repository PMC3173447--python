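"""Nonparametric statistics: ROC/AUC, DeLong paired comparison, rank tests.

The AUC is computed by Mann-Whitney pair counting (ties worth 1/2), which is
identical to the trapezoidal area under the empirical ROC curve.  Paired
AUCs from two scoring systems on the same subjects are compared with the
DeLong placement-value covariance estimator and a two-sided z test.
Mann-Whitney U and Kruskal-Wallis tests use midranks with tie-corrected
variance (through scipy.stats); the Mann-Whitney test switches to exact
enumeration for small tie-free samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "TestResult",
    "auc_mann_whitney",
    "empirical_roc",
    "delong_paired_test",
    "mann_whitney_u",
    "kruskal_wallis",
]


@dataclass
class RocResult:
    """Empirical ROC curve with the machinery needed for AUC covariance."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    placements_pos: np.ndarray  # V10_i: fraction of negatives each positive beats
    placements_neg: np.ndarray  # V01_j: fraction of positives beating each negative


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    tie_corrected: bool = False
    degenerate: bool = False


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: pairwise win fractions with ties worth 1/2."""
    p = pos[:, None]
    n = neg[None, :]
    wins = (p > n) + 0.5 * (p == n)
    return wins.mean(axis=1), wins.mean(axis=0)


def auc_mann_whitney(scores_pos, scores_neg) -> float:
    """Pair-counting AUC: P(positive score > negative score) + ties/2.

    Orientation is the caller's: positives should score higher when the
    marker works (for response assessment, non-responders are the positives
    and the score is the percent change — a less negative change is more
    non-responder-like).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def empirical_roc(scores, labels, positive_label=1) -> RocResult:
    """Empirical ROC curve with thresholds at the unique score values.

    Trapezoidal area equals the pair-counting AUC exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_mask = labels == positive_label
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(pos_mask, scores, drop_intermediate=False)
    v10, v01 = _placements(scores[pos_mask], scores[~pos_mask])
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
        n_pos=int(pos_mask.sum()),
        n_neg=int((~pos_mask).sum()),
        placements_pos=v10,
        placements_neg=v01,
    )


def delong_paired_test(scores_a, scores_b, labels, positive_label=1) -> TestResult:
    """DeLong test for equality of two correlated (paired) AUCs.

    Both score systems rate the same subjects.  The variance of
    ``auc_a - auc_b`` is estimated from the empirical covariance of the
    placement values within positives and within negatives; the statistic is
    the resulting z score, with a two-sided normal p-value.  A degenerate
    (zero) variance — e.g. identical scores — yields p = 1 with a flag.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired scores and labels must share one length")
    pos_mask = labels == positive_label
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("both classes must be present")

    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((scores_a, scores_b)):
        v10[i], v01[i] = _placements(s[pos_mask], s[~pos_mask])
        aucs[i] = v10[i].mean()

    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return TestResult(statistic=0.0, p_value=1.0, method="delong", degenerate=True)
    z = float((aucs[0] - aucs[1]) / np.sqrt(var))
    return TestResult(statistic=z, p_value=float(2 * sps.norm.sf(abs(z))), method="delong")


def mann_whitney_u(x, y, alternative: str = "two-sided", use_continuity: bool = True) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    Uses exact enumeration when there are no ties and ``len(x)*len(y) <=
    400``, otherwise the normal approximation with midranks, tie-corrected
    variance and (optionally) continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (not has_ties and x.size * y.size <= 400) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=use_continuity)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann-whitney-{method}",
        tie_corrected=has_ties and method == "asymptotic",
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across independent samples.

    Midranks with the tie correction ``1 - sum(t^3 - t)/(N^3 - N)``;
    p-value from the chi-square distribution with ``k - 1`` df.  Requires at
    least two non-empty groups (response grading uses three: complete,
    partial, non-responder).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    combined = np.concatenate(groups)
    has_ties = len(np.unique(combined)) < len(combined)
    res = sps.kruskal(*groups)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kruskal-wallis",
        tie_corrected=has_ties,
    )
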