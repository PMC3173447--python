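"""Treatment-response classification from kinetic-parameter changes.

After neoadjuvant chemotherapy the tumor's K^trans and V_e maps are reduced
to a single summary (the median over fitted voxels), pre/post percent
changes are formed, and patients are classified against pathology-derived
truth (Sataloff grade: A complete, B partial, C+D non-responder) by simple
cutoff rules:

* single-parameter rule: a patient is a **responder** when the change is at
  least as negative as the cutoff (``change <= cutoff``); a change above the
  cutoff flags **non-response**.  The boundary is inclusive toward
  responder — a drop of exactly the cutoff counts as response.
* combined rule: non-response is flagged when *either* K^trans or V_e fails
  to drop below its cutoff (OR rule); both must drop for a responder call.
* WHO size rule: response requires the tumor size to shrink by at least 50%.

Diagnostic performance (sensitivity, specificity, predictive values,
accuracy) is reported as integer percents with exact Clopper-Pearson 95%
binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.base import BaseEstimator, ClassifierMixin

from .tofts import ParamMap

__all__ = [
    "RESPONDER",
    "NON_RESPONDER",
    "PatientRecord",
    "ClassificationResult",
    "CutoffClassifier",
    "CombinedCutoffClassifier",
    "summarize_roi",
    "percent_change",
    "classify_by_cutoff",
    "classify_combined",
    "who_size_classify",
    "diagnostic_performance",
    "round_half_away",
    "clopper_pearson",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class PatientRecord:
    """Per-patient percent changes and response labels.

    Kinetic changes are carried for both AIF routes; ``sataloff`` is the
    pathologic grade (A total/near-total effect … D none), ``clinical`` the
    physician-assessed response (CR/PR/SD).
    """

    patient: int
    ktrans_change_measured: float
    ktrans_change_theoretical: float
    ve_change_measured: float
    ve_change_theoretical: float
    size_change: float
    clinical: str
    sataloff: str

    def __post_init__(self) -> None:
        if self.sataloff not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown Sataloff grade {self.sataloff!r}")
        if self.size_change < -100:
            raise ValueError("size cannot shrink by more than 100%")

    @property
    def is_responder(self) -> bool:
        """Pathologic responder = Sataloff grade A or B."""
        return self.sataloff in ("A", "B")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion, as fractions."""
    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


@dataclass
class ClassificationResult:
    """Confusion counts and the derived diagnostic rates.

    Rates are stored as raw fractions; ``as_percents()`` gives the rounded
    integer presentation.  Confidence intervals are exact Clopper-Pearson.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValueError("both classes must be present in the truth")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def ci_sensitivity(self) -> tuple[float, float]:
        return clopper_pearson(self.tp, self.tp + self.fn)

    @property
    def ci_specificity(self) -> tuple[float, float]:
        return clopper_pearson(self.tn, self.tn + self.fp)

    def as_percents(self) -> dict:
        """Rates and CI bounds as integer percents (half away from zero)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = round_half_away(100 * v) if not math.isnan(v) else None
        for name in ("ci_sensitivity", "ci_specificity"):
            lo, hi = getattr(self, name)
            out[name] = (round_half_away(100 * lo), round_half_away(100 * hi))
        return out


def summarize_roi(param_map: ParamMap) -> tuple[float, float]:
    """Median K^trans and V_e over the fitted voxels of a map."""
    if param_map.n_fitted == 0:
        raise ValueError("no fitted voxels to summarize")
    return (
        float(np.median(param_map.fitted_values("ktrans"))),
        float(np.median(param_map.fitted_values("ve"))),
    )


def percent_change(pre: float, post: float) -> float:
    """Percent change 100*(post - pre)/pre; ``pre`` must be positive."""
    if pre <= 0:
        raise ValueError("pre-treatment value must be positive")
    return 100.0 * (post - pre) / pre


class CutoffClassifier(ClassifierMixin, BaseEstimator):
    """Single-parameter cutoff rule as a scikit-learn classifier.

    ``predict(X)`` labels each percent change: ``change <= cutoff`` is a
    responder, a strictly larger change a non-responder (boundary inclusive
    toward responder).
    """

    def __init__(self, cutoff: float = -72.0):
        self.cutoff = cutoff

    def fit(self, X=None, y=None):
        self.classes_ = np.array([NON_RESPONDER, RESPONDER])
        return self

    def predict(self, X) -> np.ndarray:
        change = np.asarray(X, dtype=float).reshape(-1)
        return np.where(change <= self.cutoff, RESPONDER, NON_RESPONDER)


class CombinedCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Joint K^trans / V_e cutoff rule (OR on non-response).

    ``X`` has two columns (ktrans change, ve change); a patient is flagged
    non-responder when either parameter fails to drop to its cutoff.
    """

    def __init__(self, ktrans_cutoff: float = -82.0, ve_cutoff: float = -72.0):
        self.ktrans_cutoff = ktrans_cutoff
        self.ve_cutoff = ve_cutoff

    def fit(self, X=None, y=None):
        self.classes_ = np.array([NON_RESPONDER, RESPONDER])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        non_resp = (X[:, 0] > self.ktrans_cutoff) | (X[:, 1] > self.ve_cutoff)
        return np.where(non_resp, NON_RESPONDER, RESPONDER)


def classify_by_cutoff(change, cutoff: float):
    """Label percent change(s) by the single-parameter cutoff rule."""
    labels = CutoffClassifier(cutoff=cutoff).fit().predict(np.atleast_1d(change))
    return labels if np.ndim(change) else str(labels[0])


def classify_combined(ktrans_change, ve_change, ktrans_cutoff: float = -82.0, ve_cutoff: float = -72.0):
    """Label by the joint K^trans/V_e rule (either failing to drop → non-responder)."""
    clf = CombinedCutoffClassifier(ktrans_cutoff, ve_cutoff).fit()
    labels = clf.predict(np.column_stack([np.atleast_1d(ktrans_change), np.atleast_1d(ve_change)]))
    return labels if np.ndim(ktrans_change) else str(labels[0])


def who_size_classify(size_change):
    """WHO criterion: responder iff tumor size decreased by at least 50%."""
    labels = np.where(np.atleast_1d(np.asarray(size_change, dtype=float)) <= -50.0,
                      RESPONDER, NON_RESPONDER)
    return labels if np.ndim(size_change) else str(labels[0])


def diagnostic_performance(predicted, truth, positive_class) -> ClassificationResult:
    """Confusion counts and rates of a predicted labelling against truth.

    ``positive_class`` names the label treated as positive (conventionally
    the non-responder class when screening for treatment failure).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos = truth == positive_class
    if pos.all() or not pos.any():
        raise ValueError("truth must contain both classes")
    pred_pos = predicted == positive_class
    return ClassificationResult(
        tp=int((pred_pos & pos).sum()),
        fp=int((pred_pos & ~pos).sum()),
        tn=int((~pred_pos & ~pos).sum()),
        fn=int((~pred_pos & pos).sum()),
    )
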