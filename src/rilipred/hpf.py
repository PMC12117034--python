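"""The Human Predictive Factor (HPF) and its threshold classifier.

HPF condenses the five lung-densitometry features into one dimensionless
fibrosis-risk score:

    HPF = V ** ((HU_mean + HU_sd) / (HU_mean - HU_sd)) / (HU_max - HU_min)

with V the lung volume in cm^3. For physical lungs (HU_mean < 0 and
0 < HU_sd < |HU_mean|) the exponent lies in (0, 1), so HPF grows with lung
volume and shrinks with the HU range. Low scores indicate denser, more
heterogeneous tissue — i.e. elevated risk of radiation-induced lung injury
(RILI) — so the classifier predicts RILI when the score falls at or below a
cutoff. The cutoff is learned from labelled scores by maximising Youden's J
(sensitivity + specificity - 1) over midpoints of the sorted unique scores.

The power is evaluated in log space (exp(e * ln V - ln(range))) for
numerical stability; this agrees with direct evaluation wherever the latter
is finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import LungFeatureRecord

__all__ = [
    "HpfScore",
    "HpfThreshold",
    "hpf_exponent",
    "compute_hpf",
    "hpf_scores",
    "HPFThresholdClassifier",
    "fit_hpf_threshold",
    "classify_hpf",
]


@dataclass(frozen=True)
class HpfScore:
    """An evaluated HPF with its exponent and denominator."""

    value: float
    exponent: float
    denominator: float


@dataclass(frozen=True)
class HpfThreshold:
    """A fitted cutoff; scores <= cutoff predict RILI (positive class)."""

    cutoff: float
    youden_j: float = float("nan")

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")


def hpf_exponent(hu_mean: float, hu_sd: float) -> float:
    """(HU_mean + HU_sd) / (HU_mean - HU_sd); singular when the two coincide."""
    if hu_sd < 0:
        raise ValueError(f"hu_sd must be >= 0, got {hu_sd}")
    if hu_mean == hu_sd:
        raise ZeroDivisionError(
            f"singular exponent: hu_mean == hu_sd == {hu_mean}"
        )
    return (hu_mean + hu_sd) / (hu_mean - hu_sd)


def compute_hpf(record: LungFeatureRecord) -> HpfScore:
    """Evaluate the HPF for one feature record (log-space power)."""
    if record.volume_cm3 <= 0:
        raise ValueError(f"volume_cm3 must be > 0, got {record.volume_cm3}")
    denominator = record.hu_max - record.hu_min
    if denominator <= 0:
        raise ZeroDivisionError(
            f"hu_max - hu_min must be > 0, got {denominator}"
        )
    exponent = hpf_exponent(record.hu_mean, record.hu_sd)
    value = math.exp(exponent * math.log(record.volume_cm3) - math.log(denominator))
    return HpfScore(value=value, exponent=exponent, denominator=denominator)


def hpf_scores(table: pd.DataFrame) -> np.ndarray:
    """Vectorised HPF over a feature table; returns one score per row."""
    v = table["volume_cm3"].to_numpy(float)
    mean = table["hu_mean"].to_numpy(float)
    sd = table["hu_sd"].to_numpy(float)
    rng_ = table["hu_max"].to_numpy(float) - table["hu_min"].to_numpy(float)
    if np.any(v <= 0):
        raise ValueError("volume_cm3 must be > 0 for all rows")
    if np.any(rng_ <= 0):
        raise ZeroDivisionError("hu_max - hu_min must be > 0 for all rows")
    if np.any(mean == sd):
        raise ZeroDivisionError("singular exponent (hu_mean == hu_sd) in table")
    expo = (mean + sd) / (mean - sd)
    return np.exp(expo * np.log(v) - np.log(rng_))


class HPFThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold classifier on HPF scores.

    Fits the cutoff maximising Youden's J over midpoints of the sorted
    unique training scores. Orientation is fixed by the science (low HPF =>
    damaged tissue): a score <= cutoff is classified as RILI (label 1);
    equality goes to the positive class. Set ``positive_low=False`` to
    invert the convention.

    Attributes
    ----------
    cutoff_ : float
        Selected threshold (largest midpoint among ties).
    youden_j_ : float
        Training-set Youden's J at the cutoff.
    """

    def __init__(self, positive_low: bool = True):
        self.positive_low = positive_low

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 1:
            raise ValueError(
                f"expects a single score column, got {X.shape[1]} features"
            )
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "both classes (0 and 1) must be present to fit a threshold; "
                f"got classes {classes.tolist()}"
            )
        scores = X[:, 0]
        s = scores if self.positive_low else -scores
        pos, neg = s[y == 1], s[y == 0]
        uniq = np.unique(s)
        candidates = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
        best_j, best_c = -np.inf, candidates[0]
        for c in candidates:  # ties resolve to the larger cutoff
            j = (pos <= c).mean() + (neg > c).mean() - 1.0
            if j >= best_j:
                best_j, best_c = j, c
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        self.cutoff_ = float(best_c) if self.positive_low else float(-best_c)
        self.youden_j_ = float(best_j)
        return self

    def decision_function(self, X):
        """Higher values favour the positive (RILI) class; 0 at the cutoff."""
        check_is_fitted(self, "cutoff_")
        X = check_array(X)
        sign = 1.0 if self.positive_low else -1.0
        return sign * (self.cutoff_ - X[:, 0])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def fit_hpf_threshold(scores, labels) -> HpfThreshold:
    """Functional wrapper: Youden-J cutoff for "low HPF => RILI" scoring."""
    scores = np.asarray(scores, dtype=float)
    est = HPFThresholdClassifier().fit(scores.reshape(-1, 1), labels)
    return HpfThreshold(cutoff=est.cutoff_, youden_j=est.youden_j_)


def classify_hpf(score: HpfScore | float, threshold: HpfThreshold) -> int:
    """1 (RILI) iff the score is at or below the cutoff."""
    value = score.value if isinstance(score, HpfScore) else float(score)
    return int(value <= threshold.cutoff)
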