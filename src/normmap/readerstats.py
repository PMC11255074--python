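"""Diagnostic layer: rating-based diagnosis, confusion metrics, agreement.

Readers score mesiotemporal atrophy per hemisphere on a 0-3 Likert scale
(0 none, 1 minimal-moderate, 2 marked, 3 severe); a positive (disease)
diagnosis is triggered when the bihemispheric score reaches a threshold
(default 2). Because "bihemispheric score >= 2" admits several readings,
the combination rule is selectable: ``max`` (either hemisphere, default),
``both`` (both hemispheres), or ``sum`` (left + right).

Accuracy/sensitivity/specificity/PPV/NPV are reported as integer
percentages with half-up rounding, the convention used alongside printed
fractions such as 37/42. Agreement statistics (Cohen's kappa, ICC(2,1),
Cochran's Q, exact pairwise McNemar with Bonferroni) wrap the standard
scikit-learn / pingouin / statsmodels implementations with degenerate-case
handling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import NormMapError

SCORE_LEVELS = (0, 1, 2, 3)
DIAGNOSIS_RULES = ("max", "both", "sum")


@dataclass(frozen=True)
class RatingRecord:
    """One reader's per-hemisphere atrophy scores for one subject/map."""

    subject_id: str
    reader_id: str
    cohort_used: str
    score_right: int
    score_left: int

    def __post_init__(self):
        for name, score in (("right", self.score_right), ("left", self.score_left)):
            if score not in SCORE_LEVELS:
                raise NormMapError(
                    f"{self.subject_id}/{self.reader_id}: {name} score {score} "
                    f"outside {SCORE_LEVELS}"
                )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise NormMapError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def diagnose(rating: RatingRecord, threshold: int = 2, rule: str = "max") -> bool:
    """Positive diagnosis from the two hemisphere scores."""
    if rule not in DIAGNOSIS_RULES:
        raise NormMapError(f"rule must be one of {DIAGNOSIS_RULES}, got {rule!r}")
    left, right = rating.score_left, rating.score_right
    if rule == "max":
        return max(left, right) >= threshold
    if rule == "both":
        return min(left, right) >= threshold
    return left + right >= threshold


def confusion(predictions, truth) -> ConfusionCounts:
    """Tally a binary prediction vector against ground truth."""
    pred = np.asarray(predictions, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise NormMapError(
            f"length mismatch: {pred.shape} predictions vs {true.shape} truth"
        )
    return ConfusionCounts(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        tn=int((~pred & ~true).sum()),
        fn=int((~pred & true).sum()),
    )


def _percent(num: int, den: int):
    """num/den as an integer percentage, half-up; None when undefined."""
    if den == 0:
        return None
    return int(math.floor(100.0 * num / den + 0.5))


def diagnostic_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV as integer percents.

    A metric with a zero denominator is reported as absent (None), never as
    zero.
    """
    if c.total == 0:
        raise NormMapError("cannot compute metrics on an empty confusion table")
    return {
        "accuracy": _percent(c.tp + c.tn, c.total),
        "sensitivity": _percent(c.tp, c.tp + c.fn),
        "specificity": _percent(c.tn, c.tn + c.fp),
        "ppv": _percent(c.tp, c.tp + c.fp),
        "npv": _percent(c.tn, c.tn + c.fn),
    }


def cohens_kappa(labels_a, labels_b):
    """Cohen's kappa between two raters' categorical label vectors.

    Works for the 4-level atrophy score and for binary diagnoses. When
    chance agreement is 1 (a single shared category) kappa is undefined and
    None is returned.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise NormMapError("label vectors must be 1D and aligned")
    if a.size == 0:
        raise NormMapError("empty label vectors")
    if len(set(a.tolist()) | set(b.tolist())) < 2:
        return None  # p_e = 1, kappa undefined
    return float(cohen_kappa_score(a, b))


def icc_two_way(ratings) -> float | None:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a subjects × raters matrix with no missing cells. Other
    variants can be requested via ``icc_variant``.
    """
    return icc_variant(ratings, "ICC2")


def icc_variant(ratings, variant: str = "ICC2") -> float | None:
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise NormMapError("ICC needs a 2D matrix with >= 2 subjects and raters")
    if not np.isfinite(mat).all():
        raise NormMapError("ICC input contains missing/non-finite cells")
    if np.allclose(mat, mat.flat[0]):
        return None  # zero total variance: ICC undefined
    n_subj, n_rat = mat.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_rat),
            "rater": np.tile(np.arange(n_rat), n_subj),
            "score": mat.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # pingouin's confidence-interval arithmetic divides by zero when the
        # residual variance vanishes (perfect agreement); the point estimate
        # is still well-defined
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
    value = float(table.set_index("Type").loc[_PINGOUIN_ICC[variant], "ICC"])
    return value


# pingouin labels: ICC(1,1) one-way random; ICC(A,1) two-way random absolute
# agreement (the classic ICC(2,1)); ICC(C,1) two-way mixed consistency
_PINGOUIN_ICC = {
    "ICC1": "ICC(1,1)",
    "ICC2": "ICC(A,1)",
    "ICC3": "ICC(C,1)",
}


def cochrans_q(binary_matrix):
    """Cochran's Q over a subjects × conditions binary matrix.

    Returns ``(Q, p)`` against a chi-square reference with k-1 degrees of
    freedom. Subjects with all-equal rows carry no information; a matrix
    with no variation at all yields Q = 0, p = 1.
    """
    mat = np.asarray(binary_matrix)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise NormMapError("Cochran's Q needs >= 2 conditions")
    if not np.isin(mat, (0, 1)).all():
        raise NormMapError("Cochran's Q input must be binary")
    row_sums = mat.sum(axis=1)
    informative = (row_sums > 0) & (row_sums < mat.shape[1])
    if not informative.any():
        return 0.0, 1.0
    res = _sm_cochrans_q(mat, return_object=True)
    return float(res.statistic), float(res.pvalue)


def mcnemar_exact(binary_a, binary_b):
    """Exact (binomial) two-sided McNemar test on two paired binary vectors."""
    a = np.asarray(binary_a, dtype=bool)
    b = np.asarray(binary_b, dtype=bool)
    if a.shape != b.shape:
        raise NormMapError("paired vectors must be aligned")
    b01 = int((~a & b).sum())
    b10 = int((a & ~b).sum())
    if b01 + b10 == 0:
        return 1.0
    table = np.array([[int((a & b).sum()), b10], [b01, int((~a & ~b).sum())]])
    return float(_sm_mcnemar(table, exact=True).pvalue)


def mcnemar_pairwise(binary_matrix, correction: str = "bonferroni"):
    """Exact McNemar over every pair of conditions, with Bonferroni control.

    Returns a list of ``(i, j, p_raw, p_adjusted)``; adjusted p-values are
    ``p_raw * n_pairs`` capped at 1 (or equal to raw when correction is
    "none").
    """
    mat = np.asarray(binary_matrix)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise NormMapError("pairwise McNemar needs >= 2 conditions")
    if correction not in ("bonferroni", "none"):
        raise NormMapError(f"unknown correction {correction!r}")
    pairs = list(itertools.combinations(range(mat.shape[1]), 2))
    results = []
    for i, j in pairs:
        p_raw = mcnemar_exact(mat[:, i], mat[:, j])
        p_adj = min(1.0, p_raw * len(pairs)) if correction == "bonferroni" else p_raw
        results.append((i, j, p_raw, p_adj))
    return results


def ratings_to_diagnoses(
    ratings: list[RatingRecord], threshold: int = 2, rule: str = "max"
) -> pd.DataFrame:
    """Long-format diagnoses (one row per rating record)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in ratings],
            "reader_id": [r.reader_id for r in ratings],
            "cohort_used": [r.cohort_used for r in ratings],
            "positive": [diagnose(r, threshold=threshold, rule=rule) for r in ratings],
        }
    )
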