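"""ROC analysis, DeLong correlated-AUC comparison and cutpoint optimization.

All routines operate on one score per participant (a summary scale) plus a
binary case/control label.

* :func:`roc` builds the full ROC curve over candidate thresholds and
  computes the AUC through the Mann-Whitney concordance identity (ties
  count 1/2), so the AUC is invariant under strictly monotone score
  transforms.
* :func:`delong_compare` tests two AUCs measured on the *same* participants
  with the DeLong placement-value variance/covariance estimator.
* :func:`optimal_cutpoint` exhaustively searches thresholds placed at
  midpoints between consecutive distinct scores, either maximizing the
  Youden index J = sensitivity + specificity - 1 or maximizing sensitivity
  subject to a specificity floor.  Among equal optima the threshold with
  higher specificity, then the larger threshold, is returned, so results
  are deterministic.

A classification is "positive" when the score lies strictly beyond the
threshold in the case-indicating direction, matching the scoring module's
tie convention.

:data:`REFERENCE_CUTPOINTS` records the instrument's published preliminary
diagnostic performance table (threshold, sensitivity, specificity, AUC and
Youden index per summary scale and objective) for comparison with newly
computed tables.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InfeasibleConstraintError,
    UndefinedStatisticError,
    ValidationError,
)
from .scoring import Direction

__all__ = [
    "RocCurve",
    "CutpointResult",
    "RocComparison",
    "roc",
    "auc_mann_whitney",
    "delong_compare",
    "optimal_cutpoint",
    "REFERENCE_CUTPOINTS",
]


@dataclasses.dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # ascending, on the original score scale
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: Direction
    auc: float


@dataclasses.dataclass(frozen=True)
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden: float
    objective: str


@dataclasses.dataclass(frozen=True)
class RocComparison:
    auc_a: float
    auc_b: float
    z: float
    p_two_sided: float


def _coerce_labels(labels: Sequence) -> np.ndarray:
    """Return boolean case mask from bools or case/control strings."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        mask = arr
    else:
        vals = set(np.unique(arr).tolist())
        if not vals <= {"case", "control"}:
            raise ValidationError(
                f"labels must be booleans or 'case'/'control', got {sorted(vals)}"
            )
        mask = arr == "case"
    if mask.all() or not mask.any():
        raise DegenerateInputError(
            "both classes must be present for ROC analysis"
        )
    return mask


def _orient(scores: np.ndarray, orientation: Direction) -> np.ndarray:
    if Direction(orientation) is Direction.lower_indicates_case:
        return -scores
    return scores


def auc_mann_whitney(scores: Sequence[float], labels: Sequence,
                     orientation: Direction = Direction.higher_indicates_case,
                     ) -> float:
    """AUC as the Mann-Whitney concordance probability (ties = 1/2)."""
    case = _coerce_labels(labels)
    s = _orient(np.asarray(scores, dtype=float), orientation)
    m, n = int(case.sum()), int((~case).sum())
    ranks = stats.rankdata(s)  # average ranks handle ties
    return float((ranks[case].sum() - m * (m + 1) / 2) / (m * n))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct observed scores."""
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise DegenerateInputError(
            "all scores identical: no candidate thresholds exist"
        )
    return (distinct[:-1] + distinct[1:]) / 2.0


def _confusion(scores: np.ndarray, case: np.ndarray, threshold: float,
               orientation: Direction) -> tuple[float, float]:
    if Direction(orientation) is Direction.higher_indicates_case:
        positive = scores > threshold
    else:
        positive = scores < threshold
    sens = float(positive[case].mean())
    spec = float((~positive)[~case].mean())
    return sens, spec


def roc(scores: Sequence[float], labels: Sequence,
        orientation: Direction = Direction.higher_indicates_case) -> RocCurve:
    """ROC curve over all distinct-score midpoints plus the two trivial
    endpoints (everyone positive / everyone negative)."""
    s = np.asarray(scores, dtype=float)
    case = _coerce_labels(labels)
    mids = _candidate_thresholds(s)
    lo = float(s.min()) - 1.0
    hi = float(s.max()) + 1.0
    thresholds = np.concatenate([[lo], mids, [hi]])
    pairs = [_confusion(s, case, t, orientation) for t in thresholds]
    sens = np.array([p[0] for p in pairs])
    spec = np.array([p[1] for p in pairs])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        orientation=Direction(orientation),
        auc=auc_mann_whitney(s, case, orientation),
    )


def optimal_cutpoint(
    scores: Sequence[float],
    labels: Sequence,
    orientation: Direction = Direction.higher_indicates_case,
    objective: str = "max_youden",
    min_specificity: float | None = None,
) -> CutpointResult:
    """Exhaustive cutpoint search over distinct-score midpoints.

    Parameters
    ----------
    objective
        ``"max_youden"`` maximizes J = sensitivity + specificity - 1;
        ``"max_sens_at_spec"`` maximizes sensitivity among thresholds whose
        specificity is at least ``min_specificity``.
    min_specificity
        Required floor in (0, 1) for the constrained objective.

    Raises
    ------
    InfeasibleConstraintError
        If no candidate threshold attains the specificity floor.
    """
    s = np.asarray(scores, dtype=float)
    case = _coerce_labels(labels)
    candidates = _candidate_thresholds(s)
    rows = []
    for t in candidates:
        sens, spec = _confusion(s, case, t, orientation)
        rows.append((t, sens, spec, sens + spec - 1.0))

    if objective == "max_youden":
        feasible = rows
        key = lambda r: (r[3], r[2], r[0])  # J, then spec, then threshold
        label = "max_youden"
    elif objective == "max_sens_at_spec":
        if min_specificity is None or not 0.0 < min_specificity < 1.0:
            raise ValidationError("min_specificity must lie in (0, 1)")
        feasible = [r for r in rows if r[2] >= min_specificity]
        if not feasible:
            raise InfeasibleConstraintError(
                f"no threshold reaches specificity {min_specificity}"
            )
        key = lambda r: (r[1], r[2], r[0])  # sens, then spec, then threshold
        label = f"max_sens_at_spec({min_specificity:g})"
    else:
        raise ValidationError(f"unknown objective {objective!r}")

    t, sens, spec, j = max(feasible, key=key)
    return CutpointResult(float(t), sens, spec, j, label)


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Case and control placement values (ties count 1/2)."""
    x = scores[case]          # cases, size m
    y = scores[~case]         # controls, size n
    # psi(x_i, y_j) = 1 if x > y, 1/2 if equal, 0 otherwise
    psi = (x[:, None] > y[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)    # per-case
    v01 = psi.mean(axis=0)    # per-control
    return v10, v01


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    orientation_a: Direction = Direction.higher_indicates_case,
    orientation_b: Direction = Direction.higher_indicates_case,
) -> RocComparison:
    """DeLong test of AUC(a) = AUC(b) for scores on the same participants.

    Uses the placement-value estimator of the variance of the AUC
    difference; the statistic z = (AUC_a - AUC_b) / SE is referenced to the
    standard normal, two-sided.
    """
    sa = _orient(np.asarray(scores_a, dtype=float), orientation_a)
    sb = _orient(np.asarray(scores_b, dtype=float), orientation_b)
    if sa.shape != sb.shape:
        raise ValidationError("score vectors must have equal length")
    case = _coerce_labels(labels)
    m, n = int(case.sum()), int((~case).sum())
    if m < 2 or n < 2:
        raise DegenerateInputError("need >= 2 cases and >= 2 controls")

    v10a, v01a = _placements(sa, case)
    v10b, v01b = _placements(sb, case)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if np.allclose(sa, sb):
            return RocComparison(auc_a, auc_b, 0.0, 1.0)
        raise UndefinedStatisticError(
            "DeLong variance of the AUC difference is zero; test undefined"
        )
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RocComparison(auc_a, auc_b, float(z), p)


#: Published preliminary diagnostic-performance table for the instrument's
#: three participant-summary scales.  Integrated-index thresholds are
#: printed on the symptoms-minus-competencies difference scale.  Two rows
#: (marked ``youden_consistent = False``) have a printed Youden index that
#: does not equal sensitivity + specificity - 1 of the same row.
REFERENCE_CUTPOINTS = pd.DataFrame(
    [
        ("symptoms", 2.94, "max_youden", 0.86, 0.90, 0.95, 0.76, True),
        ("competencies", 1.93, "max_youden", 0.88, 0.88, 0.96, 0.76, True),
        ("integrated", 0.59, "max_youden", 0.91, 0.93, 0.97, 0.84, True),
        ("symptoms", 3.31, "max_sens_at_spec(0.95)", 0.82, 0.95, 0.95, 0.79, False),
        ("competencies", 1.46, "max_sens_at_spec(0.95)", 0.75, 0.95, 0.96, 0.70, True),
        ("integrated", 1.80, "max_sens_at_spec(0.95)", 0.83, 0.95, 0.97, 0.79, False),
        ("symptoms", 6.05, "max_sens_at_spec(0.99)", 0.33, 0.99, 0.95, 0.32, True),
        ("competencies", 0.99, "max_sens_at_spec(0.99)", 0.52, 0.99, 0.96, 0.51, True),
        ("integrated", 5.33, "max_sens_at_spec(0.99)", 0.33, 0.99, 0.97, 0.32, True),
    ],
    columns=[
        "scale_kind", "threshold", "objective", "sensitivity", "specificity",
        "auc", "youden", "youden_consistent",
    ],
)
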