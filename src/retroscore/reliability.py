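"""Interrater reliability: quadratic-weighted Cohen's kappa per scale.

Agreement between the two clinician raters is summarized per
(scale, valence) with Cohen's kappa using quadratic (squared-distance)
disagreement weights

    kappa = 1 - (sum_ij w_ij O_ij) / (sum_ij w_ij E_ij),
    w_ij = (i - j)^2,

where ``O`` is the observed joint proportion table and ``E`` the product of
its marginals.  The category grid is fixed by the valence (3 symptom
categories, 2 competency categories) even when a category is unobserved,
because the weights depend on the full grid.  On binary data the quadratic
weighting reduces algebraically to unweighted Cohen's kappa.

Repeated measures of one participant across reports enter as independent
pairs; every available paired rating for an item contributes, and the
number of pairs is reported alongside each estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, UndefinedStatisticError, ValidationError
from .instrument import RECORD_KEY, RatingTable, Valence, scale_ids, score_domain

__all__ = ["KappaResult", "weighted_kappa", "kappa_report"]


@dataclasses.dataclass(frozen=True)
class KappaResult:
    scale_id: str | None
    valence: str | None
    kappa: float
    n_pairs: int
    contingency: np.ndarray

    def __post_init__(self) -> None:
        assert self.n_pairs == int(self.contingency.sum())


def weighted_kappa(
    pairs: Sequence[tuple[int, int]] | np.ndarray,
    n_categories: int,
    scale_id: str | None = None,
    valence: str | None = None,
) -> KappaResult:
    """Quadratic-weighted Cohen's kappa on paired category scores.

    Parameters
    ----------
    pairs
        Sequence of (score_a, score_b) integer pairs in ``0..n_categories-1``.
    n_categories
        Size of the category grid; the contingency table is padded to the
        full grid even if some categories are unobserved.

    Raises
    ------
    UndefinedStatisticError
        If the expected weighted disagreement is zero (each rater used a
        single category), where kappa has a 0/0 form.
    """
    arr = np.asarray(pairs, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("need >= 2 (score_a, score_b) pairs")
    if arr.min() < 0 or arr.max() >= n_categories:
        raise ValidationError(
            f"scores outside 0..{n_categories - 1}: "
            f"range {arr.min()}..{arr.max()}"
        )

    k = n_categories
    contingency = np.zeros((k, k), dtype=int)
    np.add.at(contingency, (arr[:, 0], arr[:, 1]), 1)
    n = arr.shape[0]

    idx = np.arange(k)
    w = (idx[:, None] - idx[None, :]) ** 2
    observed = contingency / n
    marg_a = observed.sum(axis=1)
    marg_b = observed.sum(axis=0)
    expected = np.outer(marg_a, marg_b)

    denom = float((w * expected).sum())
    if denom == 0.0:
        raise UndefinedStatisticError(
            "kappa undefined: expected weighted disagreement is zero "
            "(each rater used only one category)"
        )
    kappa = 1.0 - float((w * observed).sum()) / denom
    return KappaResult(scale_id, valence, kappa, n, contingency)


def _n_categories(valence: str) -> int:
    return len(score_domain(valence))


def kappa_report(
    table_a: RatingTable, table_b: RatingTable
) -> tuple[list[KappaResult], dict[str, float]]:
    """Per-(scale, valence) kappas across two raters, plus per-valence means.

    The tables must align record-for-record on
    (participant, year, term, scale, valence); rater ids may differ.
    Returns the 22 :class:`KappaResult` objects in instrument order and the
    unweighted mean kappa per valence.

    Raises :class:`AlignmentError` listing orphan keys when the tables do
    not pair up exactly.
    """
    join_key = [c for c in RECORD_KEY if c != "rater_id"]
    a = table_a.df[join_key + ["score"]]
    b = table_b.df[join_key + ["score"]]
    merged = a.merge(b, on=join_key, how="outer", suffixes=("_a", "_b"),
                     indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        sample = orphans[join_key].head(5).to_dict("records")
        raise AlignmentError(
            f"{len(orphans)} record(s) present in only one table, e.g. {sample}"
        )

    results: list[KappaResult] = []
    for valence in (Valence.symptom.value, Valence.competency.value):
        for sid in scale_ids():
            sub = merged[(merged["scale_id"] == sid)
                         & (merged["valence"] == valence)]
            pairs = sub[["score_a", "score_b"]].to_numpy(dtype=int)
            results.append(
                weighted_kappa(pairs, _n_categories(valence),
                               scale_id=sid, valence=valence)
            )

    means = {
        valence: float(np.mean([r.kappa for r in results if r.valence == valence]))
        for valence in (Valence.symptom.value, Valence.competency.value)
    }
    return results, means
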