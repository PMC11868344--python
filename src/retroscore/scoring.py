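"""Summary scores, the integrated index, and diagnostic threshold rules.

Scoring proceeds in two aggregation steps:

1. :func:`year_scores` — within each school year, per-scale scores are
   averaged over the 1-2 available report terms, then summed across the 11
   scales separately per valence (``symptom_sum`` in [0, 22],
   ``competency_sum`` in [0, 11]); the mean of the nine inattention
   subcriterion scores is kept as a separate inattention summary.
2. :func:`participant_summaries` — yearly sums are averaged, unweighted,
   over the years a participant was actually rated (no imputation), giving
   ``summary_symptoms`` and ``summary_competencies``; the *integrated index*
   combines them with weight -1 for symptoms and +1 for competencies, so
   cases score low.

Published preliminary cutoffs for the instrument place the case-indicating
region above a mean summed symptoms scale of 2.94, below a mean summed
competencies scale of 1.93, and at a symptoms-minus-competencies difference
above 0.59 (equivalently an integrated index below -0.59).  A value exactly
at a threshold is classified negative.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AmbiguityError, ValidationError
from .instrument import (
    RatingTable,
    Valence,
    inattention_scale_ids,
    scale_ids,
)

log = logging.getLogger(__name__)

__all__ = [
    "ScaleKind",
    "Direction",
    "ThresholdRule",
    "default_rules",
    "select_rater",
    "consensus_scores",
    "filter_medicated",
    "year_scores",
    "inattention_summary",
    "participant_summaries",
    "classify",
    "classify_value",
]


class ScaleKind(str, enum.Enum):
    symptoms = "symptoms"
    competencies = "competencies"
    integrated = "integrated"


class Direction(str, enum.Enum):
    higher_indicates_case = "higher_indicates_case"
    lower_indicates_case = "lower_indicates_case"


_DEFAULT_DIRECTION = {
    ScaleKind.symptoms: Direction.higher_indicates_case,
    ScaleKind.competencies: Direction.lower_indicates_case,
    ScaleKind.integrated: Direction.lower_indicates_case,
}

_SUMMARY_FIELD = {
    ScaleKind.symptoms: "summary_symptoms",
    ScaleKind.competencies: "summary_competencies",
    ScaleKind.integrated: "integrated_index",
}


@dataclasses.dataclass(frozen=True)
class ThresholdRule:
    """A diagnostic cutoff on one participant-summary scale.

    ``direction`` defaults to the scale's conventional orientation: high
    symptom scores indicate a case, low competency scores and a low
    integrated index indicate a case.
    """

    scale_kind: ScaleKind
    threshold: float
    direction: Direction | None = None

    def resolved_direction(self) -> Direction:
        return self.direction or _DEFAULT_DIRECTION[self.scale_kind]


def default_rules() -> tuple[ThresholdRule, ...]:
    """The instrument's published preliminary balanced (max-Youden) cutoffs.

    The integrated-index rule stores -0.59 because the index is coded
    competencies minus symptoms (cases low); it is equivalent to flagging a
    symptoms-minus-competencies difference strictly above 0.59.
    """
    return (
        ThresholdRule(ScaleKind.symptoms, 2.94),
        ThresholdRule(ScaleKind.competencies, 1.93),
        ThresholdRule(ScaleKind.integrated, -0.59),
    )


def _as_frame(table: RatingTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, RatingTable) else table


def select_rater(table: RatingTable, rater_id: str) -> RatingTable:
    """Restrict a table to one rater's records."""
    df = table.df[table.df["rater_id"] == rater_id]
    if df.empty:
        raise ValidationError(f"no records for rater {rater_id!r}")
    return RatingTable(
        df.reset_index(drop=True),
        {**table.provenance, "rater": rater_id},
    )


def consensus_scores(table: RatingTable) -> pd.DataFrame:
    """Average scores across raters, kept fractional (no re-rounding).

    Returns a rating frame with ``rater_id`` = ``"consensus"`` and float
    scores, accepted directly by :func:`year_scores`.
    """
    df = table.df
    keys = ["participant_id", "group", "school_year", "term", "scale_id",
            "valence"]
    out = df.groupby(keys, as_index=False, sort=False).agg(
        score=("score", "mean"), medicated=("medicated", "any")
    )
    out["rater_id"] = "consensus"
    return out


def filter_medicated(table: RatingTable, include: bool = False) -> RatingTable:
    """Drop (``include=False``) or keep only medicated-flagged reports.

    Emits a warning if a whole group loses all of its reports.
    """
    df = table.df
    mask = df["medicated"] if include else ~df["medicated"]
    out = df[mask]
    for group in df["group"].unique():
        if (df["group"] == group).any() and not (out["group"] == group).any():
            log.warning(
                "medication filter removed every report of group %r", group
            )
    return RatingTable(
        out.reset_index(drop=True),
        {**table.provenance, "medication_filter": "include" if include else "exclude"},
    )


def year_scores(table: RatingTable | pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, year) scale scores and summary sums.

    Per-scale scores are the arithmetic mean over the year's available
    report terms (equal weighting of midyear and end-of-year reports).

    Returns a frame with one row per (participant_id, school_year):
    ``sym_<scale>`` / ``comp_<scale>`` per-scale columns, ``symptom_sum``,
    ``competency_sum``, per-valence inattention means, and the per-year
    integrated responses used for longitudinal modelling (``integrated`` =
    competency_sum - symptom_sum, plus family-level integrated scores for
    inattention, hyperactivity and impulsivity).

    Raises :class:`AmbiguityError` if more than one rater is present; select
    a rater or build a consensus first.
    """
    df = _as_frame(table)
    raters = df["rater_id"].unique()
    if len(raters) > 1:
        raise AmbiguityError(
            f"multiple raters present ({sorted(map(str, raters))}); apply "
            "select_rater() or consensus_scores() before scoring"
        )

    per_scale = (
        df.groupby(
            ["participant_id", "group", "school_year", "scale_id", "valence"],
            sort=False,
        )["score"]
        .mean()
        .unstack(["valence", "scale_id"])
    )
    # wide columns in fixed instrument order: sym_A1a ... comp_A2I
    cols = {}
    for sid in scale_ids():
        cols[f"sym_{sid}"] = per_scale[(Valence.symptom.value, sid)]
        cols[f"comp_{sid}"] = per_scale[(Valence.competency.value, sid)]
    wide = pd.DataFrame(cols, index=per_scale.index).reset_index()

    sym_cols = [f"sym_{sid}" for sid in scale_ids()]
    comp_cols = [f"comp_{sid}" for sid in scale_ids()]
    ia_sym = [f"sym_{sid}" for sid in inattention_scale_ids()]
    ia_comp = [f"comp_{sid}" for sid in inattention_scale_ids()]

    wide["symptom_sum"] = wide[sym_cols].sum(axis=1)
    wide["competency_sum"] = wide[comp_cols].sum(axis=1)
    wide["inattention_mean_sym"] = wide[ia_sym].mean(axis=1)
    wide["inattention_mean_comp"] = wide[ia_comp].mean(axis=1)
    wide["integrated"] = wide["competency_sum"] - wide["symptom_sum"]
    wide["inattention_integrated"] = (
        wide["inattention_mean_comp"] - wide["inattention_mean_sym"]
    )
    wide["hyperactivity_integrated"] = wide["comp_A2H"] - wide["sym_A2H"]
    wide["impulsivity_integrated"] = wide["comp_A2I"] - wide["sym_A2I"]
    return (
        wide.sort_values(["participant_id", "school_year"], kind="mergesort")
        .reset_index(drop=True)
    )


def inattention_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, year) mean of the nine inattention subcriterion
    scores, separately per valence."""
    return scores[
        ["participant_id", "group", "school_year",
         "inattention_mean_sym", "inattention_mean_comp"]
    ].copy()


def participant_summaries(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse yearly scores into one summary row per participant.

    ``summary_symptoms`` / ``summary_competencies`` are unweighted means of
    the yearly sums over the years with ratings; ``integrated_index`` applies
    the weights -1 (symptoms) and +1 (competencies).
    """
    out = (
        scores.groupby(["participant_id", "group"], sort=False)
        .agg(
            summary_symptoms=("symptom_sum", "mean"),
            summary_competencies=("competency_sum", "mean"),
            n_years=("school_year", "nunique"),
        )
        .reset_index()
    )
    out["integrated_index"] = out["summary_competencies"] - out["summary_symptoms"]
    return out.sort_values("participant_id", kind="mergesort").reset_index(drop=True)


def classify_value(value: float, rule: ThresholdRule) -> str:
    """Apply a threshold rule to a scalar summary value.

    Positive iff the value lies strictly beyond the threshold in the
    case-indicating direction; a value exactly at the threshold is negative.
    """
    direction = rule.resolved_direction()
    if direction is Direction.higher_indicates_case:
        positive = value > rule.threshold
    else:
        positive = value < rule.threshold
    return "positive" if positive else "negative"


def classify(summary: Mapping | pd.Series, rule: ThresholdRule) -> str:
    """Apply a threshold rule to one participant-summary row."""
    value = float(summary[_SUMMARY_FIELD[ScaleKind(rule.scale_kind)]])
    return classify_value(value, rule)
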