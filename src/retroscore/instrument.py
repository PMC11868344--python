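"""Rating instrument and long-format rating data model.

The instrument codes each primary-school report on eleven criterion scales:
the nine diagnostic subcriteria of inattention (A1a-A1i) plus one overall
scale each for hyperactivity (A2H) and impulsivity (A2I).  Every scale is
rated twice per report, once on the *symptom* valence (ordinal 0/1/2:
not mentioned / subclinical / clinical expression) and once on the
*competency* valence (binary 0/1: adaptive behaviour not mentioned /
explicitly described), giving 22 (scale, valence) ratings per report.
A feature that is not mentioned in the report text is an explicit score of
0, never a missing row, so a complete report always has 22 records.

Rating tables are long-format: one row per
(participant, school year, term, rater, scale, valence) with an integer
score.  :func:`load_ratings` / :func:`write_ratings` provide validated,
round-trip-safe CSV I/O; :func:`densify` fills absent (scale, valence)
pairs with explicit zeros for lenient ingestion.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import logging
import os
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "Valence",
    "Group",
    "Term",
    "CriterionFamily",
    "CriterionScale",
    "RatingTable",
    "scale_registry",
    "scale_ids",
    "inattention_scale_ids",
    "score_domain",
    "RATING_COLUMNS",
    "REPORT_KEY",
    "RECORD_KEY",
    "load_ratings",
    "write_ratings",
    "densify",
    "validate_table",
]


class Valence(str, enum.Enum):
    symptom = "symptom"
    competency = "competency"


class Group(str, enum.Enum):
    case = "case"
    control = "control"


class Term(str, enum.Enum):
    midyear = "midyear"
    endyear = "endyear"


class CriterionFamily(str, enum.Enum):
    inattention = "inattention"
    hyperactivity = "hyperactivity"
    impulsivity = "impulsivity"


@dataclasses.dataclass(frozen=True)
class CriterionScale:
    """One criterion scale of the instrument, with both valence anchors."""

    scale_id: str
    criterion_family: CriterionFamily
    symptom_text: str
    competency_text: str


_REGISTRY: tuple[CriterionScale, ...] = (
    CriterionScale(
        "A1a", CriterionFamily.inattention,
        "often fails to give close attention to details or makes careless "
        "mistakes in schoolwork or other activities",
        "pays attention to detail and rarely makes careless mistakes",
    ),
    CriterionScale(
        "A1b", CriterionFamily.inattention,
        "often has trouble holding attention on tasks or play activities",
        "is alert for extended periods of time when performing tasks or playing",
    ),
    CriterionScale(
        "A1c", CriterionFamily.inattention,
        "often does not seem to listen when spoken to directly",
        "is an attentive listener and notices when others speak to them",
    ),
    CriterionScale(
        "A1d", CriterionFamily.inattention,
        "often does not follow through on instructions and fails to finish "
        "schoolwork, chores or duties",
        "completely carries out instructions and finishes schoolwork and duties",
    ),
    CriterionScale(
        "A1e", CriterionFamily.inattention,
        "often has trouble organizing tasks and activities",
        "organizes tasks and activities effortlessly",
    ),
    CriterionScale(
        "A1f", CriterionFamily.inattention,
        "often avoids, dislikes or is reluctant to do tasks that require "
        "mental effort over a long period of time",
        "prefers, likes or tolerates tasks that require sustained mental "
        "effort and is ambitious",
    ),
    CriterionScale(
        "A1g", CriterionFamily.inattention,
        "often loses things necessary for tasks and activities",
        "has items needed for specific tasks and activities at hand",
    ),
    CriterionScale(
        "A1h", CriterionFamily.inattention,
        "is often easily distracted by external stimuli",
        "is not distracted by external stimuli",
    ),
    CriterionScale(
        "A1i", CriterionFamily.inattention,
        "is often forgetful in daily activities",
        "is reliable in everyday activities",
    ),
    CriterionScale(
        "A2H", CriterionFamily.hyperactivity,
        "overall motor hyperactivity: markedly restless, fidgety or overactive",
        "shows calm, situation-appropriate levels of activity",
    ),
    CriterionScale(
        "A2I", CriterionFamily.impulsivity,
        "overall impulsivity: blurts out, interrupts, cannot await their turn",
        "shows age-appropriate impulse control and patience",
    ),
)

_SCALE_IDS: tuple[str, ...] = tuple(s.scale_id for s in _REGISTRY)
_INATTENTION_IDS: tuple[str, ...] = tuple(
    s.scale_id for s in _REGISTRY
    if s.criterion_family is CriterionFamily.inattention
)

# Valid score sets per valence: ordinal 0/1/2 for symptoms, binary for
# competencies.
_SCORE_DOMAIN: dict[str, frozenset[int]] = {
    Valence.symptom.value: frozenset({0, 1, 2}),
    Valence.competency.value: frozenset({0, 1}),
}

#: Column order of the canonical long-format ratings CSV.
RATING_COLUMNS: tuple[str, ...] = (
    "participant_id", "group", "school_year", "term", "rater_id",
    "medicated", "scale_id", "valence", "score",
)

#: Columns identifying one school report (one rater's coding of it).
REPORT_KEY: tuple[str, ...] = (
    "participant_id", "school_year", "term", "rater_id",
)

#: Columns identifying one rating record; unique within a valid table.
RECORD_KEY: tuple[str, ...] = REPORT_KEY + ("scale_id", "valence")

MIN_SCHOOL_YEAR = 1
MAX_SCHOOL_YEAR = 4


def scale_registry() -> tuple[CriterionScale, ...]:
    """Return the fixed 11-scale instrument registry.

    The registry is immutable: nine inattention subcriteria and one overall
    scale each for hyperactivity and impulsivity, each carrying both its
    symptom and competency anchor text (22 rated scales in total).
    """
    return _REGISTRY


def scale_ids() -> tuple[str, ...]:
    """The 11 scale identifiers, in instrument order."""
    return _SCALE_IDS


def inattention_scale_ids() -> tuple[str, ...]:
    """The nine inattention subcriterion identifiers A1a-A1i."""
    return _INATTENTION_IDS


def score_domain(valence: str | Valence) -> frozenset[int]:
    """Valid integer scores for a valence (``{0,1,2}`` or ``{0,1}``)."""
    key = valence.value if isinstance(valence, Valence) else str(valence)
    try:
        return _SCORE_DOMAIN[key]
    except KeyError:
        raise ValidationError(f"unknown valence {valence!r}") from None


@dataclasses.dataclass
class RatingTable:
    """A validated long-format collection of rating records.

    Parameters
    ----------
    df
        One row per record, with the columns in :data:`RATING_COLUMNS`.
    provenance
        Free-form metadata (source file, generator config/seed).
    """

    df: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    @property
    def n_reports(self) -> int:
        return len(self.df.drop_duplicates(subset=list(REPORT_KEY)))

    @property
    def rater_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["rater_id"].unique()))

    def copy(self) -> "RatingTable":
        return RatingTable(self.df.copy(), dict(self.provenance))

    def sorted(self) -> "RatingTable":
        """Canonical row order (record key, ascending); used for stable I/O."""
        out = self.df.sort_values(list(RECORD_KEY), kind="mergesort")
        return RatingTable(out.reset_index(drop=True), dict(self.provenance))

    def equals(self, other: "RatingTable") -> bool:
        """Record-for-record equality, ignoring row order and provenance."""
        a = self.sorted().df[list(RATING_COLUMNS)].reset_index(drop=True)
        b = other.sorted().df[list(RATING_COLUMNS)].reset_index(drop=True)
        return a.equals(b)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("participant_id", "group", "term", "rater_id", "scale_id",
                "valence"):
        df[col] = df[col].astype(str)
    df["school_year"] = pd.to_numeric(df["school_year"], errors="raise").astype(int)
    df["score"] = pd.to_numeric(df["score"], errors="raise").astype(int)
    if "medicated" not in df.columns:
        df["medicated"] = False
    else:
        df["medicated"] = (
            df["medicated"]
            .map(lambda v: str(v).strip().lower() in {"true", "1", "yes"})
            .astype(bool)
        )
    return df[list(RATING_COLUMNS)]


def _check_report_completeness(df: pd.DataFrame) -> pd.DataFrame:
    """Return report keys that do not carry all 22 (scale, valence) pairs."""
    counts = df.drop_duplicates(subset=list(RECORD_KEY)).groupby(
        list(REPORT_KEY), sort=False
    ).size()
    bad = counts[counts != 2 * len(_SCALE_IDS)]
    return bad.reset_index().rename(columns={0: "n_pairs"})


def validate_table(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate (and in lenient mode repair) a long-format ratings frame.

    Checks, in order: score domains per valence, known scale ids, school-year
    range, term/group/valence domains, duplicate record keys, per-participant
    group consistency, and report completeness (all 22 pairs present).

    In strict mode the first violation raises :class:`ValidationError`; in
    lenient mode offending rows are dropped (with counts logged), duplicate
    keys keep their first row, and incomplete reports are densified with
    explicit zero scores.
    """
    df = _coerce_types(df)
    problems: list[str] = []

    def _flag(mask: pd.Series, message: str) -> pd.Series:
        nonlocal df
        n = int(mask.sum())
        if n:
            first = df.index[mask][0]
            detail = f"{message}: {n} row(s), first at input row {first}"
            if strict:
                raise ValidationError(detail)
            problems.append(detail)
            df = df[~mask]
        return mask

    _flag(~df["valence"].isin(_SCORE_DOMAIN), "unknown valence")
    for valence, domain in _SCORE_DOMAIN.items():
        mask = (df["valence"] == valence) & ~df["score"].isin(domain)
        _flag(mask, f"score outside {sorted(domain)} for valence {valence!r}")
    _flag(~df["scale_id"].isin(_SCALE_IDS), "unknown scale_id")
    _flag(
        ~df["school_year"].between(MIN_SCHOOL_YEAR, MAX_SCHOOL_YEAR),
        f"school_year outside {MIN_SCHOOL_YEAR}..{MAX_SCHOOL_YEAR}",
    )
    _flag(~df["term"].isin([t.value for t in Term]), "unknown term")
    _flag(~df["group"].isin([g.value for g in Group]), "unknown group")

    dup = df.duplicated(subset=list(RECORD_KEY), keep="first")
    if dup.any():
        if strict:
            raise ValidationError(
                f"{int(dup.sum())} duplicate record key(s), e.g. "
                f"{tuple(df.loc[df.index[dup][0], list(RECORD_KEY)])}"
            )
        problems.append(f"dropped {int(dup.sum())} duplicate record(s)")
        df = df[~dup]

    grp = df.groupby("participant_id")["group"].nunique()
    mixed = grp[grp > 1]
    if len(mixed):
        msg = f"participants with conflicting group labels: {list(mixed.index)[:5]}"
        if strict:
            raise ValidationError(msg)
        problems.append(msg)
        df = df[~df["participant_id"].isin(mixed.index)]

    incomplete = _check_report_completeness(df)
    if len(incomplete):
        msg = (
            f"{len(incomplete)} report(s) lack the full 22 (scale, valence) "
            f"pairs, e.g. {tuple(incomplete.iloc[0][list(REPORT_KEY)])}"
        )
        if strict:
            raise ValidationError(msg)
        problems.append(msg + " (densified with zero scores)")
        df = densify(RatingTable(df)).df

    for p in problems:
        log.warning("lenient load: %s", p)
    return df.reset_index(drop=True)


def densify(table: RatingTable) -> RatingTable:
    """Fill absent (scale, valence) pairs of each report with explicit 0s.

    A feature not mentioned in a report is scored 0, so absent rows are
    unambiguous; densification makes that explicit and logs the fill count.
    """
    df = table.df
    reports = df.drop_duplicates(subset=list(REPORT_KEY))[
        list(REPORT_KEY) + ["group", "medicated"]
    ]
    full = reports.merge(
        pd.MultiIndex.from_product(
            [_SCALE_IDS, [v.value for v in Valence]],
            names=["scale_id", "valence"],
        ).to_frame(index=False),
        how="cross",
    )
    merged = full.merge(
        df[list(RECORD_KEY) + ["score"]], how="left", on=list(RECORD_KEY)
    )
    n_filled = int(merged["score"].isna().sum())
    if n_filled:
        log.info("densify: filled %d absent (scale, valence) pair(s) with 0",
                 n_filled)
    merged["score"] = merged["score"].fillna(0).astype(int)
    out = merged[list(RATING_COLUMNS)]
    return RatingTable(out.reset_index(drop=True), dict(table.provenance))


def load_ratings(
    path: str | os.PathLike | io.IOBase,
    strict: bool = True,
    cohort_path: str | os.PathLike | None = None,
) -> RatingTable:
    """Load and validate a long-format ratings CSV.

    Parameters
    ----------
    path
        CSV with header ``participant_id,group,school_year,term,rater_id,
        medicated,scale_id,valence,score`` (``medicated`` optional,
        defaulting to false).  UTF-8, RFC 4180 quoting.
    strict
        If true, any invariant violation raises; if false, offending rows
        are dropped/repaired and counts logged.
    cohort_path
        Optional ``cohort.csv`` with columns participant_id, group; group
        labels are cross-checked against the ratings.

    Returns
    -------
    RatingTable
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = set(RATING_COLUMNS) - {"medicated"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    try:
        df = validate_table(df, strict=strict)
    except (ValueError, TypeError) as exc:  # non-numeric year/score
        raise ValidationError(str(exc)) from exc

    if cohort_path is not None:
        cohort = pd.read_csv(cohort_path, dtype=str)
        if not {"participant_id", "group"} <= set(cohort.columns):
            raise FormatError("cohort.csv requires participant_id and group")
        merged = df[["participant_id", "group"]].drop_duplicates().merge(
            cohort, on="participant_id", suffixes=("", "_cohort"), how="left"
        )
        clash = merged[merged["group"] != merged["group_cohort"]]
        if len(clash):
            msg = (f"group labels disagree with cohort table for "
                   f"{list(clash['participant_id'])[:5]}")
            if strict:
                raise ValidationError(msg)
            log.warning("lenient load: %s", msg)

    source = path if isinstance(path, (str, os.PathLike)) else "<stream>"
    return RatingTable(df, {"source": str(source), "strict": strict})


def write_ratings(table: RatingTable, path: str | os.PathLike | io.IOBase) -> None:
    """Write a rating table to CSV; round-trip safe with :func:`load_ratings`."""
    out = table.sorted().df.copy()
    out["medicated"] = out["medicated"].map({True: "true", False: "false"})
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def records(table: RatingTable) -> Iterable[dict]:
    """Iterate over records as plain dicts (convenience for tests/debugging)."""
    return table.df.to_dict("records")
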