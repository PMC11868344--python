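"""Shared fixtures: handmade rating tables and small synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from retroscore.instrument import RATING_COLUMNS, RatingTable, scale_ids


def build_report_rows(
    participant_id: str = "p1",
    group: str = "case",
    school_year: int = 1,
    term: str = "endyear",
    rater_id: str = "R1",
    medicated: bool = False,
    symptom_scores: dict[str, int] | int = 0,
    competency_scores: dict[str, int] | int = 0,
) -> list[dict]:
    """All 22 rows of one complete report; scores default to 0 with
    per-scale overrides, or a single int applied to every scale."""
    rows = []
    for sid in scale_ids():
        for valence, spec in (("symptom", symptom_scores),
                              ("competency", competency_scores)):
            score = spec if isinstance(spec, int) else spec.get(sid, 0)
            rows.append(dict(
                participant_id=participant_id, group=group,
                school_year=school_year, term=term, rater_id=rater_id,
                medicated=medicated, scale_id=sid, valence=valence,
                score=score,
            ))
    return rows


def make_table(rows: list[dict]) -> RatingTable:
    return RatingTable(pd.DataFrame(rows, columns=list(RATING_COLUMNS)))


@pytest.fixture
def report_builder():
    return build_report_rows


@pytest.fixture
def table_builder():
    return make_table


@pytest.fixture(scope="session")
def small_cohort():
    """A 20+20 participant synthetic cohort with default effect sizes."""
    from retroscore.synthetic import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(n_case=20, n_control=20, seed=11))
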