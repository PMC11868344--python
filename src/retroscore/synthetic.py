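"""Synthetic school-report rating cohorts with known generative truth.

No real rated school-report data are distributed, so every downstream stage
is exercised on simulated cohorts that mirror the structure the analysis
assumes: two groups (case = childhood ADHD, control = typically developing)
observed over four primary-school years, one or two coded reports per year,
11 criterion scales rated on both valences per report.

Generative model (latent-threshold, ordered-probit style). For participant
``i`` (group indicator ``g``), school year ``y`` (coded 0..3 so the group
effect is the year-1 effect), report term ``t`` and scale ``s``::

    eta = beta_group * g + beta_year * y + beta_interaction * g * y
          + u_i + eps,          u_i ~ N(0, sigma_participant^2),
                                eps ~ N(0, 1)  i.i.d. per record

The ordinal symptom score is the category of ``eta`` under two strictly
increasing cutpoints (0 below the first, 1 between, 2 above), matching the
not-mentioned / subclinical / clinical coding.  The binary competency score
is Bernoulli with::

    logit p = competency_intercept - competency_group_effect * g
              - coupling * (u_i + eps)

so that reports with high symptom latents tend to lack described
competencies; ``coupling`` sets the strength of that within-report link.
A negative ``beta_interaction`` shrinks the group gap linearly across
school years, the pattern the analysis is designed to detect.

Randomness is keyed per participant (``default_rng([seed, stream, index])``)
so enlarging the cohort never changes the records of earlier participants.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ConfigError
from .instrument import (
    RATING_COLUMNS,
    RatingTable,
    Valence,
    scale_ids,
)

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_cohort",
    "generate_paired_raters",
    "expected_symptom_score",
    "expected_symptom_sum_difference",
    "latent_auc",
]

_N_SCALES = len(scale_ids())


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a mid-sized clinical comparison: a year-1 group gap of
    1.5 latent SD that shrinks by 0.3 SD per school year, a participant
    random-intercept SD of 0.8, cutpoints placing control-group records
    mostly in the "not mentioned" category, and most years carrying both a
    midyear and an end-of-year report.
    """

    n_case: int = 100
    n_control: int = 100
    years: int = 4
    p_two_reports: float = 0.85
    beta_group: float = 1.5
    beta_year: float = -0.1
    beta_interaction: float = -0.3
    sigma_participant: float = 0.8
    ordinal_cutpoints: tuple[float, float] = (0.75, 1.75)
    competency_intercept: float = 0.5
    competency_group_effect: float = 1.5
    coupling: float = 0.5
    rater_error: float = 0.05
    p_medicated: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("n_case and n_control must be >= 1")
        if not 1 <= self.years <= 4:
            raise ConfigError("years must be in 1..4")
        for name in ("p_two_reports", "rater_error", "p_medicated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_participant < 0:
            raise ConfigError("sigma_participant must be >= 0")
        c1, c2 = self.ordinal_cutpoints
        if not c1 < c2:
            raise ConfigError("ordinal_cutpoints must be strictly increasing")


@dataclasses.dataclass
class TruthRecord:
    """Generative ground truth echoed alongside a synthetic table.

    ``latents`` carries the continuous record-level symptom latents before
    discretization (one row per symptom record), which closed-form oracles
    for the latent model can be checked against.
    """

    config: GeneratorConfig
    intercepts: pd.Series  # participant_id -> u_i
    expected_group_difference: pd.Series  # school_year -> latent case-control gap
    latents: pd.DataFrame


def _participants(config: GeneratorConfig) -> Iterator[tuple[str, str, int, int]]:
    for i in range(config.n_case):
        yield f"case-{i + 1:04d}", "case", 0, i
    for i in range(config.n_control):
        yield f"ctrl-{i + 1:04d}", "control", 1, i


def _simulate_participant(
    config: GeneratorConfig, pid: str, group: str, stream: int, index: int
) -> tuple[list[dict], float, np.ndarray]:
    rng = np.random.default_rng([config.seed, stream, index])
    g = 1.0 if group == "case" else 0.0
    u = rng.normal(0.0, config.sigma_participant)
    c1, c2 = config.ordinal_cutpoints
    sids = scale_ids()

    rows: list[dict] = []
    latents: list[np.ndarray] = []
    for year in range(1, config.years + 1):
        y0 = year - 1
        mu = (config.beta_group * g + config.beta_year * y0
              + config.beta_interaction * g * y0)
        two = rng.random() < config.p_two_reports
        terms = ["midyear", "endyear"] if two else ["endyear"]
        for term in terms:
            medicated = bool(g and rng.random() < config.p_medicated)
            eps = rng.normal(0.0, 1.0, size=_N_SCALES)
            eta = mu + u + eps
            sym = np.digitize(eta, [c1, c2]).astype(int)  # 0/1/2
            p_comp = expit(
                config.competency_intercept
                - config.competency_group_effect * g
                - config.coupling * (u + eps)
            )
            comp = (rng.random(_N_SCALES) < p_comp).astype(int)
            latents.append(eta)
            for s, sid in enumerate(sids):
                base = dict(
                    participant_id=pid, group=group, school_year=year,
                    term=term, rater_id="R1", medicated=medicated,
                    scale_id=sid,
                )
                rows.append({**base, "valence": Valence.symptom.value,
                             "score": int(sym[s])})
                rows.append({**base, "valence": Valence.competency.value,
                             "score": int(comp[s])})
    return rows, u, np.concatenate(latents) if latents else np.empty(0)


def generate_cohort(config: GeneratorConfig) -> tuple[RatingTable, TruthRecord]:
    """Simulate a rating table for one rater plus its generative truth.

    Deterministic given ``config`` (including its seed); all 22
    (scale, valence) pairs are emitted for every report.
    """
    config.validate()
    all_rows: list[dict] = []
    intercepts: dict[str, float] = {}
    latent_frames: list[pd.DataFrame] = []
    for pid, group, stream, index in _participants(config):
        rows, u, eta = _simulate_participant(config, pid, group, stream, index)
        all_rows.extend(rows)
        intercepts[pid] = u
        sym_rows = [r for r in rows if r["valence"] == Valence.symptom.value]
        lf = pd.DataFrame(sym_rows)[
            ["participant_id", "group", "school_year", "term", "scale_id"]
        ]
        lf["latent"] = eta
        latent_frames.append(lf)

    df = pd.DataFrame(all_rows, columns=list(RATING_COLUMNS))
    years = np.arange(1, config.years + 1)
    expected = pd.Series(
        config.beta_group + config.beta_interaction * (years - 1),
        index=pd.Index(years, name="school_year"),
        name="latent_group_difference",
    )
    truth = TruthRecord(
        config=config,
        intercepts=pd.Series(intercepts, name="u"),
        expected_group_difference=expected,
        latents=pd.concat(latent_frames, ignore_index=True),
    )
    table = RatingTable(df, {"source": "synthetic", "seed": config.seed})
    return table.sorted(), truth


def generate_paired_raters(
    config: GeneratorConfig,
) -> tuple[RatingTable, RatingTable, TruthRecord]:
    """Simulate the same cohort coded by two raters.

    Rater R2 sees the identical reports; each of their scores is
    independently perturbed with probability ``rater_error`` by +/-1,
    clamped to the valence's score domain (near-miss disagreement, as
    typical between trained expert raters).
    """
    config.validate()
    table_a, truth = generate_cohort(config)
    df_b = table_a.df.copy()
    df_b["rater_id"] = "R2"

    score = df_b["score"].to_numpy().copy()
    is_sym = (df_b["valence"] == Valence.symptom.value).to_numpy()
    pid_codes, pid_order = pd.factorize(df_b["participant_id"], sort=False)
    group = df_b["group"].to_numpy()

    for k, pid in enumerate(pid_order):
        mask = pid_codes == k
        stream = 2 if group[np.argmax(mask)] == "case" else 3
        # participant index inside its group, recovered from the id suffix
        index = int(str(pid).split("-")[1]) - 1
        rng = np.random.default_rng([config.seed, stream, index])
        n = int(mask.sum())
        perturb = rng.random(n) < config.rater_error
        direction = np.where(rng.random(n) < 0.5, -1, 1)
        s = score[mask]
        hi = np.where(is_sym[mask], 2, 1)
        s = np.where(perturb, np.clip(s + direction, 0, hi), s)
        score[mask] = s

    df_b["score"] = score.astype(int)
    table_b = RatingTable(
        df_b, {"source": "synthetic", "seed": config.seed, "rater": "R2"}
    )
    return table_a, table_b.sorted(), truth


# ---------------------------------------------------------------------------
# Closed-form oracles for the latent generative model
# ---------------------------------------------------------------------------

def _latent_mean(config: GeneratorConfig, group: str, year: int) -> float:
    g = 1.0 if group == "case" else 0.0
    y0 = year - 1
    return (config.beta_group * g + config.beta_year * y0
            + config.beta_interaction * g * y0)


def expected_symptom_score(config: GeneratorConfig, group: str, year: int) -> float:
    """E[ordinal symptom score] for one record, marginal over u and eps.

    The record latent is Gaussian with variance ``1 + sigma_participant^2``;
    the expected category is P(eta > c1) + P(eta > c2).
    """
    mu = _latent_mean(config, group, year)
    s = np.sqrt(1.0 + config.sigma_participant ** 2)
    c1, c2 = config.ordinal_cutpoints
    return float(stats.norm.sf(c1, mu, s) + stats.norm.sf(c2, mu, s))


def expected_symptom_sum_difference(config: GeneratorConfig, year: int) -> float:
    """Expected case-control difference in the 11-scale symptom sum at a year."""
    return _N_SCALES * (
        expected_symptom_score(config, "case", year)
        - expected_symptom_score(config, "control", year)
    )


def latent_auc(config: GeneratorConfig, year: int = 1) -> float:
    """Binormal AUC of a single record's symptom latent, case vs control.

    Both groups' latents are Gaussian with variance ``1 + sigma_participant^2``
    and mean gap ``Delta`` at the given year, so the AUC is
    ``Phi(Delta / sqrt(2 + 2 sigma_participant^2))``.
    """
    delta = _latent_mean(config, "case", year) - _latent_mean(config, "control", year)
    return float(stats.norm.cdf(
        delta / np.sqrt(2.0 + 2.0 * config.sigma_participant ** 2)
    ))
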