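"""Config-driven end-to-end analysis runner.

One call to :func:`run_all` executes the full analysis graph on either a
ratings CSV or a synthetic cohort:

    load / generate -> (optional) interrater reliability -> yearly and
    participant summary scores -> ROC / cutpoint / DeLong diagnostics
    (plus a medication-exclusion subgroup rerun) -> linear mixed models
    for the six responses.

Outputs are written to the configured directory as ``scores.csv``,
``diag.json``, ``lmm.json``, ``kappa.json`` (when paired raters are
analysed) and ``run.log``.  JSON outputs use sorted keys and fixed 12
significant-digit float formatting, so identical (config, seed) runs
produce byte-identical files and test diffs are meaningful.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, mixed_model, reliability, scoring, synthetic
from .errors import (
    ConfigError,
    InfeasibleConstraintError,
    RetroscoreError,
)
from .instrument import RatingTable, load_ratings
from .scoring import Direction, ScaleKind
from .synthetic import GeneratorConfig

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_SCALE_FIELDS = {
    ScaleKind.symptoms: ("summary_symptoms", Direction.higher_indicates_case),
    ScaleKind.competencies: ("summary_competencies", Direction.lower_indicates_case),
    ScaleKind.integrated: ("integrated_index", Direction.lower_indicates_case),
}


@dataclasses.dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``ratings_path`` and ``generator`` must be given.
    """

    ratings_path: str | None = None
    generator: GeneratorConfig | None = None
    paired_raters: bool = False
    rater: str = "R1"
    medication_rerun: bool = True
    select_random_structure: bool = True
    responses: tuple[str, ...] = tuple(r.value for r in mixed_model.Response)
    fixed_specificities: tuple[float, ...] = (0.90, 0.95, 0.99)
    out_dir: str = "retroscore_out"
    seed: int = 0
    strict: bool = True

    def validate(self) -> None:
        if (self.ratings_path is None) == (self.generator is None):
            raise ConfigError(
                "exactly one of ratings_path and generator must be set"
            )
        if self.paired_raters and self.generator is None:
            raise ConfigError("paired_raters requires a generator config")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            if "ordinal_cutpoints" in gen:
                gen["ordinal_cutpoints"] = tuple(gen["ordinal_cutpoints"])
            gen = GeneratorConfig(**gen)
        for key in ("responses", "fixed_specificities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)


def _jsonify(obj: Any) -> Any:
    """Convert to plain JSON types with stable 12-sig-digit floats."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(_jsonify(payload), sort_keys=True, indent=1) + "\n",
        encoding="utf-8",
    )


def _diagnostics_block(summaries, fixed_specs) -> dict:
    block: dict[str, Any] = {}
    labels = summaries["group"].to_numpy()
    values = {}
    for kind, (field, direction) in _SCALE_FIELDS.items():
        scores_vec = summaries[field].to_numpy(dtype=float)
        values[kind] = (scores_vec, direction)
        entry: dict[str, Any] = {
            "auc": diagnostics.auc_mann_whitney(scores_vec, labels, direction)
        }
        cut = diagnostics.optimal_cutpoint(scores_vec, labels, direction,
                                           "max_youden")
        rows = [dataclasses.asdict(cut)]
        for c in fixed_specs:
            try:
                rows.append(dataclasses.asdict(
                    diagnostics.optimal_cutpoint(
                        scores_vec, labels, direction,
                        "max_sens_at_spec", min_specificity=c,
                    )
                ))
            except InfeasibleConstraintError as exc:
                rows.append({"objective": f"max_sens_at_spec({c:g})",
                             "infeasible": str(exc)})
        entry["cutpoints"] = rows
        block[kind.value] = entry

    comparisons = []
    pairs = [
        (ScaleKind.symptoms, ScaleKind.competencies),
        (ScaleKind.integrated, ScaleKind.competencies),
        (ScaleKind.integrated, ScaleKind.symptoms),
    ]
    for a, b in pairs:
        sa, da = values[a]
        sb, db = values[b]
        cmp = diagnostics.delong_compare(sa, sb, labels, da, db)
        comparisons.append({
            "pair": f"{a.value}_vs_{b.value}",
            **dataclasses.asdict(cmp),
        })
    adjusted = mixed_model.holm([c["p_two_sided"] for c in comparisons])
    for c, ph in zip(comparisons, adjusted):
        c["p_holm"] = float(ph)
    block["delong"] = comparisons
    return block


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the consolidated run report.

    The report dict mirrors what is written to disk.  Identical
    (config, seed) runs produce identical outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w",
                                  encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("retroscore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict[str, Any] = {}
    try:
        t0 = time.perf_counter()

        # -- stage: input -------------------------------------------------
        kappa_payload = None
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            if config.paired_raters:
                table, table_b, _truth = synthetic.generate_paired_raters(gen)
                results, means = reliability.kappa_report(table, table_b)
                kappa_payload = {
                    "per_scale": [
                        {"scale_id": r.scale_id, "valence": r.valence,
                         "kappa": r.kappa, "n_pairs": r.n_pairs}
                        for r in results
                    ],
                    "mean_by_valence": means,
                }
            else:
                table, _truth = synthetic.generate_cohort(gen)
        else:
            table = load_ratings(config.ratings_path, strict=config.strict)
        log.info("stage=input records=%d participants=%d", table.n_records,
                 table.n_participants)

        # -- stage: scoring ------------------------------------------------
        analysed = scoring.select_rater(table, config.rater) \
            if config.rater in table.rater_ids else table
        years = scoring.year_scores(analysed)
        summaries = scoring.participant_summaries(years)
        scores_out = years.copy()
        scores_out["integrated_index"] = scores_out["integrated"]
        scores_path = out_dir / "scores.csv"
        cols = ["participant_id", "group", "school_year", "symptom_sum",
                "competency_sum", "inattention_mean_sym",
                "inattention_mean_comp", "integrated_index"]
        summary_rows = summaries.rename(columns={
            "summary_symptoms": "symptom_sum",
            "summary_competencies": "competency_sum",
        }).assign(school_year="ALL", inattention_mean_sym=np.nan,
                  inattention_mean_comp=np.nan)
        combined = pd.concat(
            [scores_out[cols], summary_rows[cols]], ignore_index=True
        )
        combined.to_csv(scores_path, index=False, lineterminator="\n")
        log.info("stage=scoring year_rows=%d participants=%d", len(years),
                 len(summaries))

        # -- stage: diagnostics ---------------------------------------------
        diag: dict[str, Any] = {
            "all_reports": _diagnostics_block(summaries,
                                              config.fixed_specificities)
        }
        if config.medication_rerun and analysed.df["medicated"].any():
            filtered = scoring.filter_medicated(analysed, include=False)
            sub = scoring.participant_summaries(scoring.year_scores(filtered))
            diag["excluding_medicated"] = _diagnostics_block(
                sub, config.fixed_specificities
            )
        _write_json(diag, out_dir / "diag.json")
        log.info("stage=diagnostics scales=%d", len(_SCALE_FIELDS))

        # -- stage: mixed models --------------------------------------------
        base_spec = mixed_model.LmmSpec()
        if config.select_random_structure:
            base_spec = mixed_model.select_random_structure(years, base_spec)
        lmm: dict[str, Any] = {
            "random_structure": base_spec.random_structure.value
        }
        for resp in config.responses:
            spec = dataclasses.replace(
                base_spec, response=mixed_model.Response(resp)
            )
            fit = mixed_model.fit_lmm(years, spec)
            tests = mixed_model.wald_tests(fit)
            lmm[resp] = {
                "beta": dict(fit.beta),
                "sigma2_participant": fit.sigma2_participant,
                "sigma2_residual": fit.sigma2_residual,
                "loglik": fit.loglik,
                "n_obs": fit.n_obs,
                "n_participants": fit.n_participants,
                "wald": [dataclasses.asdict(t) for t in tests],
            }
        _write_json(lmm, out_dir / "lmm.json")
        log.info("stage=mixed_model responses=%d", len(config.responses))

        if kappa_payload is not None:
            _write_json(kappa_payload, out_dir / "kappa.json")
            log.info("stage=reliability scales=%d",
                     len(kappa_payload["per_scale"]))

        report = {"scores": str(scores_path), "diagnostics": diag,
                  "mixed_models": lmm}
        if kappa_payload is not None:
            report["reliability"] = kappa_payload
        log.info("stage=done elapsed=%.2fs", time.perf_counter() - t0)
        return report
    except RetroscoreError:
        log.exception("pipeline failed")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
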