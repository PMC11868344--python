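"""Random-intercept linear mixed models of yearly scores and Wald contrasts.

Yearly summary scores are repeated measures of one participant, so group and
school-year effects are estimated with a Gaussian linear mixed model

    y_iy = X_iy beta + u_i + eps_iy,   u_i ~ N(0, sigma2_participant),
                                       eps ~ N(0, sigma2_residual),

with a saturated group x year(categorical) fixed-effect design.  Fitting is
delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`
(REML by default for reporting, ML for likelihood-ratio model comparison);
the contrast machinery on top is what this module provides.

Four families of chi-square Wald hypotheses about the case-control gap are
derived from the single saturated fit:

1. overall group difference, averaged across school years (1 df);
2. linear trend of the group difference across school years (1 df);
3. group difference separately per school year (Holm-corrected over the
   number of years);
4. group difference in year 1 versus each later year (Holm-corrected over
   the number of comparisons).

Families 1-2 are statistically independent of each other and are reported
uncorrected.  Each contrast c gives chi2 = (c'beta)^2 / (c' V c) with V the
fixed-effect covariance, referenced to chi-square with 1 df.

Random-structure selection (:func:`select_random_structure`) starts from a
correlated random intercept + year slope and iteratively removes components
that do not significantly improve the ML fit; a variance component tested
on its boundary uses the 50:50 chi-square mixture (halved p).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import ContrastError, EstimationError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "Response",
    "RandomStructure",
    "LmmSpec",
    "LmmFit",
    "WaldResult",
    "fit_lmm",
    "wald_tests",
    "select_random_structure",
    "holm",
]


class Response(str, enum.Enum):
    integrated = "integrated"
    symptom_sum = "symptom_sum"
    competency_sum = "competency_sum"
    inattention = "inattention"
    hyperactivity = "hyperactivity"
    impulsivity = "impulsivity"


#: Column of the year-scores frame modelled for each response. Criterion
#: families enter through their integrated (competency minus symptom) score.
RESPONSE_COLUMNS: dict[Response, str] = {
    Response.integrated: "integrated",
    Response.symptom_sum: "symptom_sum",
    Response.competency_sum: "competency_sum",
    Response.inattention: "inattention_integrated",
    Response.hyperactivity: "hyperactivity_integrated",
    Response.impulsivity: "impulsivity_integrated",
}


class RandomStructure(str, enum.Enum):
    intercept = "intercept"
    intercept_slope_uncorrelated = "intercept_slope_uncorrelated"
    intercept_slope_correlated = "intercept_slope_correlated"


@dataclasses.dataclass(frozen=True)
class LmmSpec:
    response: Response = Response.integrated
    estimation: str = "REML"  # "REML" or "ML"
    random_structure: RandomStructure = RandomStructure.intercept

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValidationError("estimation must be 'REML' or 'ML'")


@dataclasses.dataclass
class LmmFit:
    spec: LmmSpec
    beta: pd.Series
    vcov_beta: pd.DataFrame
    sigma2_participant: float
    sigma2_residual: float
    sigma2_slope: float | None
    loglik: float
    n_obs: int
    n_participants: int
    years: tuple[int, ...]
    converged: bool


@dataclasses.dataclass(frozen=True)
class WaldResult:
    label: str
    family: int
    chi2: float
    df: int
    p: float
    p_holm: float | None = None


def _prepare(scores: pd.DataFrame, response: Response) -> pd.DataFrame:
    col = RESPONSE_COLUMNS[Response(response)]
    if col not in scores.columns:
        raise ValidationError(f"year-scores frame lacks column {col!r}")
    data = scores[["participant_id", "group", "school_year", col]].copy()
    data = data.rename(columns={col: "y"})
    data["is_case"] = (data["group"] == "case").astype(float)
    data["year0"] = data["school_year"].astype(int) - 1
    return data


def fit_lmm(scores: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """Fit the random-intercept (optionally + slope) model for one response.

    ``scores`` is a year-scores frame (one row per participant-year).
    Raises :class:`EstimationError` on non-convergence and for designs with
    too little replication (need >= 2 participants, and overall more
    observations than participants for the intercept variance to be
    identified).
    """
    data = _prepare(scores, spec.response)
    n_participants = data["participant_id"].nunique()
    if n_participants < 2:
        raise EstimationError("need >= 2 participants")
    if len(data) <= n_participants:
        raise EstimationError(
            "need repeated measures (more observations than participants)"
        )

    years = tuple(sorted(data["school_year"].unique()))
    formula = "y ~ is_case * C(school_year)" if len(years) > 1 else "y ~ is_case"

    kwargs: dict = {"groups": "participant_id"}
    structure = RandomStructure(spec.random_structure)
    if structure is RandomStructure.intercept_slope_correlated:
        kwargs["re_formula"] = "1 + year0"
    elif structure is RandomStructure.intercept_slope_uncorrelated:
        kwargs["re_formula"] = "1"
        kwargs["vc_formula"] = {"slope": "0 + year0"}

    model = smf.mixedlm(formula, data, **kwargs)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=(spec.estimation == "REML"))
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular design: {exc}") from exc
    except Exception as exc:  # optimizer failures
        raise EstimationError(f"mixed-model fit failed: {exc}") from exc
    if not result.converged:
        raise EstimationError(
            f"mixed-model fit did not converge for response "
            f"{spec.response!r} ({structure.value})"
        )

    fe = result.fe_params
    vcov = result.cov_params().loc[fe.index, fe.index]
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    sigma2_p = float(cov_re[0, 0]) if cov_re.size else 0.0
    sigma2_slope = None
    if structure is RandomStructure.intercept_slope_correlated:
        sigma2_slope = float(cov_re[1, 1])
    elif structure is RandomStructure.intercept_slope_uncorrelated:
        sigma2_slope = float(result.vcomp[0]) if len(result.vcomp) else 0.0

    return LmmFit(
        spec=spec,
        beta=fe,
        vcov_beta=vcov,
        sigma2_participant=sigma2_p,
        sigma2_residual=float(result.scale),
        sigma2_slope=sigma2_slope,
        loglik=float(result.llf),
        n_obs=len(data),
        n_participants=n_participants,
        years=years,
        converged=bool(result.converged),
    )


# ---------------------------------------------------------------------------
# Wald contrasts
# ---------------------------------------------------------------------------

def _group_diff_row(fit: LmmFit, year: int) -> np.ndarray:
    """Contrast vector for the case-control difference at one school year."""
    names = list(fit.beta.index)
    row = np.zeros(len(names))
    row[names.index("is_case")] = 1.0
    inter = f"is_case:C(school_year)[T.{year}]"
    if inter in names:
        row[names.index(inter)] = 1.0
    elif year != fit.years[0]:
        raise ContrastError(f"no interaction term for school year {year}")
    return row


def wald_chi2(fit: LmmFit, contrast: np.ndarray) -> tuple[float, int, float]:
    """Chi-square Wald statistic for a single contrast row c'beta = 0."""
    c = np.asarray(contrast, dtype=float)
    est = float(c @ fit.beta.to_numpy())
    var = float(c @ fit.vcov_beta.to_numpy() @ c)
    if var <= 0:
        if est == 0.0:
            return 0.0, 1, 1.0  # null contrast: trivially zero
        raise ContrastError("contrast is not estimable (zero variance)")
    chi2 = est * est / var
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


def holm(pvalues: "list[float] | np.ndarray") -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def wald_tests(fit: LmmFit) -> list[WaldResult]:
    """The four families of group-difference hypotheses from one fit."""
    years = fit.years
    k = len(years)
    results: list[WaldResult] = []

    # family 1: group difference averaged over school years
    avg = np.mean([_group_diff_row(fit, y) for y in years], axis=0)
    chi2, df, p = wald_chi2(fit, avg)
    results.append(WaldResult("group_overall", 1, chi2, df, p))

    # family 2: linear trend of the group difference across years
    if k > 1:
        w = np.array(years, dtype=float)
        w -= w.mean()
        lin = np.sum([wi * _group_diff_row(fit, y) for wi, y in zip(w, years)],
                     axis=0)
        chi2, df, p = wald_chi2(fit, lin)
        results.append(WaldResult("group_by_year_linear", 2, chi2, df, p))

    # family 3: group difference per school year, Holm over k
    fam3 = [(f"group_year{y}", *wald_chi2(fit, _group_diff_row(fit, y)))
            for y in years]
    adj3 = holm([r[3] for r in fam3])
    for (label, chi2, df, p), ph in zip(fam3, adj3):
        results.append(WaldResult(label, 3, chi2, df, p, float(ph)))

    # family 4: year-1 group difference vs each later year, Holm over k-1
    if k > 1:
        first = years[0]
        fam4 = []
        for y in years[1:]:
            c = _group_diff_row(fit, first) - _group_diff_row(fit, y)
            fam4.append((f"year{first}_vs_year{y}", *wald_chi2(fit, c)))
        adj4 = holm([r[3] for r in fam4])
        for (label, chi2, df, p), ph in zip(fam4, adj4):
            results.append(WaldResult(label, 4, chi2, df, p, float(ph)))

    return results


# ---------------------------------------------------------------------------
# Random-structure selection
# ---------------------------------------------------------------------------

def _try_fit(scores: pd.DataFrame, spec: LmmSpec) -> LmmFit | None:
    try:
        return fit_lmm(scores, spec)
    except EstimationError as exc:
        log.info("candidate %s failed: %s", spec.random_structure, exc)
        return None


def select_random_structure(
    scores: pd.DataFrame,
    spec: LmmSpec | None = None,
    alpha: float = 0.05,
) -> LmmSpec:
    """Iteratively remove random-effect components that do not pay for
    themselves.

    Candidates, most to least complex: correlated intercept + year slope,
    uncorrelated intercept + year slope, intercept only.  Adjacent candidates
    are compared with ML likelihood-ratio tests; removing the
    intercept-slope correlation is a 1-df interior test, removing the slope
    variance is a boundary test whose p-value is halved (50:50 mixture of
    chi2_0 and chi2_1).  Returns the selected spec with the caller's
    response/estimation settings.
    """
    spec = spec or LmmSpec()
    data = _prepare(scores, spec.response)
    max_years = data.groupby("participant_id")["school_year"].nunique().max()
    ml = dataclasses.replace(spec, estimation="ML")
    if max_years < 2:
        raise EstimationError("random effects unidentifiable with one "
                              "observation per participant")
    if max_years == 2 or len(set(data["year0"])) < 2:
        # a random year slope is not identifiable against the residual
        return dataclasses.replace(spec,
                                   random_structure=RandomStructure.intercept)

    fits = {
        s: _try_fit(scores, dataclasses.replace(ml, random_structure=s))
        for s in RandomStructure
    }
    if all(f is None for f in fits.values()):
        raise EstimationError("no random-structure candidate converged")

    current = RandomStructure.intercept_slope_correlated

    def _lrt(full: LmmFit | None, reduced: LmmFit | None,
             boundary: bool) -> bool:
        """True when the richer structure significantly improves fit."""
        if full is None:
            return False
        if reduced is None:
            return True
        lr = 2.0 * (full.loglik - reduced.loglik)
        p = float(stats.chi2.sf(max(lr, 0.0), 1))
        if boundary:
            p /= 2.0
        return p < alpha

    # step 1: does the correlation earn its keep?
    if not _lrt(fits[RandomStructure.intercept_slope_correlated],
                fits[RandomStructure.intercept_slope_uncorrelated],
                boundary=False):
        current = RandomStructure.intercept_slope_uncorrelated
        # step 2: does the slope variance earn its keep? (boundary test)
        if not _lrt(fits[RandomStructure.intercept_slope_uncorrelated],
                    fits[RandomStructure.intercept],
                    boundary=True):
            current = RandomStructure.intercept

    return dataclasses.replace(spec, random_structure=current)
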