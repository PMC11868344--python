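"""Mixed-model fitting, Wald contrast families and structure selection."""

import numpy as np
import pandas as pd
import patsy
import pytest
import statsmodels.formula.api as smf
from scipy import stats

from retroscore.errors import ContrastError, EstimationError
from retroscore.mixed_model import (
    LmmSpec,
    RandomStructure,
    Response,
    fit_lmm,
    holm,
    select_random_structure,
    wald_chi2,
    wald_tests,
    _group_diff_row,
)
from retroscore.scoring import year_scores
from retroscore.synthetic import (
    GeneratorConfig,
    expected_symptom_sum_difference,
    generate_cohort,
)


def block_loglik(data: pd.DataFrame, beta: np.ndarray, s2p: float,
                 s2r: float) -> float:
    """Independent Gaussian log-likelihood of the random-intercept model,
    evaluated per participant block (oracle; no statsmodels)."""
    X = np.asarray(patsy.dmatrix("is_case * C(school_year)", data))
    resid = data["y"].to_numpy() - X @ beta
    ll = 0.0
    for _, idx in data.groupby("participant_id").indices.items():
        r = resid[idx]
        m = len(r)
        cov = s2r * np.eye(m) + s2p * np.ones((m, m))
        ll += stats.multivariate_normal.logpdf(r, mean=np.zeros(m), cov=cov)
    return float(ll)


def gls_beta(data: pd.DataFrame, s2p: float, s2r: float) -> np.ndarray:
    """Profile GLS fixed effects at fixed variance components (oracle)."""
    X = np.asarray(patsy.dmatrix("is_case * C(school_year)", data))
    y = data["y"].to_numpy()
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    xtvy = np.zeros(X.shape[1])
    for _, idx in data.groupby("participant_id").indices.items():
        cov = s2r * np.eye(len(idx)) + s2p * np.ones((len(idx), len(idx)))
        vinv = np.linalg.inv(cov)
        xtvx += X[idx].T @ vinv @ X[idx]
        xtvy += X[idx].T @ vinv @ y[idx]
    return np.linalg.solve(xtvx, xtvy)


def _model_frame(scores: pd.DataFrame, column: str = "integrated") -> pd.DataFrame:
    data = scores[["participant_id", "group", "school_year", column]].copy()
    data = data.rename(columns={column: "y"})
    data["is_case"] = (data["group"] == "case").astype(float)
    return data


@pytest.fixture(scope="module")
def cohort_scores():
    cfg = GeneratorConfig(n_case=40, n_control=40, seed=5)
    table, _ = generate_cohort(cfg)
    return year_scores(table)


class TestFit:
    def test_zero_intercept_variance_limit_matches_ols(self):
        cfg = GeneratorConfig(n_case=40, n_control=40, sigma_participant=0.0,
                              p_two_reports=1.0, seed=5)
        table, _ = generate_cohort(cfg)
        ys = year_scores(table)
        fit = fit_lmm(ys, LmmSpec(estimation="ML"))
        data = _model_frame(ys)
        ols = smf.ols("y ~ is_case * C(school_year)", data).fit()
        # balanced design: GLS = OLS for the fixed effects
        assert np.abs(fit.beta.to_numpy() - ols.params.to_numpy()).max() < 1e-6
        # fitted intercept variance collapses relative to the residual
        assert fit.sigma2_participant < 0.05 * fit.sigma2_residual
        # independent likelihood oracle at sigma2_p = 0 reproduces OLS loglik
        s2r_ml = np.mean(ols.resid ** 2)
        oracle = block_loglik(data, ols.params.to_numpy(), 0.0, s2r_ml)
        assert oracle == pytest.approx(ols.llf, abs=1e-8)

    def test_loglik_agrees_with_block_oracle(self, cohort_scores):
        fit = fit_lmm(cohort_scores, LmmSpec(estimation="ML"))
        data = _model_frame(cohort_scores)
        oracle = block_loglik(data, fit.beta.to_numpy(),
                              fit.sigma2_participant, fit.sigma2_residual)
        assert oracle == pytest.approx(fit.loglik, abs=1e-4)

    def test_ml_optimum_beats_variance_grid(self):
        cfg = GeneratorConfig(n_case=3, n_control=3, seed=21,
                              p_two_reports=1.0)
        table, _ = generate_cohort(cfg)
        ys = year_scores(table)
        fit = fit_lmm(ys, LmmSpec(estimation="ML"))
        data = _model_frame(ys)
        s2p_grid = np.linspace(0.0, 4 * max(fit.sigma2_participant, 1.0), 50)
        s2r_grid = np.linspace(0.2, 4 * fit.sigma2_residual, 50)
        best = -np.inf
        for s2p in s2p_grid:
            for s2r in s2r_grid:
                beta = gls_beta(data, s2p, s2r)
                best = max(best, block_loglik(data, beta, s2p, s2r))
        assert fit.loglik >= best - 1e-6

    def test_group_effect_recovered_within_two_se(self):
        cfg = GeneratorConfig(n_case=100, n_control=100, seed=13)
        table, _ = generate_cohort(cfg)
        ys = year_scores(table)
        fit = fit_lmm(ys, LmmSpec(response=Response.symptom_sum))
        c = _group_diff_row(fit, 1)
        est = float(c @ fit.beta.to_numpy())
        se = float(np.sqrt(c @ fit.vcov_beta.to_numpy() @ c))
        truth = expected_symptom_sum_difference(cfg, 1)
        assert abs(est - truth) <= 2 * se

    def test_invariant_to_relabeling_and_row_order(self, cohort_scores):
        fit_a = fit_lmm(cohort_scores, LmmSpec())
        scrambled = cohort_scores.sample(frac=1.0, random_state=2).copy()
        scrambled["participant_id"] = "zz_" + scrambled["participant_id"]
        fit_b = fit_lmm(scrambled, LmmSpec())
        assert np.abs(fit_a.beta.to_numpy() - fit_b.beta.to_numpy()).max() < 1e-6

    def test_too_few_participants_raise(self, cohort_scores):
        one = cohort_scores[cohort_scores["participant_id"] == "case-0001"]
        with pytest.raises(EstimationError):
            fit_lmm(one, LmmSpec())


class TestWald:
    def test_one_df_chi2_is_squared_z(self, cohort_scores):
        fit = fit_lmm(cohort_scores, LmmSpec())
        c = _group_diff_row(fit, 2)
        chi2, df, p = wald_chi2(fit, c)
        est = float(c @ fit.beta.to_numpy())
        se = float(np.sqrt(c @ fit.vcov_beta.to_numpy() @ c))
        assert chi2 == pytest.approx((est / se) ** 2)
        assert df == 1

    def test_zero_contrast_is_trivial(self, cohort_scores):
        fit = fit_lmm(cohort_scores, LmmSpec())
        chi2, df, p = wald_chi2(fit, np.zeros(len(fit.beta)))
        assert chi2 == 0.0 and p == 1.0

    def test_four_families_emitted_with_holm(self, cohort_scores):
        fit = fit_lmm(cohort_scores, LmmSpec())
        results = wald_tests(fit)
        by_family = {f: [r for r in results if r.family == f] for f in (1, 2, 3, 4)}
        assert len(by_family[1]) == 1 and by_family[1][0].p_holm is None
        assert len(by_family[2]) == 1
        assert len(by_family[3]) == 4
        assert len(by_family[4]) == 3
        for fam in (3, 4):
            for r in by_family[fam]:
                assert r.p_holm is not None and r.p_holm >= r.p - 1e-15

    def test_holm_hand_example(self):
        adjusted = holm([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.03, 0.04, 0.04])

    def test_strong_group_effect_detected(self, cohort_scores):
        fit = fit_lmm(cohort_scores, LmmSpec())
        overall = wald_tests(fit)[0]
        assert overall.label == "group_overall"
        assert overall.p < 1e-6


class TestStructureSelection:
    def test_intercept_only_data_selects_intercept(self, cohort_scores):
        spec = select_random_structure(cohort_scores)
        assert spec.random_structure is RandomStructure.intercept

    def test_strong_random_slopes_retained(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(80):
            u = rng.normal(0, 1)
            slope = rng.normal(0, 2.0)
            group = "case" if i < 40 else "control"
            for year in range(1, 5):
                rows.append(dict(
                    participant_id=f"p{i:03d}", group=group, school_year=year,
                    integrated=(1.0 * (group == "case") + u
                                + slope * (year - 1) + rng.normal(0, 1)),
                ))
        spec = select_random_structure(pd.DataFrame(rows))
        assert spec.random_structure is not RandomStructure.intercept

    def test_single_year_per_participant_unidentifiable(self, cohort_scores):
        one_year = cohort_scores[cohort_scores["school_year"] == 1]
        with pytest.raises(EstimationError, match="unidentifiable"):
            select_random_structure(one_year)

    def test_two_years_cannot_support_slopes(self, cohort_scores):
        two = cohort_scores[cohort_scores["school_year"].isin([1, 2])]
        spec = select_random_structure(two)
        assert spec.random_structure is RandomStructure.intercept
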