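"""ROC/AUC, DeLong and cutpoint search against exhaustive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from retroscore.diagnostics import (
    auc_mann_whitney,
    delong_compare,
    optimal_cutpoint,
    roc,
)
from retroscore.errors import (
    DegenerateInputError,
    InfeasibleConstraintError,
    UndefinedStatisticError,
)
from retroscore.scoring import Direction


def pair_counting_auc(scores, case_mask):
    """All-pairs concordance with ties counted 1/2 (independent oracle)."""
    x = scores[case_mask]
    y = scores[~case_mask]
    wins = (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    return wins / (len(x) * len(y))


def brute_force_cutpoints(scores, case_mask):
    """Every midpoint threshold with its sensitivity/specificity."""
    distinct = np.unique(scores)
    rows = []
    for t in (distinct[:-1] + distinct[1:]) / 2:
        pos = scores > t
        rows.append((t, pos[case_mask].mean(), (~pos)[~case_mask].mean()))
    return rows


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0, 1, 2, 10, 11, 12], dtype=float)
        labels = np.array([False] * 3 + [True] * 3)
        curve = roc(scores, labels)
        assert curve.auc == 1.0
        assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=3000)
        labels = rng.random(3000) < 0.5
        assert auc_mann_whitney(scores, labels) == pytest.approx(0.5, abs=0.04)

    def test_six_vs_six_with_cross_class_tie(self):
        scores = np.array([1, 2, 3, 4, 5, 5, 5, 6, 7, 8, 9, 10], dtype=float)
        labels = np.array([False] * 6 + [True] * 6)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels)
        )

    def test_matches_reference_auc_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = rng.integers(8, 40)
            scores = rng.integers(0, 6, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            ours = auc_mann_whitney(scores, labels)
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    @given(st.lists(st.floats(-5, 5).map(lambda v: round(v, 3)),
                    min_size=6, max_size=30),
           st.floats(0.1, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, raw, slope):
        # quantized scores keep exp() strictly monotone in double precision
        scores = np.asarray(raw)
        labels = np.arange(len(scores)) % 2 == 0
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(np.exp(slope * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_negated_scores_flipped_orientation_same_curve(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        hi = roc(scores, labels, Direction.higher_indicates_case)
        lo = roc(-scores, labels, Direction.lower_indicates_case)
        assert hi.auc == pytest.approx(lo.auc)
        a = sorted(zip(hi.sensitivity, hi.specificity))
        b = sorted(zip(lo.sensitivity, lo.specificity))
        assert np.allclose(a, b)

    def test_sensitivity_monotone_against_specificity(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60) + np.repeat([0, 1], 30)
        labels = np.repeat([False, True], 30)
        curve = roc(scores, labels)
        order = np.argsort(curve.specificity, kind="stable")
        sens_sorted = curve.sensitivity[order]
        assert (np.diff(sens_sorted) <= 1e-12).all()

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            roc([1.0, 2.0], [True, True])


class TestOptimalCutpoint:
    def test_perfect_separation(self):
        scores = np.array([0, 1, 2, 10, 11, 12], dtype=float)
        labels = np.array([False] * 3 + [True] * 3)
        result = optimal_cutpoint(scores, labels)
        assert result.sensitivity == result.specificity == 1.0
        assert result.youden == pytest.approx(1.0)

    def test_youden_identity_always_holds(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            scores = rng.integers(0, 8, 30).astype(float)
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any() or np.unique(scores).size < 2:
                continue
            r = optimal_cutpoint(scores, labels)
            assert r.youden == pytest.approx(r.sensitivity + r.specificity - 1)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            scores = rng.normal(size=20).round(1)
            labels = rng.random(20) < 0.5
            if labels.all() or not labels.any() or np.unique(scores).size < 2:
                continue
            r = optimal_cutpoint(scores, labels)
            best_j = max(se + sp - 1 for _, se, sp in
                         brute_force_cutpoints(scores, labels))
            assert r.youden == pytest.approx(best_j)

    def test_constrained_objective_respects_floor(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.repeat([False, True], 50)
        r = optimal_cutpoint(scores, labels, objective="max_sens_at_spec",
                             min_specificity=0.9)
        assert r.specificity >= 0.9
        feasible = [se for _, se, sp in brute_force_cutpoints(scores, labels)
                    if sp >= 0.9]
        assert r.sensitivity == pytest.approx(max(feasible))

    def test_infeasible_constraint_raises(self):
        scores = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array([False, True, False, True])
        # the single midpoint 0.5 has specificity 0.5 < 0.99
        with pytest.raises(InfeasibleConstraintError):
            optimal_cutpoint(scores, labels, objective="max_sens_at_spec",
                             min_specificity=0.99)

    def test_tie_break_prefers_higher_specificity(self):
        # thresholds 1.5 and 2.5 both give J = 0.5; 2.5 has spec 1.0
        scores = np.array([1.0, 2.0, 2.0, 3.0])
        labels = np.array([False, False, True, True])
        r = optimal_cutpoint(scores, labels)
        assert r.threshold == pytest.approx(2.5)
        assert r.specificity == 1.0


class TestDeLong:
    def test_identical_scores_z_zero_p_one(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        cmp = delong_compare(scores, scores, labels)
        assert cmp.z == 0.0 and cmp.p_two_sided == 1.0

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(2)
        n = 30
        labels = np.repeat([True, False], n)
        a = rng.normal(size=2 * n) + labels
        b = rng.normal(size=2 * n) + 0.3 * labels
        ab = delong_compare(a, b, labels)
        ba = delong_compare(b, a, labels)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p_two_sided == pytest.approx(ba.p_two_sided)

    def test_variance_matches_stratified_bootstrap(self):
        rng = np.random.default_rng(0)
        n = 30
        labels = np.array(["case"] * n + ["control"] * n)
        case = labels == "case"
        sa = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
        sb = 0.5 * sa + rng.normal(0, 1, 2 * n)
        cmp = delong_compare(sa, sb, labels)
        delong_var = ((cmp.auc_a - cmp.auc_b) / cmp.z) ** 2

        brng = np.random.default_rng(1)
        diffs = []
        for _ in range(2000):
            ic = brng.choice(np.where(case)[0], n, replace=True)
            ictl = brng.choice(np.where(~case)[0], n, replace=True)
            idx = np.concatenate([ic, ictl])
            diffs.append(auc_mann_whitney(sa[idx], labels[idx])
                         - auc_mann_whitney(sb[idx], labels[idx]))
        boot_var = np.var(diffs, ddof=1)
        assert abs(delong_var - boot_var) / boot_var < 0.15

    def test_degenerate_identical_aucs_at_one(self):
        # different score vectors, both separating perfectly: variance 0
        labels = np.array([True] * 3 + [False] * 3)
        a = np.array([10, 11, 12, 0, 1, 2], dtype=float)
        b = np.array([20, 21, 22, 3, 4, 5], dtype=float)
        with pytest.raises(UndefinedStatisticError):
            delong_compare(a, b, labels)
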