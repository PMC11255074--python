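import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from normmap import (
    ConfusionCounts,
    RatingRecord,
    cochrans_q,
    cohens_kappa,
    confusion,
    diagnose,
    diagnostic_metrics,
    icc_two_way,
    mcnemar_exact,
    mcnemar_pairwise,
)
from normmap.errors import NormMapError
from normmap.readerstats import icc_variant


def rating(left, right, sid="s", reader="r1", cohort="HCP-A"):
    return RatingRecord(subject_id=sid, reader_id=reader, cohort_used=cohort,
                        score_left=left, score_right=right)


class TestDiagnose:
    @pytest.mark.parametrize(
        "left,right,expected",
        [(0, 0, False), (2, 0, True), (0, 2, True), (1, 1, False),
         (3, 3, True), (1, 2, True)],
    )
    def test_max_rule(self, left, right, expected):
        assert diagnose(rating(left, right)) is expected

    def test_both_rule_requires_two_hemispheres(self):
        assert diagnose(rating(2, 0), rule="both") is False
        assert diagnose(rating(2, 2), rule="both") is True

    def test_sum_rule(self):
        assert diagnose(rating(1, 1), rule="sum") is True
        assert diagnose(rating(1, 0), rule="sum") is False

    def test_score_range_enforced(self):
        with pytest.raises(NormMapError):
            rating(4, 0)


class TestConfusion:
    def test_all_correct_case_control(self):
        truth = [True] * 21 + [False] * 21
        c = confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (21, 21, 0, 0)

    def test_inversion_swaps_counts(self, rng):
        truth = rng.random(50) < 0.5
        pred = rng.random(50) < 0.5
        c = confusion(pred, truth)
        ci = confusion(~pred, truth)
        assert (ci.tp, ci.fn) == (c.fn, c.tp)
        assert (ci.tn, ci.fp) == (c.fp, c.tn)

    def test_brute_force_tally(self, rng):
        truth = rng.random(200) < 0.4
        pred = rng.random(200) < 0.6
        c = confusion(pred, truth)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, truth):
            key = ("t" if p == t else "f") + ("p" if p else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"]
        )
        assert c.total == 200

    def test_length_mismatch(self):
        with pytest.raises(NormMapError):
            confusion([True], [True, False])


class TestDiagnosticMetrics:
    def test_high_sensitivity_cohort_row(self):
        m = diagnostic_metrics(ConfusionCounts(tp=16, fn=5, fp=0, tn=21))
        assert m == {"accuracy": 88, "sensitivity": 76, "specificity": 100,
                     "ppv": 100, "npv": 81}

    def test_row_with_one_false_positive(self):
        m = diagnostic_metrics(ConfusionCounts(tp=15, fn=6, fp=1, tn=20))
        assert m == {"accuracy": 83, "sensitivity": 71, "specificity": 95,
                     "ppv": 94, "npv": 77}

    def test_undefined_ppv_reported_absent(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert m["ppv"] is None
        assert m["specificity"] == 100

    def test_half_up_rounding(self):
        # 50.0% exactly -> 50; 62.5% -> 63 (half-up, not banker's)
        m = diagnostic_metrics(ConfusionCounts(tp=5, fn=3, fp=0, tn=0))
        assert m["sensitivity"] == 63

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40), st.integers(0, 40))
    def test_direct_ratio_oracle(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = diagnostic_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))

        def oracle(num, den):
            if den == 0:
                return None
            from decimal import ROUND_HALF_UP, Decimal
            ratio = Decimal(100 * num) / Decimal(den)
            return int(ratio.quantize(Decimal(1), rounding=ROUND_HALF_UP))

        assert m["accuracy"] == oracle(tp + tn, tp + fp + tn + fn)
        assert m["sensitivity"] == oracle(tp, tp + fn)
        assert m["specificity"] == oracle(tn, tn + fp)
        assert m["ppv"] == oracle(tp, tp + fp)
        assert m["npv"] == oracle(tn, tn + fn)


class TestCohensKappa:
    def test_perfect_agreement(self):
        labels = [0, 1, 2, 3, 0, 1, 2, 3]
        assert cohens_kappa(labels, labels) == pytest.approx(1.0)

    def test_worked_two_by_two(self):
        # table a=8, b=2 / c=2, d=8: p_o=0.8, p_e=0.5, kappa=0.6
        a = [0] * 10 + [1] * 10
        b = [0] * 8 + [1] * 2 + [0] * 2 + [1] * 8
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_perfect_disagreement(self):
        a = [0] * 10 + [1] * 10
        b = [1] * 10 + [0] * 10
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        a = rng.integers(0, 4, size=60)
        b = rng.integers(0, 4, size=60)
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_single_shared_category_undefined(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) is None


class TestICC:
    def test_identical_raters_give_one(self):
        scores = np.arange(10.0)
        mat = np.column_stack([scores, scores, scores])
        assert icc_two_way(mat) == pytest.approx(1.0)

    def test_pure_noise_raters_near_zero(self):
        rng = np.random.default_rng(4)
        subj = rng.normal(0, 1, size=200)
        mat = np.column_stack([
            subj + rng.normal(0, 10, 200), subj + rng.normal(0, 10, 200)
        ])
        assert icc_two_way(mat) < 0.2

    def test_anova_mean_squares_oracle(self):
        """ICC(2,1) from the explicit two-way ANOVA decomposition."""
        mat = np.array([
            [9.0, 2.0, 5.0],
            [6.0, 1.0, 3.0],
            [8.0, 4.0, 6.0],
            [7.0, 1.0, 2.0],
            [10.0, 5.0, 6.0],
            [6.0, 2.0, 4.0],
        ])
        n, k = mat.shape
        grand = mat.mean()
        ms_rows = k * ((mat.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((mat.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = (mat - mat.mean(axis=1, keepdims=True)
                 - mat.mean(axis=0, keepdims=True) + grand)
        ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
        oracle = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        assert icc_two_way(mat) == pytest.approx(oracle, rel=1e-8)

    def test_degenerate_constant_matrix_absent(self):
        assert icc_two_way(np.full((5, 3), 2.0)) is None

    def test_consistency_variant_selectable(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(20, 3)) + np.arange(3)  # rater offsets
        # consistency ICC ignores rater offsets, absolute agreement does not
        assert icc_variant(mat, "ICC3") > icc_variant(mat, "ICC2")


class TestCochransQ:
    def test_identical_columns(self):
        col = np.array([1, 0, 1, 1, 0])
        q, p = cochrans_q(np.column_stack([col, col, col]))
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_no_variation_at_all(self):
        q, p = cochrans_q(np.ones((6, 3), dtype=int))
        assert (q, p) == (0.0, 1.0)

    def test_k2_equals_uncorrected_mcnemar_chi_square(self, rng):
        a = rng.random(40) < 0.5
        b = rng.random(40) < 0.5
        q, _ = cochrans_q(np.column_stack([a, b]).astype(int))
        b01 = int((~a & b).sum())
        b10 = int((a & ~b).sum())
        chi2 = (b01 - b10) ** 2 / (b01 + b10)
        assert q == pytest.approx(chi2, rel=1e-10)

    def test_direct_formula_oracle(self, rng):
        mat = (rng.random((20, 4)) < 0.5).astype(int)
        q, p = cochrans_q(mat)
        k = mat.shape[1]
        col = mat.sum(axis=0)
        row = mat.sum(axis=1)
        n_total = mat.sum()
        q_oracle = (k - 1) * (k * (col**2).sum() - n_total**2) / (
            k * n_total - (row**2).sum()
        )
        assert q == pytest.approx(q_oracle, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(q_oracle, k - 1), rel=1e-9)


class TestMcNemar:
    def test_symmetric_discordants_give_one(self):
        a = np.array([True] * 3 + [False] * 3 + [True] * 4)
        b = np.array([False] * 3 + [True] * 3 + [True] * 4)
        assert mcnemar_exact(a, b) == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        # 1 vs 5 discordant pairs: p = 2 * P(X <= 1 | n=6, p=1/2) = 0.21875
        a = np.array([True] * 5 + [False] * 1 + [True] * 4)
        b = np.array([False] * 5 + [True] * 1 + [True] * 4)
        assert mcnemar_exact(a, b) == pytest.approx(0.21875, abs=1e-12)

    def test_no_discordants(self):
        a = np.array([True, False, True])
        assert mcnemar_exact(a, a) == 1.0

    def test_bonferroni_arithmetic(self, rng):
        mat = (rng.random((30, 4)) < 0.5).astype(int)
        results = mcnemar_pairwise(mat)
        assert len(results) == 6
        for _, _, p_raw, p_adj in results:
            assert 0.0 <= p_raw <= 1.0
            assert p_adj == pytest.approx(min(1.0, p_raw * 6))
            assert p_adj >= p_raw
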