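import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nvafsurv.stats import (EXACT_TEST_CUTOFF, cohens_kappa,
                            compare_concordance, compare_predictive_values,
                            discordant_counts, exact_binomial_test, f_score,
                            icc_two_way_random, mcnemar_test,
                            ordinal_concordance, paired_confusion,
                            paired_proportion_test,
                            permute_predictive_value_test)
from nvafsurv.stats import TestMethod as Method


class TestFScore:
    def test_combined_surveillance_value(self):
        assert round(f_score(1.0, 0.93), 3) == 0.964

    def test_structured_pair_interval_contains_published_value(self):
        """The printed 2-d.p. (sensitivity, PPV) pair determines F only to
        ~2 d.p.; the exact F interval over the rounding neighbourhood of
        (0.54, 0.95) must contain the published 0.686 and the point value
        must agree at the supported precision."""
        point = f_score(0.54, 0.95)
        assert round(point, 2) == round(0.686, 2) == 0.69
        lo = f_score(0.535, 0.945)
        hi = f_score(0.545, 0.955)
        assert lo <= 0.686 <= hi

    def test_underlying_count_table_reproduces_published_f(self):
        """The confusion table consistent with the published review-sample
        metrics (n=300, 264 true cases) yields F = 0.686 / 0.964 at 3 d.p."""
        structured = paired_confusion(
            [True] * 264 + [False] * 36,
            [True] * 142 + [False] * 122 + [True] * 8 + [False] * 28)
        combined = paired_confusion(
            [True] * 264 + [False] * 36,
            [True] * 264 + [True] * 20 + [False] * 16)
        assert round(structured.sensitivity, 2) == 0.54
        assert round(structured.ppv, 2) == 0.95
        assert round(structured.f_score, 3) == 0.686
        assert round(combined.ppv, 2) == 0.93
        assert round(combined.f_score, 3) == 0.964

    def test_perfect_classifier(self):
        m = paired_confusion([1, 0, 1], [1, 0, 1])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            paired_confusion([], [])

    def test_ordinal_threshold(self):
        m = paired_confusion([0, 2, 5, 1], [3, 2, 0, 0], threshold=2)
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 1, 1)


class TestMcNemar:
    def test_balanced_discordance(self):
        r = mcnemar_test(10, 10)
        assert r.statistic == 0 and r.p_value == 1

    @pytest.mark.parametrize("b,expected", [(72, 72.0), (16, 16.0)])
    def test_one_directional_reduces_to_b(self, b, expected):
        assert mcnemar_test(b, 0).statistic == expected

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm
        r = mcnemar_test(13, 5)
        ref = sm([[0, 13], [5, 0]], exact=False, correction=False)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_continuity_correction_toggle(self):
        assert mcnemar_test(13, 5, continuity_correction=True).statistic == \
            pytest.approx((abs(13 - 5) - 1) ** 2 / 18)

    def test_no_discordance_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(0, 0)


class TestExactBinomial:
    def test_single_discordant(self):
        assert exact_binomial_test(1, 0).p_value == 1.0

    def test_eight_zero(self):
        assert exact_binomial_test(8, 0).p_value == pytest.approx(2 * 0.5 ** 8)

    def test_symmetric_capped(self):
        assert exact_binomial_test(7, 7).p_value == 1.0

    def test_degenerate_flagged(self):
        r = exact_binomial_test(0, 0)
        assert r.p_value == 1.0 and r.degenerate

    def test_agrees_with_exhaustive_pmf_enumeration(self):
        """Doubled-tail p equals direct enumeration of the binomial pmf for
        every split with b + c <= 20."""
        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                k = min(b, c)
                tail = sum(sps.binom.pmf(i, n, 0.5) for i in range(k + 1))
                expected = min(1.0, 2.0 * tail)
                assert exact_binomial_test(b, c).p_value == \
                    pytest.approx(expected, abs=1e-12)

    def test_switch_rule(self):
        assert paired_proportion_test(5, 3).method is \
            Method.EXACT_BINOMIAL
        assert paired_proportion_test(40, 20).method is Method.MCNEMAR
        assert EXACT_TEST_CUTOFF == 25


class TestDiscordantCounts:
    def test_sensitivity_direction(self):
        g = [1, 1, 1, 0]
        t1 = [1, 0, 0, 0]
        t2 = [1, 1, 0, 1]
        assert discordant_counts(g, t1, t2, "positive") == (1, 0)
        assert discordant_counts(g, t1, t2, "negative") == (0, 1)


class TestGeneralizedScore:
    def build_example(self):
        # 60 subjects; test2 finds 10 extra true positives, no extra FPs
        g = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        t1 = np.zeros(60, bool)
        t2 = np.zeros(60, bool)
        t1[:15] = True
        t2[:25] = True
        t1[30:32] = t2[30:32] = True
        return g, t1, t2

    def test_identical_tests_null(self):
        g, t1, _ = self.build_example()
        ppv, npv = compare_predictive_values(g, t1, t1)
        assert ppv.statistic == 0 and ppv.p_value == 1
        assert npv.statistic == 0 and npv.p_value == 1

    def test_extra_true_positives_improve_npv(self):
        g, t1, t2 = self.build_example()
        ppv, npv = compare_predictive_values(g, t1, t2)
        assert npv.statistic > 0 and npv.p_value < 0.05
        assert ppv.statistic >= 0

    def test_subject_order_invariance(self):
        g, t1, t2 = self.build_example()
        perm = np.random.default_rng(0).permutation(g.size)
        a = compare_predictive_values(g, t1, t2)
        b = compare_predictive_values(g[perm], t1[perm], t2[perm])
        assert a[0].statistic == pytest.approx(b[0].statistic)
        assert a[1].statistic == pytest.approx(b[1].statistic)

    def test_no_positive_subject_rejected(self):
        g = np.zeros(5, bool)
        with pytest.raises(ValueError, match="PPV"):
            compare_predictive_values(g, g, g)

    def test_agrees_with_permutation_oracle(self):
        """Analytic chi-square p matches the within-subject label-swap
        permutation distribution (exchangeable construction: equal
        positivity) within Monte-Carlo plus asymptotic slack."""
        g = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        t1 = np.zeros(80, bool)
        t2 = np.zeros(80, bool)
        t1[:20] = True
        t1[40:50] = True
        t2[:16] = True
        t2[20:28] = True
        t2[40:46] = True
        ppv, npv = compare_predictive_values(g, t1, t2)
        p_perm = permute_predictive_value_test(g, t1, t2, "ppv",
                                               n_perm=4000, seed=2)
        assert abs(ppv.p_value - p_perm) < 0.015
        p_perm_n = permute_predictive_value_test(g, t1, t2, "npv",
                                                 n_perm=4000, seed=2)
        assert abs(npv.p_value - p_perm_n) < 0.015


class TestCohensKappa:
    def test_perfect_agreement(self):
        r = cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0], n_boot=50, seed=0)
        assert r.estimate == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        r = cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0], n_boot=50, seed=0)
        assert r.estimate == pytest.approx(0.0, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(123)
        a = rng.random(10000) < 0.5
        b = rng.random(10000) < 0.5
        r = cohens_kappa(a, b, n_boot=100, seed=1)
        assert abs(r.estimate) < 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 80)
        b = (a ^ (rng.random(80) < 0.3)).astype(int)
        r = cohens_kappa(a, b, n_boot=50, seed=0)
        assert r.estimate == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_marginals_flagged(self):
        r = cohens_kappa([1, 1, 1], [1, 1, 1], n_boot=20, seed=0)
        assert r.degenerate

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 60)
        b = rng.integers(0, 2, 60)
        r1 = cohens_kappa(a, b, n_boot=300, seed=9)
        r2 = cohens_kappa(a, b, n_boot=300, seed=9)
        assert r1.ci == r2.ci
        assert r1.ci[0] <= r1.estimate <= r1.ci[1]


class TestIcc:
    def test_identical_raters(self):
        x = np.arange(10, dtype=float)
        r = icc_two_way_random(np.column_stack([x, x]), n_boot=50, seed=0)
        assert r.estimate == pytest.approx(1.0)

    def test_variance_ratio_recovered(self):
        """Subject variance 4, error variance 1 -> ICC near 0.8."""
        rng = np.random.default_rng(77)
        subj = rng.normal(0, 2.0, 500)
        ratings = subj[:, None] + rng.normal(0, 1.0, (500, 3))
        r = icc_two_way_random(ratings, n_boot=50, seed=0)
        assert abs(r.estimate - 0.8) < 0.05

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(40, 2))
        perm = rng.permutation(40)
        a = icc_two_way_random(m, n_boot=10, seed=0).estimate
        b = icc_two_way_random(m[perm], n_boot=10, seed=0).estimate
        assert a == pytest.approx(b)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(11)
        m = rng.normal(size=(30, 3)) + rng.normal(size=(30, 1))
        df = pd.DataFrame(m).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        ref = pg.intraclass_corr(df, targets="index", raters="rater",
                                 ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        r = icc_two_way_random(m, n_boot=10, seed=0)
        assert r.estimate == pytest.approx(icc2, abs=1e-9)

    def test_zero_between_subject_variance_flagged(self):
        m = np.ones((6, 3))
        r = icc_two_way_random(m, n_boot=10, seed=0)
        assert r.estimate == 0.0 and r.degenerate


def brute_force_concordance(pred, gold):
    conc = disc = ties = total = 0
    n = len(pred)
    for i in range(n):
        for j in range(i + 1, n):
            if gold[i] == gold[j]:
                continue
            total += 1
            d = (pred[i] - pred[j]) * (gold[i] - gold[j])
            if d > 0:
                conc += 1
            elif d < 0:
                disc += 1
            else:
                ties += 1
    return (conc + 0.5 * ties) / total


class TestOrdinalConcordance:
    def test_perfect_predictor(self):
        r = ordinal_concordance([0, 1, 2, 3], [0, 1, 2, 3])
        assert r.c_index == 1 and r.somers_d == 1

    def test_constant_predictor(self):
        r = ordinal_concordance([2, 2, 2, 2], [0, 1, 2, 3])
        assert r.c_index == 0.5 and r.somers_d == 0

    def test_frozen_brute_force_example(self):
        """pred (1,2,3,0) vs gold (0,1,2,3): enumeration gives 3 concordant,
        3 discordant of 6 usable pairs -> C = 0.5."""
        assert brute_force_concordance([1, 2, 3, 0], [0, 1, 2, 3]) == 0.5
        r = ordinal_concordance([1, 2, 3, 0], [0, 1, 2, 3])
        assert r.c_index == pytest.approx(0.5)

    def test_all_gold_equal_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ordinal_concordance([1, 2, 3], [4, 4, 4])

    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)),
                    min_size=3, max_size=25))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_identity_and_oracle(self, pairs):
        pred = [p for p, _ in pairs]
        gold = [g for _, g in pairs]
        if len(set(gold)) < 2:
            return
        r = ordinal_concordance(pred, gold)
        assert r.somers_d == pytest.approx(2 * r.c_index - 1, abs=1e-12)
        assert r.c_index == pytest.approx(
            brute_force_concordance(pred, gold))

    @pytest.mark.parametrize("c,d", [(0.914, 0.829), (0.863, 0.726),
                                     (0.816, 0.633), (0.797, 0.595)])
    def test_published_c_d_pairs_satisfy_identity(self, c, d):
        assert abs((2 * c - 1) - d) <= 0.001 + 1e-12


class TestCompareConcordance:
    def test_identical_predictors(self):
        r = compare_concordance([1, 2, 3], [1, 2, 3], [0, 1, 2])
        assert r.z == 0 and r.p_value == 1

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        gold = rng.integers(0, 9, 60)
        p1 = gold + rng.integers(-1, 2, 60)
        p2 = rng.integers(0, 9, 60)
        a = compare_concordance(p1, p2, gold)
        b = compare_concordance(p2, p1, gold)
        assert a.z == pytest.approx(-b.z)

    def test_signal_versus_degraded_predictor(self):
        """Noise-free predictor vs one with 30% of entries corrupted on 300
        subjects: directionally significant."""
        rng = np.random.default_rng(202)
        gold = rng.integers(0, 10, 300)
        p1 = gold.copy()
        p2 = gold.copy()
        bad = rng.random(300) < 0.3
        p2[bad] = rng.integers(0, 10, int(bad.sum()))
        r = compare_concordance(p1, p2, gold)
        assert r.z > 1.96 and r.p_value < 0.05
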