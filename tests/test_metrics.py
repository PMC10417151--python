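import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cvgwas.io import ValidationError
from cvgwas.metrics import (
    aggregate_ci,
    chi2_contingency,
    confusion_metrics,
    linear_shap,
    mwu_tie_corrected,
    roc_auc,
)

from _oracles import auc_pair_counting, chi2_2xk_oracle, mwu_exact_permutation_p

# Printed cohort-table inputs: per-category counts for affected vs
# non-affected patients (treatment cycles ordered 3 < 4 < 5+ < high-dose)
CYCLES_AFFECTED = [30, 85, 9, 22]
CYCLES_NON_AFFECTED = [86, 180, 10, 2]
HISTOLOGY_TABLE = [[34, 112], [54, 224]]  # rows affected/non-affected


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 0, 0, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        s = np.round(rng.random(8), 1)  # coarse grid forces ties
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        assert roc_auc(s, y) == pytest.approx(auc_pair_counting(s, y), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        s = rng.random(30)
        y = (rng.random(30) < 0.4).astype(int)
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=40))
    def test_invariant_under_monotone_transform(self, vals):
        s = np.asarray(vals)
        y = (np.arange(s.size) % 2).astype(int)
        assert roc_auc(3.0 * s, y) == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics([0.9, 0.8, 0.1], [1, 1, 0])
        assert m["sensitivity"] == 1 and m["specificity"] == 1 and m["mcc"] == 1

    def test_hand_counted_fixture(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.3, 0.2, 0.1]
        labels = [1, 1, 0, 0, 0, 0, 1]  # TP=2 FP=2 TN=2 FN=1
        m = confusion_metrics(scores, labels)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["ppv"] == pytest.approx(0.5)
        assert m["npv"] == pytest.approx(2 / 3)

    def test_complement_identities(self):
        rng = np.random.default_rng(4)
        m = confusion_metrics(rng.random(50), (rng.random(50) < 0.4).astype(int))
        assert m["ppv"] + m["fdr"] == pytest.approx(1.0)
        assert m["npv"] + m["for"] == pytest.approx(1.0)
        assert -1 <= m["mcc"] <= 1


class TestAggregateCI:
    def test_constant_values_zero_width(self):
        m, (lo, hi) = aggregate_ci([0.7, 0.7, 0.7])
        assert m == pytest.approx(0.7)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_two_value_mean(self):
        m, _ = aggregate_ci([0.6, 0.8])
        assert m == pytest.approx(0.7)

    def test_close_to_bootstrap_percentile(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.73, 0.02, size=30)
        m1, ci1 = aggregate_ci(vals, method="normal")
        m2, ci2 = aggregate_ci(vals, method="bootstrap", seed=1)
        assert m1 == pytest.approx(m2)
        assert abs(ci1[0] - ci2[0]) < 0.01 and abs(ci1[1] - ci2[1]) < 0.01

    def test_single_value_errors(self):
        with pytest.raises(ValidationError):
            aggregate_ci([0.5])


class TestLinearShap:
    def test_zero_coefficient_zero_attribution(self):
        phi, _ = linear_shap([0.0, 1.0], 0.2, [[3.0, 4.0]], [1.0, 1.0])
        assert phi[0, 0] == 0.0

    def test_sample_at_background_gets_zero(self):
        phi, base = linear_shap([0.5, -1.0], 0.2, [[1.0, 2.0]], [1.0, 2.0])
        assert np.all(phi == 0.0)
        assert base == pytest.approx(0.2 + 0.5 - 2.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_additivity_reconstructs_log_odds(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 6))
        coef = rng.normal(size=p)
        X = rng.normal(size=(7, p))
        bg = rng.normal(size=p)
        b0 = float(rng.normal())
        phi, base = linear_shap(coef, b0, X, bg)
        np.testing.assert_allclose(base + phi.sum(axis=1), b0 + X @ coef, atol=1e-10)


class TestMannWhitney:
    def test_treatment_cycles_reproduce_printed_p(self):
        _, z, p = mwu_tie_corrected(CYCLES_AFFECTED, CYCLES_NON_AFFECTED)
        assert float(f"{p:.0e}") == pytest.approx(1e-5)  # one significant figure

    def test_identical_groups_z_zero(self):
        _, z, p = mwu_tie_corrected([5, 3, 2], [5, 3, 2])
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_approximation_close_to_exact_permutation(self):
        xa = [5, 1, 0, 5, 0]
        xb = [4, 1, 2, 3, 3]
        from cvgwas.metrics import mwu_from_samples

        _, _, p_approx = mwu_from_samples(xa, xb)
        p_exact = mwu_exact_permutation_p(xa, xb)
        assert abs(p_approx - p_exact) < 0.02

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(6)
        xa = rng.integers(0, 4, 25)
        xb = rng.integers(0, 5, 30)
        from cvgwas.metrics import mwu_from_samples

        u, _, p = mwu_from_samples(xa, xb)
        ref = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_z_squared_agrees_with_uncorrected_chi2_on_2x2(self):
        a, b = [12, 30], [25, 13]
        _, z, _ = mwu_tie_corrected(a, b)
        stat, _ = chi2_contingency([[12, 30], [25, 13]], continuity_correction=False)
        # binary-vs-binary MWU z^2 equals Pearson chi2 up to the (n-1)/n factor
        n = sum(a) + sum(b)
        assert z**2 == pytest.approx(stat * (n - 1) / n, abs=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            mwu_tie_corrected([0, 0], [1, 2])


class TestChi2:
    def test_histology_reproduces_printed_p(self):
        _, p = chi2_contingency(HISTOLOGY_TABLE)
        assert round(p, 2) == 0.42

    def test_proportional_table_is_null(self):
        stat, p = chi2_contingency([[10, 20], [30, 60]])
        assert p == pytest.approx(1.0) or stat == pytest.approx(0.0, abs=1e-10)

    def test_2x3_matches_direct_formula(self):
        table = [[8, 12, 5], [15, 9, 11]]
        stat, p = chi2_contingency(table)  # 2x3: no continuity correction applies
        ostat, op = chi2_2xk_oracle(table)
        assert stat == pytest.approx(ostat, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValidationError):
            chi2_contingency([[0, 0], [1, 2]])
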