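"""Two-sample t test, significance classification and comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proxitome import (
    Comparison,
    DesignSpec,
    ThresholdSpec,
    adjust_p,
    classify_significance,
    compare,
    student_t_test,
)
from proxitome.preprocess import IntensityMatrix

LOG2_CUTOFF_IN_LOG10 = 3 * math.log10(2)  # ~0.9031


def _matrix(values, design, log_base=10):
    frame = pd.DataFrame(values, index=[f"P{i}" for i in range(len(values))],
                         columns=list(design.samples.index))
    return IntensityMatrix(values=frame,
                           imputed=pd.DataFrame(False, index=frame.index, columns=frame.columns),
                           log_base=log_base, validity_filtered=True)


class TestStudentT:
    def test_worked_example(self):
        t, df, p = student_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=1e-4)

    def test_identical_groups_give_t0_p1(self):
        t, _, p = student_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=4), rng.normal(size=5)
        t1, _, p1 = student_t_test(a, b)
        t2, _, p2 = student_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_oracle_equivalence_random_instances(self):
        """Matches scipy's independent pooled-variance t test to |dp| < 1e-10."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            na, nb = rng.choice([3, 6]), 3
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 2), na)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 2), nb)
            t, df, p = student_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert abs(p - ref.pvalue) < 1e-10
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert df == na + nb - 2

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, _, p = student_t_test([1, 1, 1], [2, 2, 2])
        assert math.isinf(t) and t < 0
        assert 0 < p < 1e-300

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            student_t_test([1], [2, 3])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-100, 100), st.integers(0, 2**31 - 1))
    def test_location_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=3), rng.normal(size=3)
        t1, _, p1 = student_t_test(a, b)
        t2, _, p2 = student_t_test(a + shift, b + shift)
        assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize("d,p,expected", [
        (1.0, 0.001, "up"),            # 1.0 log10 units > 0.9031 cutoff
        (0.5, 1e-6, "not_significant"),  # effect too small despite tiny p
        (-1.2, 0.01, "down"),
        (1.0, 0.05, "not_significant"),  # p not strictly below 0.05
        (LOG2_CUTOFF_IN_LOG10, 0.001, "up"),  # boundary |d_log2| = 3 inclusive
    ])
    def test_rectangular_rule_log10_matrix(self, d, p, expected):
        assert classify_significance(d, p, ThresholdSpec(), log_base=10) == expected

    def test_grid_matches_brute_force_oracle(self):
        """200x200 (d, p) grid against an independently coded AND rule."""
        thr = ThresholdSpec()
        ds = np.linspace(-2, 2, 200)
        ps = np.linspace(1e-6, 1, 200)
        for d in ds:
            for p in ps:
                d_log2 = d / math.log10(2)
                if p < 0.05 and abs(d_log2) >= 3:
                    expected = "up" if d_log2 > 0 else "down"
                else:
                    expected = "not_significant"
                assert classify_significance(float(d), float(p), thr) == expected

    def test_matrix_units_mode(self):
        thr = ThresholdSpec(difference_units="matrix")
        assert classify_significance(1.0, 0.001, thr) == "not_significant"
        assert classify_significance(3.0, 0.001, thr) == "up"

    def test_hyperbolic_curve_tightens_near_cutoff(self):
        thr = ThresholdSpec(s0=0.5)
        # far beyond the cutoff the curve approaches the rectangular rule
        assert classify_significance(3.0, 0.01, thr) == "up"
        # just past the cutoff the required p is much smaller
        d_near = (3.0 + 0.01) * math.log10(2)
        assert classify_significance(d_near, 0.01, thr) == "not_significant"

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(1.0, 0.0)


class TestCompare:
    def test_null_type_one_error(self, design_3v3):
        rng = np.random.default_rng(5)
        values = rng.normal(7.5, 1.0, size=(1000, 6))
        result = compare(_matrix(values, design_3v3), design_3v3, ("bait", "control"))
        frac = (result["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_enriched_fixture_recovered(self, design_3v3):
        rng = np.random.default_rng(6)
        values = rng.normal(7.5, 0.1, size=(1000, 6))
        effect = 5 * math.log10(2)
        values[:50, :3] += effect
        result = compare(_matrix(values, design_3v3), design_3v3, ("bait", "control"))
        up = set(result.loc[result["class"] == "up", "protein"])
        assert up == {f"P{i}" for i in range(50)}
        assert result.attrs["summary"]["up"] == 50 and result.attrs["summary"]["down"] == 0

    def test_same_condition_all_zero(self, design_3v3):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(20, 6))
        result = compare(_matrix(values, design_3v3), design_3v3, ("bait", "bait"))
        assert np.allclose(result["difference"], 0)
        assert (result["class"] == "not_significant").all()

    def test_antisymmetry(self, design_3v3):
        rng = np.random.default_rng(8)
        values = rng.normal(7.5, 0.3, size=(100, 6))
        values[:10, :3] += 2
        values[10:20, 3:] += 2
        ab = compare(_matrix(values, design_3v3), design_3v3, ("bait", "control")).set_index("protein")
        ba = compare(_matrix(values, design_3v3), design_3v3, ("control", "bait")).set_index("protein")
        ba = ba.loc[ab.index]
        assert np.allclose(ab["difference"], -ba["difference"])
        assert np.allclose(ab["t"], -ba["t"])
        assert np.allclose(ab["p"], ba["p"])
        swap = {"up": "down", "down": "up", "not_significant": "not_significant"}
        assert (ab["class"].map(swap) == ba["class"]).all()

    def test_location_invariance_of_full_comparison(self, design_3v3):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(50, 6))
        r1 = compare(_matrix(values, design_3v3), design_3v3, ("bait", "control"))
        r2 = compare(_matrix(values + 5.0, design_3v3), design_3v3, ("bait", "control"))
        assert np.allclose(r1["t"], r2["t"])
        assert np.allclose(r1["p"], r2["p"])
        assert np.allclose(r1["difference"], r2["difference"])

    def test_sorted_by_significance_and_unknown_condition(self, design_3v3):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(30, 6))
        result = compare(_matrix(values, design_3v3), design_3v3, ("bait", "control"))
        assert (result["neg_log10_p"].diff().dropna() <= 1e-12).all()
        with pytest.raises(KeyError):
            compare(_matrix(values, design_3v3), design_3v3, ("bait", "nope"))

    def test_missing_values_rejected(self, design_3v3):
        values = np.full((2, 6), 7.0)
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            compare(_matrix(values, design_3v3), design_3v3, ("bait", "control"))

    def test_null_p_distribution_uniform(self, design_3v3):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(10_000, 6))
        result = compare(_matrix(values, design_3v3), design_3v3, ("bait", "control"))
        ks = stats.kstest(result["p"], "uniform")
        assert ks.pvalue > 0.01


class TestAdjustP:
    def test_none_returns_input_unchanged(self, design_3v3):
        rng = np.random.default_rng(12)
        result = compare(_matrix(rng.normal(size=(10, 6)), design_3v3), design_3v3, ("bait", "control"))
        assert adjust_p(result, "none") is result

    def test_bh_ladder_hand_computed(self):
        result = pd.DataFrame({"p": [0.01, 0.02, 0.03, 0.04], "class": ["up"] * 4})
        out = adjust_p(result, "benjamini_hochberg")
        assert np.allclose(out["q"], [0.04, 0.04, 0.04, 0.04])
        assert (out["class"] == "up").all()

    def test_single_p_unchanged_by_bh(self):
        out = adjust_p(pd.DataFrame({"p": [0.2]}), "benjamini_hochberg")
        assert out["q"].iloc[0] == pytest.approx(0.2)
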