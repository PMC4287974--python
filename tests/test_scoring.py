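import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sigrank.core_io import ExpressionMatrix, SignedSignature
from sigrank.scoring import (
    ScoreVector,
    calibrate_activity,
    dichotomize,
    pearson_with_p,
    score_signature,
    stratify_pten_p53,
)


def matrix_from(rows, genes, samples):
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))


class TestScoreSignature:
    def test_single_up_gene_equals_its_zscore(self, rng):
        vals = rng.normal(size=(1, 6))
        m = matrix_from(vals, ["g"], [f"s{i}" for i in range(6)])
        sv = score_signature(m, SignedSignature("s", {"g"}, set()))
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        np.testing.assert_allclose(sv.score, z)

    def test_flipping_sides_negates_scores(self, rng):
        m = matrix_from(rng.normal(size=(4, 5)), list("abcd"), [f"s{i}" for i in range(5)])
        sig = SignedSignature("s", {"a", "b"}, {"c", "d"})
        s1 = score_signature(m, sig)
        s2 = score_signature(m, sig.flipped())
        np.testing.assert_allclose(s1.score, -s2.score, atol=1e-12)

    def test_hand_computed_three_gene_matrix(self):
        rows = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],  # up gene
                [2.0, 2.0, 4.0, 4.0],  # up gene
                [5.0, 3.0, 1.0, 3.0],  # down gene
            ]
        )
        m = matrix_from(rows, ["u1", "u2", "d1"], ["s1", "s2", "s3", "s4"])
        sv = score_signature(m, SignedSignature("s", {"u1", "u2"}, {"d1"}))
        z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, ddof=1, keepdims=True)
        expected = z[:2].mean(axis=0) - z[2]
        np.testing.assert_allclose(sv.score, expected, atol=1e-12)

    def test_invariant_to_per_gene_affine_transform(self, rng):
        rows = rng.normal(size=(6, 8))
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(8)]
        sig = SignedSignature("s", {"g0", "g1"}, {"g2", "g3"})
        base = score_signature(matrix_from(rows, genes, samples), sig)
        scaled = rows * rng.uniform(0.5, 3, size=(6, 1)) + rng.normal(size=(6, 1))
        trans = score_signature(matrix_from(scaled, genes, samples), sig)
        np.testing.assert_allclose(base.score, trans.score, atol=1e-10)

    def test_absent_genes_skipped_and_all_absent_errors(self, rng):
        m = matrix_from(rng.normal(size=(2, 4)), ["a", "b"], list("wxyz"))
        sv = score_signature(m, SignedSignature("s", {"a", "nope"}, set()))
        assert len(sv) == 4
        with pytest.raises(ValueError, match="no gene"):
            score_signature(m, SignedSignature("s", {"nope"}, set()))


class TestDichotomize:
    def test_top_quantile_30_of_10_gives_3_positive(self):
        sv = ScoreVector([f"s{i}" for i in range(10)], np.arange(10.0))
        lab = dichotomize(sv, "top_quantile", q=0.30)
        assert lab.label.sum() == 3
        assert lab.label[np.argsort(sv.score)[-3:]].all()

    def test_all_equal_median_all_negative(self):
        sv = ScoreVector(list("abcd"), np.ones(4))
        assert dichotomize(sv, "median").label.sum() == 0

    def test_threshold_below_min_all_positive(self):
        sv = ScoreVector(list("abc"), np.array([1.0, 2.0, 3.0]))
        assert dichotomize(sv, "threshold", threshold=0.0).label.sum() == 3

    def test_ties_at_cut_go_negative(self):
        sv = ScoreVector(list("abcde"), np.array([1.0, 2.0, 3.0, 3.0, 3.0]))
        lab = dichotomize(sv, "top_quantile", q=0.40)
        # top 40% of 5 = 2 slots, but the boundary value 3.0 is tied across
        # three samples -> none of them can be cleanly in the top block
        assert lab.label.sum() == 0

    def test_invalid_quantile_rejected(self):
        sv = ScoreVector(list("ab"), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dichotomize(sv, "top_quantile", q=1.5)

    def test_median_split_is_balanced_for_even_distinct(self, rng):
        sv = ScoreVector([f"s{i}" for i in range(100)], rng.normal(size=100))
        assert dichotomize(sv, "median").label.sum() == 50


class TestCalibration:
    def test_reference_median_lands_exactly_on_target(self, rng):
        ref = rng.normal(2.0, 1.0, size=51)
        sv = ScoreVector([f"s{i}" for i in range(10)], rng.normal(size=10))
        shifted, params = calibrate_activity(sv, ref, target=0.15)
        assert np.median(ref + params.offset) == pytest.approx(0.15, abs=1e-14)

    def test_identity_when_already_calibrated(self):
        ref = np.array([0.1, 0.15, 0.2])
        sv = ScoreVector(list("ab"), np.array([1.0, 2.0]))
        shifted, params = calibrate_activity(sv, ref, target=0.15)
        assert params.offset == 0.0
        np.testing.assert_array_equal(shifted.score, sv.score)

    def test_ordering_preserved(self, rng):
        sv = ScoreVector([f"s{i}" for i in range(20)], rng.normal(size=20))
        shifted, _ = calibrate_activity(sv, rng.normal(size=11))
        np.testing.assert_array_equal(np.argsort(sv.score), np.argsort(shifted.score))

    def test_empty_reference_rejected(self):
        sv = ScoreVector(["a"], np.array([1.0]))
        with pytest.raises(ValueError, match="empty"):
            calibrate_activity(sv, [])

    def test_dichotomize_commutes_with_calibration(self, rng):
        # threshold split after a shift == shifted-threshold split before
        sv = ScoreVector([f"s{i}" for i in range(30)], rng.normal(size=30))
        shifted, params = calibrate_activity(sv, rng.normal(size=9), target=0.15)
        a = dichotomize(shifted, "threshold", threshold=0.15)
        b = dichotomize(sv, "threshold", threshold=0.15 - params.offset)
        np.testing.assert_array_equal(a.label, b.label)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_example(self):
        # x={1,2,3}, y={1,3,2}: cov=0.5, sd_x=1, sd_y=1 -> r=0.5
        r, p = pearson_with_p([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5, abs=1e-12)
        t = 0.5 * np.sqrt(1 / (1 - 0.25))
        assert p == pytest.approx(2 * stats.t.sf(t, 1), rel=1e-10)

    def test_type_i_error_rate(self, rng):
        rejections = sum(
            pearson_with_p(rng.normal(size=25), rng.normal(size=25))[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 < rejections / 400 < 0.09

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30).filter(lambda v: len(set(v)) > 1))
    def test_self_correlation_is_one(self, xs):
        r, _ = pearson_with_p(xs, xs)
        assert r == pytest.approx(1.0, abs=1e-6)


class TestStratify:
    def _vectors(self, pten, p53):
        ids = [f"s{i}" for i in range(len(pten))]
        return ScoreVector(ids, np.asarray(pten, float)), ScoreVector(ids, np.asarray(p53, float))

    def test_no_p53_low_when_all_above_reference(self, rng):
        pten, p53 = self._vectors(rng.normal(size=40), rng.uniform(0.2, 1.0, size=40))
        _, freqs = stratify_pten_p53(pten, p53)
        assert freqs["p53_low"] == 0.0

    def test_quartile_rule_forces_count(self, rng):
        pten, p53 = self._vectors(rng.normal(size=100), rng.normal(size=100))
        table, freqs = stratify_pten_p53(pten, p53, pten_low_quantile=0.25)
        assert table["pten_low"].sum() == 25

    def test_recovers_planted_joint_low_fraction(self):
        # bivariate-normal truth: P(pten in bottom 25% and p53 < its 65.6%
        # quantile) computed from the Gaussian copula is the planted value
        rho = 0.3
        n = 200_000
        rng = np.random.default_rng(42)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        q_p53 = stats.norm.ppf(0.656)
        expected = stats.multivariate_normal.cdf(
            [stats.norm.ppf(0.25), q_p53], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        pten, p53 = self._vectors(xy[:, 0], xy[:, 1] - q_p53 + 0.15)
        _, freqs = stratify_pten_p53(pten, p53, pten_low_quantile=0.25)
        assert freqs["p53_low"] == pytest.approx(0.656, abs=0.01)
        assert freqs["both_low"] == pytest.approx(expected, abs=0.01)

    def test_sample_mismatch_rejected(self, rng):
        a = ScoreVector(["x", "y", "z"], rng.normal(size=3))
        b = ScoreVector(["x", "y", "w"], rng.normal(size=3))
        with pytest.raises(ValueError, match="sample sets"):
            stratify_pten_p53(a, b)
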