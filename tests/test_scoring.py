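import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mirsig import (
    CohortSimSpec,
    ExpressionMatrix,
    PanelMember,
    SignaturePanel,
    SignatureValidator,
    auc_ci,
    auc_permutation_test,
    cohort_preprocess,
    default_panel,
    generate_human_cohort,
    optimal_threshold,
    roc_auc,
    signature_score,
    zscore_features,
)


def _counts(values, ids, samples):
    df = pd.DataFrame(np.asarray(values, dtype=np.int64), index=ids, columns=samples)
    return ExpressionMatrix(df, "raw_counts")


class TestPreprocess:
    def test_log_scale_returned_unchanged(self, tiny_matrix):
        mat, _ = tiny_matrix
        assert cohort_preprocess(mat) is mat

    def test_matches_hand_computed_cpm(self, rng):
        counts = rng.integers(0, 500, size=(6, 4))
        counts[0] += 10  # avoid zero library columns
        mat = _counts(counts, [f"f{i}" for i in range(6)], list("abcd"))
        out = cohort_preprocess(mat)
        lib = counts.sum(axis=0)
        expected = np.log2(counts / lib * 1e6 + 1)
        np.testing.assert_allclose(out.values, expected)
        assert out.scale == "log_intensity"

    def test_equal_counts_give_identical_columns(self):
        mat = _counts([[5, 5], [10, 10]], ["f1", "f2"], ["a", "b"])
        out = cohort_preprocess(mat)
        np.testing.assert_allclose(out.data["a"], out.data["b"])

    def test_zero_library_size_raises(self):
        mat = _counts([[0, 1]], ["f1"], ["a", "b"])
        with pytest.raises(ValueError, match="library"):
            cohort_preprocess(mat)


class TestZscore:
    def test_rows_have_mean_zero_sd_one(self, tiny_matrix):
        z = zscore_features(tiny_matrix[0])
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0)

    def test_constant_feature_becomes_zeros_with_warning(self):
        mat = ExpressionMatrix(
            pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]], index=["c", "v"],
                         columns=list("abc"))
        )
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_features(mat)
        np.testing.assert_allclose(z.loc["c"], 0.0)

    def test_idempotent(self, tiny_matrix):
        z1 = zscore_features(tiny_matrix[0])
        z2 = zscore_features(ExpressionMatrix(z1))
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_single_sample_raises(self):
        mat = ExpressionMatrix(pd.DataFrame([[1.0]], index=["f"], columns=["s"]))
        with pytest.raises(ValueError, match="2 samples"):
            zscore_features(mat)


class TestSignatureScore:
    def test_all_down_panel_with_z_minus_one(self):
        z = pd.DataFrame(
            -np.ones((2, 3)), index=["hsa-miR-a", "hsa-miR-b"], columns=list("xyz")
        )
        panel = SignaturePanel(
            [PanelMember("hsa-mir-a", "down"), PanelMember("hsa-mir-b", "down")]
        )
        scores, coverage = signature_score(z, panel)
        np.testing.assert_allclose(scores, 1.0)
        assert coverage == 1.0

    def test_mixed_directions_formula(self):
        z = pd.DataFrame(
            [[0.7], [-0.2]], index=["hsa-miR-d", "hsa-miR-u"], columns=["s"]
        )
        panel = SignaturePanel(
            [PanelMember("hsa-mir-d", "down"), PanelMember("hsa-mir-u", "up")]
        )
        scores, _ = signature_score(z, panel)
        assert scores["s"] == pytest.approx(-0.7 - (-0.2))

    def test_depressed_panel_in_pd_raises_pd_scores(self):
        spec = CohortSimSpec(n_pd=30, n_control=30, rng_seed=2)
        mat, ann = generate_human_cohort(spec, default_panel())
        z = zscore_features(cohort_preprocess(mat))
        scores, _ = signature_score(z, default_panel())
        pd_mean = scores[ann.index[ann["class"] == "PD"]].mean()
        ctrl_mean = scores[ann.index[ann["class"] == "Control"]].mean()
        assert pd_mean > ctrl_mean

    def test_invariant_to_constant_row_shift_pre_zscoring(self, rng):
        vals = rng.normal(size=(3, 8))
        ids = ["hsa-miR-a", "hsa-miR-b", "hsa-miR-c"]
        cols = [f"s{i}" for i in range(8)]
        panel = SignaturePanel([PanelMember("hsa-mir-a", "down"), PanelMember("hsa-mir-b", "up")])
        m1 = ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=cols))
        shifted = vals.copy()
        shifted[0] += 11.0
        m2 = ExpressionMatrix(pd.DataFrame(shifted, index=ids, columns=cols))
        s1, _ = signature_score(zscore_features(m1), panel)
        s2, _ = signature_score(zscore_features(m2), panel)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_duplicate_core_matches_are_averaged(self):
        z = pd.DataFrame(
            [[1.0], [3.0]], index=["hsa-miR-a-3p", "hsa-miR-a-5p"], columns=["s"]
        )
        panel = SignaturePanel([PanelMember("hsa-mir-a", "down")])
        scores, _ = signature_score(z, panel)
        assert scores["s"] == pytest.approx(-2.0)

    def test_partial_coverage_warns(self):
        z = pd.DataFrame([[1.0]], index=["hsa-miR-a"], columns=["s"])
        panel = SignaturePanel([PanelMember("hsa-mir-a", "down"), PanelMember("hsa-mir-x", "down")])
        with pytest.warns(UserWarning, match="coverage"):
            _, coverage = signature_score(z, panel)
        assert coverage == 0.5

    def test_no_match_raises(self):
        z = pd.DataFrame([[1.0]], index=["hsa-miR-a"], columns=["s"])
        panel = SignaturePanel([PanelMember("hsa-mir-x", "down")])
        with pytest.raises(ValueError, match="no panel member"):
            signature_score(z, panel)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, orient = roc_auc([2, 3, 0, 1], ["PD", "PD", "Control", "Control"])
        assert auc == 1.0 and orient == "as_scored"

    def test_complete_ties_give_half(self):
        auc, _ = roc_auc([0, 1, 0, 1], ["PD", "PD", "Control", "Control"])
        assert auc == 0.5

    def test_matches_all_pairs_counting_oracle(self, rng):
        for _ in range(100):
            n1, n0 = rng.integers(3, 12, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # induce ties
            y = np.array([1] * n1 + [0] * n0)
            wins = sum(
                1.0 if sp > sn else 0.5 if sp == sn else 0.0
                for sp in scores[y == 1]
                for sn in scores[y == 0]
            )
            expected = wins / (n1 * n0)
            auc, _ = roc_auc(scores, y)
            assert auc == pytest.approx(max(expected, 1 - expected))

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        auc, orient = roc_auc(scores, y)
        sk = roc_auc_score(y, scores)
        assert auc == pytest.approx(max(sk, 1 - sk))

    def test_orientation_complement_sums_to_one(self, rng):
        scores = rng.normal(size=30)
        y = np.array([1] * 12 + [0] * 18)
        from mirsig.scoring import _auc_pd_positive

        assert _auc_pd_positive(scores, y) + _auc_pd_positive(-scores, y) == pytest.approx(1.0)

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], ["PD", "PD"])


class TestAucCi:
    def test_bounds_contain_point_estimate(self, rng):
        for _ in range(10):
            scores = rng.normal(size=30)
            y = np.array([1] * 14 + [0] * 16)
            auc, _ = roc_auc(scores, y)
            lo, hi = auc_ci(scores, y, n_boot=300, rng=rng)
            assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_perfect_separation_upper_bound_is_one(self, rng):
        scores = np.r_[np.ones(25), np.zeros(25)]
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        lo, hi = auc_ci(scores, y, n_boot=300, rng=rng)
        assert hi == 1.0

    def test_small_n_boot_rejected(self, rng):
        with pytest.raises(ValueError):
            auc_ci([1, 0], [1, 0], n_boot=10, rng=rng)


class TestOptimalThreshold:
    def test_perfect_separation_sens_spec_one(self):
        thr, sens, spec = optimal_threshold([3, 4, 0, 1], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 1.0
        assert 1 < thr <= 3

    def test_maximizes_youden_against_brute_force(self, rng):
        for _ in range(100):
            scores = np.round(rng.normal(size=20), 1)
            y = rng.integers(0, 2, size=20)
            y[:2] = [0, 1]
            thr, sens, spec = optimal_threshold(scores, y)
            s = scores if roc_auc(scores, y)[1] == "as_scored" else -scores
            best_j = max(
                (s >= c)[y == 1].mean() + (s < c)[y == 0].mean() - 1
                for c in np.unique(s)
            )
            assert sens + spec - 1 == pytest.approx(best_j)

    def test_degenerate_identical_scores(self):
        thr, sens, spec = optimal_threshold([2, 2, 2, 2], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 0.0


class TestAucPermutation:
    def test_perfect_separation_hits_floor(self):
        # n=20+20: the only label permutations reproducing AUC=1 are the
        # identity and its complement, never drawn among 500 of C(40,20)
        scores = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        p = auc_permutation_test(scores, y, B=500, rng=0)
        assert p == pytest.approx(1 / 501)

    def test_add_one_always_at_least_literal(self, rng):
        for _ in range(20):
            scores = rng.normal(size=24)
            y = np.array([1] * 10 + [0] * 14)
            rng2 = np.random.default_rng(7)
            p1 = auc_permutation_test(scores, y, B=200, rng=np.random.default_rng(7))
            p2 = auc_permutation_test(
                scores, y, B=200, rng=np.random.default_rng(7), add_one=False
            )
            assert p1 >= p2


class TestSignatureValidator:
    def test_planted_cohort_end_to_end(self):
        spec = CohortSimSpec(n_pd=40, n_control=40, platform="exosome_counts", rng_seed=4)
        mat, ann = generate_human_cohort(spec, default_panel())
        res = SignatureValidator(mat, ann, default_panel(), cohort_id="test").fit(
            B=300, n_boot=300, rng=1
        )
        assert res.auc >= 0.7
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.perm_p < 0.05
        assert res.n_pd == 40 and res.n_control == 40
        assert "AUC" in res.summary()

    def test_null_cohort_is_unremarkable(self):
        spec = CohortSimSpec(n_pd=25, n_control=25, panel_effect_sd_units=0.0, rng_seed=8)
        mat, ann = generate_human_cohort(spec, default_panel())
        res = SignatureValidator(mat, ann, default_panel()).fit(B=300, n_boot=300, rng=1)
        assert res.auc < 0.7  # headline AUC is >= 0.5 by construction
        assert res.perm_p > 0.05
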