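import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    ExpressionMatrix,
    MouseSimSpec,
    StabilitySelection,
    build_panel,
    generate_mouse_experiment,
    loocv_elastic_net,
    selection_permutation_test,
    univariate_filter,
)
from mirsig._enet import fit_enet_logistic, lambda_max, standardize
from mirsig.selection import _two_sample_t


def _d0_data(spec):
    matrix, ann = generate_mouse_experiment(spec)
    d0 = ann.index[ann["time"] == "D0"]
    return matrix.subset_samples(d0), ann.loc[d0, "group"].to_numpy()


def _mat(values, ids, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples))


class TestUnivariateFilter:
    def _toy(self, rng):
        ids = [f"f{i:02d}" for i in range(30)]
        samples = [f"s{i}" for i in range(10)]
        vals = rng.normal(size=(30, 10))
        vals[7, 5:] += 5.0  # 5-SD separated feature
        labels = ["A"] * 5 + ["B"] * 5
        return _mat(vals, ids, samples), labels

    def test_separated_feature_ranks_first(self, rng):
        mat, labels = self._toy(rng)
        assert univariate_filter(mat, labels, 5)[0] == "f07"

    def test_k_equals_n_features_returns_all(self, rng):
        mat, labels = self._toy(rng)
        assert set(univariate_filter(mat, labels, 30)) == set(mat.feature_ids)

    def test_label_swap_leaves_ranking_invariant(self, rng):
        mat, labels = self._toy(rng)
        swapped = ["B" if l == "A" else "A" for l in labels]
        assert univariate_filter(mat, labels, 10) == univariate_filter(mat, swapped, 10)

    def test_zero_variance_feature_gets_t_zero(self):
        X = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 4.0]])
        t = _two_sample_t(X, np.array([0, 0, 1, 1]))
        assert t[0] == 0.0 and np.isfinite(t[1])

    def test_k_too_large_raises(self, rng):
        mat, labels = self._toy(rng)
        with pytest.raises(ValueError, match="k exceeds"):
            univariate_filter(mat, labels, 31)


class TestStabilitySelection:
    def test_recovers_planted_panel_with_modest_background(self, small_mouse_spec):
        # with 2-of-4 subsamples the same 8 day-0 samples are reused, so a
        # single realization caps how cleanly any procedure can separate
        # planted from background; most panel members must clear the
        # threshold while the typical background feature stays far below
        mat, labels = _d0_data(small_mouse_spec)
        res = StabilitySelection(mat, labels).fit(n_iterations=2000, rng=1)
        panel = res.pi_hat[list(small_mouse_spec.planted_panel)]
        background = res.pi_hat.drop(
            list(small_mouse_spec.planted_down) + list(small_mouse_spec.planted_up)
        )
        assert (panel >= 0.6).sum() >= 5
        assert panel.mean() > 0.6
        assert background.median() < 0.3

    def test_fixed_seed_is_bit_identical(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        r1 = StabilitySelection(mat, labels).fit(n_iterations=200, rng=3)
        r2 = StabilitySelection(mat, labels).fit(n_iterations=200, rng=3)
        assert r1.pi_hat.equals(r2.pi_hat)

    def test_chunking_does_not_change_results(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        r1 = StabilitySelection(mat, labels).fit(n_iterations=150, rng=3, chunk_size=7)
        r2 = StabilitySelection(mat, labels).fit(n_iterations=150, rng=3, chunk_size=150)
        assert r1.pi_hat.equals(r2.pi_hat)

    def test_sampled_pi_matches_exhaustive_36_subsample_enumeration(self, small_mouse_spec):
        # with 2-of-4 per class there are only C(4,2)^2 = 36 distinct
        # subsamples; 2000 sampled iterations must agree with the exact
        # equal-weight enumeration within Monte-Carlo error
        mat, labels = _d0_data(small_mouse_spec)
        res = StabilitySelection(mat, labels).fit(n_iterations=2000, rng=11)

        X = mat.values
        y01 = (np.asarray(labels) == sorted(set(labels))[1]).astype(int)
        idx0, idx1 = np.flatnonzero(y01 == 0), np.flatnonzero(y01 == 1)
        lexrank = np.argsort(np.argsort(np.asarray(mat.feature_ids, dtype=object)))
        counts = np.zeros(X.shape[0])
        y_sub = np.array([0.0, 0.0, 1.0, 1.0])
        n_combos = 0
        for c0 in combinations(idx0, 2):
            for c1 in combinations(idx1, 2):
                Xi = X[:, list(c0) + list(c1)]
                t = _two_sample_t(Xi, y_sub)
                top = np.lexsort((lexrank, -np.abs(t)))[:20]
                Xs, _, _, active = standardize(Xi[top].T)
                lam = 0.1 * lambda_max(Xs, y_sub, 0.5)
                coef, _ = fit_enet_logistic(Xs, y_sub, 0.5, lam)
                counts[top[np.abs(coef) > 1e-10]] += 1
                n_combos += 1
        exact_pi = counts / n_combos
        mc_se = np.sqrt(exact_pi * (1 - exact_pi) / 2000)
        assert np.all(np.abs(res.pi_hat.to_numpy() - exact_pi) <= 4 * mc_se + 0.01)

    def test_pure_noise_keeps_max_pi_below_threshold(self):
        # a large background is essential here: with few features one lucky
        # noise feature can dominate every subsample of the same 8 samples
        mat, labels = _d0_data(MouseSimSpec().null())
        res = StabilitySelection(mat, labels).fit(n_iterations=500, rng=5)
        assert res.pi_hat.max() < 0.6
        assert res.selected == []

    def test_zero_iterations_raise(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        with pytest.raises(ValueError, match="n_iterations"):
            StabilitySelection(mat, labels).fit(n_iterations=0)

    def test_bad_threshold_raises(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        with pytest.raises(ValueError, match="threshold"):
            StabilitySelection(mat, labels).fit(n_iterations=10, threshold=1.2)


class TestSelectionPermutationTest:
    def test_planted_signal_gives_small_p(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        obs = StabilitySelection(mat, labels).fit(n_iterations=400, rng=2)
        assert len(obs.selected) >= 4
        p = selection_permutation_test(mat, labels, obs, B=100, iter_per_perm=50, rng=9)
        assert p <= 0.05

    def test_empty_observed_selection_gives_p_one(self, small_mouse_spec):
        from mirsig.selection import StabilityResult

        mat, labels = _d0_data(small_mouse_spec.null())
        obs = StabilityResult(
            pi_hat=pd.Series(0.0, index=mat.feature_ids),
            n_iterations=200, n_effective=200, subsample_per_class=2,
            threshold=0.6, alpha=0.5, lambda_frac=0.1, filter_k=20,
        )
        assert obs.selected == []
        p = selection_permutation_test(mat, labels, obs, B=100, iter_per_perm=20, rng=9)
        assert p == 1.0


class TestBuildPanel:
    def _stability_with(self, pi, feature_ids):
        from mirsig.selection import StabilityResult

        return StabilityResult(
            pi_hat=pd.Series(pi, index=feature_ids),
            n_iterations=100, n_effective=100, subsample_per_class=2,
            threshold=0.6, alpha=0.5, lambda_frac=0.1, filter_k=20,
        )

    def test_directions_follow_logfc_signs(self):
        stab = self._stability_with([0.9, 0.8, 0.1], ["mmu-miR-a", "mmu-miR-b", "mmu-miR-c"])
        de = pd.DataFrame(
            {"logFC": [-2.0, 1.4, 0.0]}, index=["mmu-miR-a", "mmu-miR-b", "mmu-miR-c"]
        )
        panel = build_panel(stab, de)
        directions = {m.source_name: m.direction for m in panel.members}
        assert directions == {"mmu-miR-a": "down", "mmu-miR-b": "up"}

    def test_missing_de_record_raises(self):
        stab = self._stability_with([0.9], ["mmu-miR-a"])
        with pytest.raises(ValueError, match="missing"):
            build_panel(stab, pd.DataFrame({"logFC": []}))

    def test_empty_selection_warns_and_returns_empty_panel(self):
        stab = self._stability_with([0.1], ["mmu-miR-a"])
        with pytest.warns(UserWarning, match="empty"):
            panel = build_panel(stab, pd.DataFrame({"logFC": [1.0]}, index=["mmu-miR-a"]))
        assert len(panel) == 0


class TestLoocv:
    def test_separated_data_scores_high(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        report = loocv_elastic_net(mat, labels, rng=4)
        assert report.pooled_auc >= 0.9
        assert len(report.scores) == mat.shape[1]

    def test_no_leakage_fold_features_derive_from_training_only(self, small_mouse_spec):
        mat, labels = _d0_data(small_mouse_spec)
        report = loocv_elastic_net(mat, labels, rng=4)
        labels = np.asarray(labels)
        for fold in report.folds:
            held = fold["held_out"]
            train_ids = [s for s in mat.sample_ids if s != held]
            train_mask = np.array([s != held for s in mat.sample_ids])
            expected = univariate_filter(
                mat.subset_samples(train_ids), labels[train_mask], 20
            )
            assert fold["features"] == expected

    def test_too_few_samples_raise(self, rng):
        mat = _mat(rng.normal(size=(10, 4)), [f"f{i}" for i in range(10)], list("abcd"))
        with pytest.raises(ValueError, match="6 samples"):
            loocv_elastic_net(mat, ["A", "A", "B", "B"])
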