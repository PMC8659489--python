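"""Fold construction, classifiers, metrics and permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bradyflux.classify import (
    evaluate,
    fit_predict,
    make_individual_folds,
    permutation_significance,
    run_group_model,
    run_individual_model,
    significance_across_subjects,
    ModelResult,
)
from bradyflux.features import FEATURE_NAMES


def brute_force_auc(scores, labels):
    """Pair-counting Mann-Whitney AUC (ties worth one half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def subject_table(subject="S001", n=30, effect=2.0, seed=0):
    """Balanced standardized-style windows with a mean shift on half the
    features in the post state."""
    rng = np.random.default_rng(seed)
    rows = []
    for state in ("pre", "post"):
        for i in range(n):
            values = rng.normal(size=103)
            if state == "post":
                values[:50] += effect
            row = {"subject_id": subject, "state": state, "window_index": i}
            row.update(dict(zip(FEATURE_NAMES, values)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestFolds:
    def test_exactly_41_folds(self):
        assert len(make_individual_folds(30, 30)) == 41

    def test_fold_0_and_40_block_positions(self):
        n = 50
        folds = make_individual_folds(n, n)
        n_total = 2 * n
        first = folds[0]
        # percentiles [0, 10) and [50, 60) of the concatenated sequence
        assert first.test_idx.min() == 0
        pre_block = first.test_idx[first.test_idx < n]
        post_block = first.test_idx[first.test_idx >= n]
        assert pre_block.tolist() == list(range(0, n_total // 10))
        assert post_block.tolist() == list(range(n, n + n_total // 10))
        last = folds[40]
        assert last.test_idx.max() == n_total - 1
        assert (last.test_idx[last.test_idx < n]).tolist() == list(range(int(0.4 * n_total), n))

    def test_no_overlap_and_no_buffer_leak(self):
        for fold in make_individual_folds(40, 40):
            test = set(fold.test_idx.tolist())
            train = set(fold.train_idx.tolist())
            buffer = set(fold.buffer_idx.tolist())
            assert not (test & train)
            assert not (buffer & train)
            assert not (buffer & test)
            assert fold.test_idx.size > 0

    def test_union_of_test_blocks_covers_both_halves(self):
        n = 40
        folds = make_individual_folds(n, n)
        covered = set()
        for fold in folds:
            covered.update(fold.test_idx.tolist())
        assert covered == set(range(2 * n))

    def test_unbalanced_or_tiny_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_individual_folds(30, 25)
        with pytest.raises(ValueError):
            make_individual_folds(3, 3)


class TestFitPredict:
    def test_separable_clusters_perfect_auc(self, rng):
        x_pos = rng.normal(5, 0.2, size=(20, 103))
        x_neg = rng.normal(-5, 0.2, size=(20, 103))
        x = np.vstack([x_neg, x_pos])
        y = np.array([0] * 20 + [1] * 20)
        for kind in ("sv", "rf"):
            scores = fit_predict(x, y, x, kind, model_seed=0)
            auc, acc = evaluate(scores, y, kind)
            assert auc == 1.0
            assert acc == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(400, 103))
        y = rng.integers(0, 2, 400)
        x_test = rng.normal(size=(200, 103))
        y_test = rng.integers(0, 2, 200)
        scores = fit_predict(x, y, x_test, "sv", model_seed=0)
        auc, _ = evaluate(scores, y_test, "sv")
        assert 0.35 < auc < 0.65

    def test_single_class_training_rejected(self):
        x = np.zeros((10, 103))
        with pytest.raises(ValueError):
            fit_predict(x, np.zeros(10, dtype=int), x, "sv")

    def test_rf_deterministic_given_seed(self, rng):
        x = rng.normal(size=(60, 103))
        y = rng.integers(0, 2, 60)
        s1 = fit_predict(x, y, x, "rf", model_seed=7)
        s2 = fit_predict(x, y, x, "rf", model_seed=7)
        np.testing.assert_array_equal(s1, s2)


class TestEvaluate:
    def test_matches_brute_force_pair_counting(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.array([1, 0, 1, 0])
        auc, _ = evaluate(scores, labels, "rf")
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_random_scores_match_brute_force(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, _ = evaluate(scores, labels, "sv")
        assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_constant_scores_all_ties(self):
        auc, _ = evaluate(np.zeros(10), np.array([0, 1] * 5), "rf")
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.arange(4.0), np.ones(4, dtype=int), "sv")


class TestIndividualModel:
    def test_strong_effect_high_mean_auc(self):
        res = run_individual_model(subject_table(effect=3.0), "sv")
        assert res.training_mode == "individual"
        assert np.sum(~np.isnan(res.fold_aucs)) == 41
        assert res.auc > 0.9

    def test_mean_over_folds(self):
        res = run_individual_model(subject_table(effect=3.0), "sv")
        assert res.auc == pytest.approx(np.nanmean(res.fold_aucs))


class TestGroupModel:
    def build_cohort(self, n_subjects=4, effect=2.0):
        return pd.concat(
            [subject_table(f"S{i:03d}", n=20, effect=effect, seed=i) for i in range(n_subjects)],
            ignore_index=True,
        )

    def test_excludes_test_subject_from_training(self):
        table = self.build_cohort()
        with pytest.raises(ValueError):
            run_group_model(table, "S001", training_subjects=["S001", "S002"])
        res = run_group_model(table, "S001", "sv")
        assert res.auc > 0.9

    def test_unknown_subject(self):
        with pytest.raises(KeyError):
            run_group_model(self.build_cohort(), "nope")


class TestPermutation:
    def test_p_value_formula_and_threshold(self):
        labels = np.array([0, 1] * 20)
        rng_scores = np.random.default_rng(0).normal(size=40)

        def auc_fn(perm):
            return brute_force_auc(rng_scores, perm)

        observed = 0.99
        p, threshold, null = permutation_significance(auc_fn, labels, observed, 200, seed=1)
        assert p == pytest.approx((1 + np.sum(null >= observed)) / 201)
        assert threshold == pytest.approx(np.percentile(null, 95))

    def test_observed_below_null_median_large_p(self):
        labels = np.array([0, 1] * 15)
        scores = np.random.default_rng(2).normal(size=30)
        p, _, _ = permutation_significance(
            lambda perm: brute_force_auc(scores, perm), labels, 0.30, 200, seed=3
        )
        assert p > 0.5

    def test_type_one_error_calibrated(self):
        """Under label exchange the permutation test rejects at ~alpha."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            scores = rng.normal(size=40)
            labels = np.array([0] * 20 + [1] * 20)
            observed = brute_force_auc(scores, rng.permutation(labels))
            p, _, _ = permutation_significance(
                lambda perm: brute_force_auc(scores, perm), labels, observed, 100, seed=rep
            )
            rejections += p <= 0.05
        rate = rejections / n_rep
        assert 0.0 <= rate <= 0.13  # ~alpha with Monte-Carlo slack

    def test_null_pvalues_super_uniform(self):
        """Permutation p-values under the null pass a KS test against
        super-uniformity."""
        rng = np.random.default_rng(10)
        pvals = []
        for rep in range(100):
            scores = rng.normal(size=30)
            labels = np.array([0] * 15 + [1] * 15)
            observed = brute_force_auc(scores, rng.permutation(labels))
            p, _, _ = permutation_significance(
                lambda perm: brute_force_auc(scores, perm), labels, observed, 100, seed=1000 + rep
            )
            pvals.append(p)
        # super-uniform: P(p <= x) <= x; one-sided KS should not reject
        d_plus = max(np.arange(1, 101) / 100 - np.sort(pvals))
        assert d_plus < 1.63 / np.sqrt(100)  # 1% critical value

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            permutation_significance(lambda p: 0.5, np.array([0, 1]), 0.5, 10)


def test_significance_across_subjects_matches_bh():
    results = []
    pvals = [0.001, 0.2, 0.01, 0.8]
    for i, p in enumerate(pvals):
        r = ModelResult(f"S{i}", "sv", "group", auc=0.7, accuracy=0.6)
        r.p_value = p
        results.append(r)
    flagged = [r.fdr_significant for r in significance_across_subjects(results)]
    from bradyflux.groupstats import fdr_bh

    expected, _ = fdr_bh(pvals)
    assert flagged == expected.tolist()
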