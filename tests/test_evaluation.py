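"""LOOCV, confusion statistics, ROC, permutation test, Holm, scan reduction."""

from dataclasses import replace

import numpy as np
import pytest

from aslgpc import evaluation
from aslgpc.evaluation import (
    ClassifierConfig,
    FoldPrediction,
    classify_loocv,
    comparison_feature_matrix,
    confusion_stats,
    holm_stepdown,
    permutation_test,
    roc_auc,
    scan_reduction_curve,
)
from aslgpc.preprocess import FeatureMatrix, preprocess_records
from aslgpc.synthetic import CohortSpec, simulate_cohort
from aslgpc.volume import ellipsoid_mask

FAST = ClassifierConfig(optimize=False, reoptimize_in_permutations=False)


def _toy_fm(rng, n_subjects=8, per_subject=2, p=12, sep=0.0):
    """Feature matrix with one +1 and one -1 sample per subject."""
    rows, labels, subjects = [], [], []
    for s in range(n_subjects):
        for lab in (1, -1):
            for _ in range(per_subject // 2 or 1):
                x = rng.normal(size=p)
                x[0] += sep * lab
                rows.append(x)
                labels.append(lab)
                subjects.append(f"sub-{s:02d}")
    return FeatureMatrix(
        X=np.array(rows),
        labels=np.array(labels),
        subject_ids=np.array(subjects, dtype=object),
        voxel_index=np.argwhere(np.ones((p, 1, 1), dtype=bool)),
        grid_shape=(p, 1, 1),
    )


def _fold(probs, labels, subject="s"):
    return FoldPrediction(
        subject_id=subject,
        probabilities=np.asarray(probs, dtype=float),
        true_labels=np.asarray(labels),
    )


class TestLOOCV:
    def test_one_fold_per_subject_and_no_leakage_of_held_out_subject(self, rng):
        fm = _toy_fm(rng, n_subjects=8)
        folds = classify_loocv(fm, FAST)
        assert len(folds) == 8
        assert sorted(f.subject_id for f in folds) == sorted(set(fm.subject_ids))
        for f in folds:
            assert len(f.probabilities) == 2

    def test_separable_cohort_reaches_perfect_accuracy(self, rng):
        fm = _toy_fm(rng, n_subjects=6, sep=25.0)
        folds = classify_loocv(fm, ClassifierConfig(optimize=True))
        assert confusion_stats(folds).balanced_accuracy == 1.0

    def test_fold_identity_is_by_subject_not_position(self, rng):
        fm = _toy_fm(rng, n_subjects=6, sep=2.0)
        perm = rng.permutation(fm.n_samples)
        fm_shuf = FeatureMatrix(
            X=fm.X[perm],
            labels=fm.labels[perm],
            subject_ids=fm.subject_ids[perm],
            voxel_index=fm.voxel_index,
            grid_shape=fm.grid_shape,
        )
        a = {f.subject_id: np.sort(f.probabilities) for f in classify_loocv(fm, FAST)}
        b = {f.subject_id: np.sort(f.probabilities) for f in classify_loocv(fm_shuf, FAST)}
        for subj in a:
            # agreement up to the EP convergence tolerance (sweep order
            # follows row order, so bitwise equality is not expected)
            np.testing.assert_allclose(a[subj], b[subj], atol=1e-6)

    def test_training_partition_missing_a_class_names_subject(self, rng):
        fm = _toy_fm(rng, n_subjects=3)
        # make subject sub-00 the only carrier of class +1
        labels = fm.labels.copy()
        labels[(fm.subject_ids != "sub-00") & (labels == 1)] = -1
        fm = FeatureMatrix(
            X=fm.X, labels=labels, subject_ids=fm.subject_ids,
            voxel_index=fm.voxel_index, grid_shape=fm.grid_shape,
        )
        with pytest.raises(ValueError, match="sub-00"):
            classify_loocv(fm, FAST)

    def test_held_out_features_do_not_enter_training_state(self, rng):
        """Guard: a fold's model is a function of the other subjects only.

        Corrupting the held-out subject's rows must yield exactly the
        predictions of a model trained without that subject, applied to
        the corrupted rows — i.e. the corruption leaks only through the
        prediction input, never through training.
        """
        from aslgpc import gpc

        fm = _toy_fm(rng, n_subjects=5, sep=2.0)
        target = fm.subject_ids == "sub-02"
        corrupted = FeatureMatrix(
            X=fm.X.copy(), labels=fm.labels, subject_ids=fm.subject_ids,
            voxel_index=fm.voxel_index, grid_shape=fm.grid_shape,
        )
        corrupted.X[target] += 1e3
        fold = next(
            f for f in classify_loocv(corrupted, FAST) if f.subject_id == "sub-02"
        )
        # independent reconstruction from the *uncorrupted* training rows
        model = gpc.fit(fm.X[~target], fm.labels[~target].astype(float),
                        optimize_hyperparams=False)
        expected = gpc.predict_probability(model, corrupted.X[target])
        np.testing.assert_allclose(fold.probabilities, expected, atol=1e-10)


class TestConfusionStats:
    @pytest.mark.parametrize(
        "correct_pos, correct_neg, expected_ba",
        [(19, 15, 0.85), (15, 13, 0.70), (20, 20, 1.0)],
    )
    def test_rates_from_correct_counts(self, correct_pos, correct_neg, expected_ba):
        """Balanced accuracy is the mean of the two class-wise rates."""
        n = 20
        p_pos = np.r_[np.full(correct_pos, 0.9), np.full(n - correct_pos, 0.1)]
        p_neg = np.r_[np.full(correct_neg, 0.1), np.full(n - correct_neg, 0.9)]
        folds = [_fold(p_pos, np.ones(n, int)), _fold(p_neg, -np.ones(n, int))]
        rep = confusion_stats(folds)
        assert rep.sensitivity == pytest.approx(correct_pos / n)
        assert rep.specificity == pytest.approx(correct_neg / n)
        assert rep.balanced_accuracy == pytest.approx(expected_ba)

    def test_threshold_tie_counts_as_error_for_both_classes(self):
        folds = [_fold([0.5, 0.5], [1, -1])]
        rep = confusion_stats(folds)
        assert rep.sensitivity == 0.0 and rep.specificity == 0.0

    def test_single_class_pool_flagged(self):
        with pytest.raises(ValueError, match="absent"):
            confusion_stats([_fold([0.9], [1])])


class TestROC:
    def test_perfect_and_reversed_ranking(self):
        folds = [_fold([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])]
        assert roc_auc(folds)[2] == 1.0
        folds = [_fold([0.1, 0.2, 0.8, 0.9], [1, 1, -1, -1])]
        assert roc_auc(folds)[2] == 0.0

    def test_auc_equals_concordant_pair_count(self, rng):
        """Rank AUC == brute-force concordant-pair fraction (ties half)."""
        p = np.array([0.9, 0.7, 0.7, 0.4, 0.3, 0.2])
        y = np.array([1, -1, 1, 1, -1, -1])
        auc = roc_auc([_fold(p, y)])[2]
        pos, neg = p[y == 1], p[y == -1]
        pairs = [(a, b) for a in pos for b in neg]
        brute = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
        assert auc == pytest.approx(brute)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        p = rng.random(40)
        y = np.where(rng.random(40) < 0.5, 1, -1)
        y[:2] = [1, -1]  # both classes present
        auc = roc_auc([_fold(p, y)])[2]
        assert auc == pytest.approx(roc_auc_score((y == 1).astype(int), p))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([_fold([0.9, 0.8], [1, 1])])


class TestPermutationTest:
    def test_observed_below_all_null_gives_p_one(self, rng):
        fm = _toy_fm(rng, n_subjects=4)
        p, null, _ = permutation_test(fm, FAST, n_perm=20, seed=0, observed=-1.0)
        assert p == 1.0

    def test_strong_signal_reaches_estimator_minimum(self, rng):
        # enough subjects that no drawn flip pattern is the identity or the
        # global inversion (either would reproduce the separable problem)
        fm = _toy_fm(rng, n_subjects=12, sep=25.0)
        p, null, obs = permutation_test(fm, FAST, n_perm=49, seed=1)
        assert obs == 1.0
        assert p == pytest.approx(1.0 / 50.0)

    def test_plus_one_minimum_matches_thousand_perm_convention(self):
        """With 1,000 permutations the smallest attainable p is ~0.001."""
        null = np.zeros(1000)
        p = (1.0 + np.sum(null >= 1.0)) / (1.0 + 1000)
        assert p == pytest.approx(0.001, abs=1e-4)

    def test_subject_level_flips_keep_within_subject_pairing(self, rng):
        """Null labels always flip a subject's two samples together."""
        fm = _toy_fm(rng, n_subjects=5)
        seen = []

        def spy_loocv(fm_, config, labels=None):
            if labels is not None:
                seen.append(labels.copy())
            return [
                _fold([0.5], [1], "a"),
                _fold([0.4], [-1], "b"),
            ]

        import aslgpc.evaluation as ev

        orig = ev.classify_loocv
        ev.classify_loocv = spy_loocv
        try:
            # optimize=True exercises the generic path, where every null
            # replicate goes through (the spied) classify_loocv
            permutation_test(
                fm, ClassifierConfig(optimize=True), n_perm=15, seed=3, observed=0.6
            )
        finally:
            ev.classify_loocv = orig
        assert len(seen) == 15
        any_flip = False
        for labels in seen:
            for s in np.unique(fm.subject_ids):
                sel = fm.subject_ids == s
                ratio = labels[sel] / fm.labels[sel]
                assert np.all(ratio == ratio[0])  # whole-subject flip
                any_flip |= ratio[0] == -1
        assert any_flip

    def test_frozen_kernel_path_matches_generic_loocv(self, rng):
        """The precomputed-kernel permutation path reproduces classify_loocv
        exactly at fixed hyperparameters."""
        from aslgpc.evaluation import _fold_kernels, _predictions_from_kernels

        fm = _toy_fm(rng, n_subjects=6, sep=1.5)
        kernels = _fold_kernels(fm, FAST.start)
        fast = _predictions_from_kernels(kernels, fm.labels)
        slow = classify_loocv(fm, FAST)
        for a, b in zip(sorted(fast, key=lambda f: f.subject_id),
                        sorted(slow, key=lambda f: f.subject_id)):
            assert a.subject_id == b.subject_id
            np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-12)

    def test_null_distribution_exchangeable(self, rng):
        """Two independent null batches have the same BA distribution."""
        from scipy.stats import ks_2samp

        fm = _toy_fm(rng, n_subjects=6)
        _, null_a, _ = permutation_test(fm, FAST, n_perm=60, seed=10, observed=1.0)
        _, null_b, _ = permutation_test(fm, FAST, n_perm=60, seed=20, observed=1.0)
        assert ks_2samp(null_a, null_b).pvalue > 0.01


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_stepdown([0.03]), [0.03])

    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            holm_stepdown([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_dominance_and_monotonicity(self, rng):
        p = rng.random(12)
        adj = holm_stepdown(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(9)
        np.testing.assert_allclose(
            holm_stepdown(p), multipletests(p, method="holm")[1], rtol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            holm_stepdown([0.5, 1.2])


@pytest.fixture(scope="module")
def small_processed():
    spec = CohortSpec(
        n_subjects=4, n_scans_per_session=3, grid_shape=(10, 12, 10), seed=5
    )
    records = simulate_cohort(spec)
    mask = ellipsoid_mask(spec.grid_shape)
    return preprocess_records(records, mask), mask


class TestScanReduction:
    def test_curve_shape_and_full_entry_matches_direct_analysis(self, small_processed):
        records, mask = small_processed
        entries = scan_reduction_curve(
            records, mask, FAST, max_scans=3, sides=["left"],
            n_perm=9, seed=2, preprocessed=True,
        )
        assert [e.n_scans for e in entries] == [1, 2, 3]
        # the all-scans entry reproduces the direct averaged analysis
        fm = comparison_feature_matrix(
            records, mask, "followup_vs_post", side="left", aggregate="session"
        )
        direct = confusion_stats(classify_loocv(fm, FAST))
        assert entries[-1].balanced_accuracy == pytest.approx(direct.balanced_accuracy)
        assert all(e.p_value_holm is not None for e in entries)
        np.testing.assert_allclose(
            [e.p_value_holm for e in entries],
            holm_stepdown([e.p_value for e in entries]),
        )

    def test_insufficient_scans_rejected(self, small_processed):
        records, mask = small_processed
        with pytest.raises(ValueError, match="only 3 scans"):
            scan_reduction_curve(records, mask, FAST, max_scans=6, preprocessed=True)


class TestComparisons:
    def test_pre_vs_post_labels(self, tiny_cohort, tiny_mask):
        fm = comparison_feature_matrix(tiny_cohort, tiny_mask, "pre_vs_post")
        assert set(fm.labels) == {1, -1}
        n_subj = len(set(fm.subject_ids))
        assert fm.n_samples == 2 * n_subj  # one sample per subject per class

    def test_followup_vs_post_restricts_side(self, tiny_cohort, tiny_mask):
        fm = comparison_feature_matrix(
            tiny_cohort, tiny_mask, "followup_vs_post", side="left", aggregate="session"
        )
        n_subj = len(set(fm.subject_ids))
        assert fm.n_samples == 2 * n_subj
        with pytest.raises(ValueError, match="side"):
            comparison_feature_matrix(tiny_cohort, tiny_mask, "followup_vs_post")

    def test_left_vs_right_uses_only_postsurgical_scans(self, tiny_cohort, tiny_mask):
        fm = comparison_feature_matrix(
            tiny_cohort, tiny_mask, "left_vs_right", aggregate="session"
        )
        n_subj = len(set(fm.subject_ids))
        assert fm.n_samples == 2 * n_subj
        assert np.sum(fm.labels == 1) == np.sum(fm.labels == -1)

    def test_laterality_is_chance_level_on_synthetic_data(self):
        """Left and right postsurgery share one template: decoding is null."""
        bas = []
        for seed in (1, 2, 3, 4, 5, 6):
            spec = CohortSpec(
                n_subjects=8, n_scans_per_session=2, grid_shape=(10, 12, 10), seed=seed
            )
            mask = ellipsoid_mask(spec.grid_shape)
            records = preprocess_records(simulate_cohort(spec), mask)
            fm = comparison_feature_matrix(
                records, mask, "left_vs_right", aggregate="session"
            )
            bas.append(confusion_stats(classify_loocv(fm, FAST)).balanced_accuracy)
        assert abs(np.mean(bas) - 0.5) < 0.15
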