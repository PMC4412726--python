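import numpy as np
import pandas as pd
import pytest

from petroi.errors import ConfigurationError, EvaluationError
from petroi.evaluation import (
    AtlasFeaturizer,
    ClassifierSpec,
    FoldResult,
    GMMFeaturizer,
    TTestFeaturizer,
    auc_pooled,
    corrected_resampled_ttest,
    cross_validate,
    default_positive_label,
    dissimilarity_ratio,
    informative_regions_report,
    inner_select_bins,
    stratified_folds,
    summarize,
    train_eval_fold,
)
from petroi.roi_discovery import Cluster, ClusterMap
from petroi.volume_io import Atlas, Volume


class TestStratifiedFolds:
    def test_30_30_gives_3_per_class_and_54_training(self):
        labels = np.array(["MCI"] * 30 + ["AD"] * 30)
        plan = stratified_folds(labels, n_folds=10, n_repeats=2, seed=0)
        for r in range(2):
            for f in range(10):
                fold = plan.assignment[r] == f
                assert fold.sum() == 6
                assert (labels[fold] == "MCI").sum() == 3
                assert (labels[fold] == "AD").sum() == 3
                assert (~fold).sum() == 54

    def test_10_10_gives_1_per_class(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        plan = stratified_folds(labels, n_folds=10, n_repeats=1, seed=1)
        for f in range(10):
            fold = plan.assignment[0] == f
            assert (labels[fold] == "a").sum() == 1
            assert (labels[fold] == "b").sum() == 1

    def test_folds_partition_subjects(self):
        labels = np.array(["a"] * 17 + ["b"] * 23)
        plan = stratified_folds(labels, n_folds=5, n_repeats=3, seed=2)
        for r in range(3):
            assert sorted(np.unique(plan.assignment[r])) == list(range(5))
            for cls in ("a", "b"):
                sizes = [((plan.assignment[r] == f) & (labels == cls)).sum() for f in range(5)]
                assert max(sizes) - min(sizes) <= 1

    def test_deterministic(self):
        labels = np.array(["a", "b"] * 20)
        a = stratified_folds(labels, 4, 2, seed=3)
        b = stratified_folds(labels, 4, 2, seed=3)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_small_class_rejected(self):
        labels = np.array(["a"] * 3 + ["b"] * 30)
        with pytest.raises(ConfigurationError):
            stratified_folds(labels, n_folds=10)


class TestAucPooled:
    def test_perfect_separation(self):
        auc, _ = auc_pooled([True, True, False, False], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_all_equal_scores(self):
        auc, _ = auc_pooled([True, False, True, False], [0.5] * 4)
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        truth = rng.random(60) > 0.5
        truth[0], truth[1] = True, False
        scores = np.round(rng.random(60), 2)  # induce ties
        auc, _ = auc_pooled(truth, scores)
        wins = ties = 0
        pos = scores[truth]
        neg = scores[~truth]
        for sp in pos:
            for sn in neg:
                if sp > sn:
                    wins += 1
                elif sp == sn:
                    ties += 1
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc_pooled([True, True], [0.1, 0.2])


class TestCorrectedResampledTTest:
    def test_all_zero_differences(self):
        assert corrected_resampled_ttest(np.zeros(10), 54, 6) == (0.0, 1.0)

    def test_reduces_to_classical_paired_t(self, rng):
        from scipy import stats

        d = rng.normal(0.03, 0.02, size=10)
        t, p = corrected_resampled_ttest(d, n_train=54, n_test=0)
        t_ref, p_ref = stats.ttest_1samp(d, 0.0)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_p_increases_with_test_train_ratio(self, rng):
        d = rng.normal(0.05, 0.03, size=10)
        ps = [corrected_resampled_ttest(d, 100, n_test)[1] for n_test in (0, 10, 50, 100, 400)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_zero_variance_nonzero_mean(self):
        t, p = corrected_resampled_ttest(np.full(5, 0.1), 54, 6)
        assert np.isinf(t) and p == 0.0


class TestSummarize:
    @staticmethod
    def toy_folds():
        """12 subjects, 2 folds x 1 repeat, hand-checkable confusion."""
        mk = lambda r, f, yt, yp, s: FoldResult(
            r, f, np.arange(len(yt)), np.array(yt), np.array(yp), np.array(s), None, 1.0
        )
        return [
            mk(0, 0, ["AD", "AD", "NC", "NC", "NC", "AD"],
                      ["AD", "NC", "NC", "NC", "AD", "AD"], [0.9, 0.4, 0.2, 0.1, 0.6, 0.8]),
            mk(0, 1, ["AD", "NC", "NC", "AD", "NC", "AD"],
                      ["AD", "NC", "NC", "AD", "NC", "NC"], [0.7, 0.3, 0.2, 0.8, 0.1, 0.45]),
        ]

    def test_matches_hand_confusion(self):
        s = summarize(self.toy_folds(), positive_label="AD")
        # pooled: 12 instances, 9 correct; TP 4/6, TN 5/6
        assert s.accuracy == pytest.approx(9 / 12)
        assert s.sensitivity == pytest.approx(4 / 6)
        assert s.specificity == pytest.approx(5 / 6)

    def test_all_correct_gives_ones(self):
        folds = [
            FoldResult(0, 0, np.arange(4), np.array(["AD", "NC", "AD", "NC"]),
                       np.array(["AD", "NC", "AD", "NC"]), np.array([0.9, 0.1, 0.8, 0.2]), None, 1.0)
        ]
        s = summarize(folds, positive_label="AD")
        assert (s.accuracy, s.auc, s.sensitivity, s.specificity) == (1.0, 1.0, 1.0, 1.0)

    def test_majority_vote_convention(self):
        folds = [
            FoldResult(0, 0, np.arange(4), np.array(["AD", "AD", "NC", "NC"]),
                       np.array(["AD", "AD", "AD", "AD"]), np.array([0.6, 0.6, 0.6, 0.6]), None, 1.0)
        ]
        s = summarize(folds, positive_label="AD")
        assert s.accuracy == 0.5
        assert s.sensitivity == 1.0
        assert s.specificity == 0.0


class TestDissimilarityRatio:
    def test_forced_arithmetic(self):
        # distances 1.26 vs 1.00 -> rho = 0.26
        res = dissimilarity_ratio([0.0], [[1.26]], [[1.0]], [1.0])
        assert res.rho == pytest.approx(0.26)

    def test_equal_distances_give_zero(self):
        res = dissimilarity_ratio([0.0, 0.0], [[3.0, 4.0]], [[4.0, 3.0]], [1.0, 1.0])
        assert res.rho == 0.0

    def test_zero_weights_rejected(self):
        with pytest.raises(EvaluationError):
            dissimilarity_ratio([1.0], [[2.0]], [[3.0]], [0.0])


class TestPositiveLabel:
    def test_impairment_ordering(self):
        assert default_positive_label(["NC", "AD", "NC"]) == "AD"
        assert default_positive_label(["MCI", "NC"]) == "MCI"
        assert default_positive_label(["MCI", "AD"]) == "AD"


class _StubFeaturizer:
    """Featurizer whose features are supplied directly (index lookup)."""

    chosen_bins_ = None

    def __init__(self, table):
        self.table = np.asarray(table, dtype=np.float64)

    def fit(self, train_volumes, train_labels, seed=0):
        return self

    def transform(self, volumes):
        return self.table[[v for v in volumes]]

    def select(self, train_values, train_labels, seed=0):
        return None


class TestTrainEvalFold:
    def test_separable_features_perfect_fold(self):
        rng = np.random.default_rng(0)
        table = np.vstack([rng.normal(0, 0.1, (10, 4)), rng.normal(5, 0.1, (10, 4))])
        labels = np.array(["NC"] * 10 + ["AD"] * 10)
        volumes = list(range(20))
        fr = train_eval_fold(
            volumes, labels, np.arange(2, 20), np.array([0, 1, 10, 11]),
            _StubFeaturizer(table), ClassifierSpec(), seed=0, positive_label="AD",
        )
        assert (fr.y_pred == fr.y_true).all()
        assert (fr.scores[fr.y_true == "AD"] > fr.scores[fr.y_true == "NC"].max()).all()

    def test_random_features_near_chance(self):
        rng = np.random.default_rng(1)
        table = rng.normal(size=(60, 10))
        labels = np.array(["NC", "AD"] * 30)
        volumes = list(range(60))
        res = cross_validate(
            volumes, labels, _StubFeaturizer(table), n_folds=10, n_repeats=3, seed=5
        )
        assert 0.3 <= res.summary.accuracy <= 0.7

    def test_single_class_training_rejected(self):
        table = np.zeros((4, 2))
        labels = np.array(["NC", "NC", "NC", "AD"])
        with pytest.raises(EvaluationError):
            train_eval_fold(
                list(range(4)), labels, np.arange(3), np.array([3]),
                _StubFeaturizer(table), ClassifierSpec(), seed=0, positive_label="AD",
            )


class TestInnerSelectBins:
    def test_single_grid_value_short_circuits(self, small_cohort):
        cohort = small_cohort
        feat = GMMFeaturizer(
            cohort.mask, bin_grid=(4,), gmm_kws=dict(n_restarts=1, tol=1e-2, max_iter=30)
        )
        feat.fit(cohort.volumes, np.array(cohort.labels), seed=0)
        assert feat.chosen_bins_ == 4

    def test_informative_map_beats_destroyed_map(self):
        """A map aligned with the group effect wins over a signal-destroying one."""
        rng = np.random.default_rng(2)
        shape = (6, 6, 6)
        n = 20
        labels = np.array(["NC"] * (n // 2) + ["AD"] * (n // 2))
        volumes = []
        for lab in labels:
            data = rng.normal(1.0, 0.05, shape)
            if lab == "AD":
                data[:3] -= 0.3  # effect confined to one half
            volumes.append(Volume(data))
        grid_all = np.indices(shape).reshape(3, -1).T
        good = ClusterMap(
            [Cluster(0, 1, 0, grid_all[grid_all[:, 0] < 3]),
             Cluster(1, 1, 1, grid_all[grid_all[:, 0] >= 3])],
            2, "bic", shape, 0)
        # single whole-brain cluster: effect diluted below the noise
        bad = ClusterMap([Cluster(0, 1, 0, grid_all)], 1, "bic", shape, 0)
        maps = {50: good, 150: bad}
        chosen, _, accs = inner_select_bins(
            volumes, labels, reference=volumes[0], discover=lambda b: maps[b],
            bin_grid=(50, 150), top_m=2, classifier=ClassifierSpec(probability=False),
            seed=0,
        )
        assert chosen == 50
        assert accs[50] >= accs[150]
        assert chosen in (50, 150)


class TestLeakageGuard:
    def test_mutating_test_volumes_changes_nothing_trained(self, small_cohort):
        cohort = small_cohort
        labels = np.array(cohort.labels)
        train_idx = np.arange(2, 16)
        test_idx = np.array([0, 1])
        kw = dict(bin_grid=(3, 6), gmm_kws=dict(n_restarts=1, tol=1e-2, max_iter=30))
        a = train_eval_fold(
            cohort.volumes, labels, train_idx, test_idx,
            GMMFeaturizer(cohort.mask, **kw), ClassifierSpec(), seed=4, positive_label="AD",
        )
        mutated = list(cohort.volumes)
        for i in test_idx:
            mutated[i] = Volume(np.full(cohort.volumes[i].shape, 42.0))
        b = train_eval_fold(
            mutated, labels, train_idx, test_idx,
            GMMFeaturizer(cohort.mask, **kw), ClassifierSpec(), seed=4, positive_label="AD",
        )
        assert a.chosen_bins == b.chosen_bins
        assert a.chosen_c == b.chosen_c
        assert [u[0] for u in a.top_units] == [u[0] for u in b.top_units]


class TestInformativeRegionsReport:
    def test_single_cluster_single_region_100_percent(self):
        labels = np.zeros((4, 4, 4), dtype=np.int64)
        labels[1:3, 1:3, 1:3] = 5
        atlas = Atlas(labels, {5: "precuneus"})
        coords = np.argwhere(labels == 5)
        fr = FoldResult(0, 0, np.array([0]), np.array(["AD"]), np.array(["AD"]),
                        np.array([0.9]), None, 1.0,
                        top_units=[(coords.tobytes(), coords, 10)])
        report = informative_regions_report([fr], atlas)
        assert len(report) == 1
        assert report.loc[0, "region_name"] == "precuneus"
        assert report.loc[0, "share_pct"] == pytest.approx(100.0)

    def test_shares_sum_at_most_100(self, small_cohort):
        cohort = small_cohort
        labels = np.array(cohort.labels)
        res = cross_validate(
            cohort.volumes, labels,
            GMMFeaturizer(cohort.mask, bin_grid=(4,), gmm_kws=dict(n_restarts=1, tol=1e-2, max_iter=30)),
            n_folds=4, n_repeats=1, seed=0,
        )
        report = informative_regions_report(res.folds, cohort.atlas)
        assert report["share_pct"].sum() <= 100.0 + 1e-9
        assert (report["share_pct"] > 0).all()


class TestBaselineFeaturizers:
    def test_atlas_featurizer_dimension(self, small_cohort):
        feat = AtlasFeaturizer(small_cohort.atlas)
        values = feat.transform(small_cohort.volumes[:2])
        assert values.shape == (2, 2 * len(small_cohort.atlas.names))

    def test_ttest_featurizer_selects_affected_voxels(self, small_cohort):
        cohort = small_cohort
        feat = TTestFeaturizer(cohort.mask, alpha=0.05, top_m=50)
        feat.fit(cohort.volumes, np.array(cohort.labels), seed=0)
        affected = np.isin(
            cohort.atlas.labels[tuple(feat.coords_.T)], cohort.affected_regions
        )
        assert affected.mean() > 0.8  # selected voxels concentrate in true regions
        values = feat.transform(cohort.volumes[:3])
        assert values.shape == (3, feat.coords_.shape[0])
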