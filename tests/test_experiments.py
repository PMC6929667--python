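"""Metrics, split protocol, grid enumeration, runners, leakage guards."""

import numpy as np
import pytest

import painconn as pc
from painconn.augmentation import AugmentationConfig
from painconn.experiments import (GridConfig, classical_baseline_search,
                                  default_search_space)
from painconn.models import TrainConfig

SMALL_ARCH = dict(e2e_filters=4, e2n_filters=8, n2g_units=16,
                  fc_sizes=(16, 8, 2), conv1d_filters=(16, 16), conv1d_fc=16)


class TestMetrics:
    def test_balanced_accuracy_examples(self):
        assert pc.balanced_accuracy([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
        assert pc.balanced_accuracy([1, 1, 0, 0], [1, 0, 0, 0]) == 0.75
        assert pc.balanced_accuracy([1, 1, 1, 0], [1, 1, 1, 1]) == 0.5
        with pytest.raises(ValueError):
            pc.balanced_accuracy([1, 1], [1, 0])

    def test_log_loss_examples(self):
        y = np.array([1, 0, 1])
        assert pc.log_loss(y, [1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)
        assert pc.log_loss(y, [0.5, 0.5, 0.5]) == pytest.approx(np.log(2))
        big = pc.log_loss([1], [0.0], clip_eps=1e-15)
        assert big == pytest.approx(-np.log(1e-15))

    def test_auc_examples(self):
        assert pc.auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert pc.auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
        assert pc.auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == 0.75
        with pytest.raises(ValueError):
            pc.auc([1, 1], [0.5, 0.6])

    def test_metrics_match_sklearn_oracles(self, rng):
        """200 random label/score vectors against scikit-learn's versions."""
        from sklearn.metrics import (balanced_accuracy_score,
                                     log_loss as sk_log_loss, roc_auc_score)

        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(n)
            yhat = (p >= 0.5).astype(int)
            if len(np.unique(yhat)) >= 1:
                assert pc.balanced_accuracy(y, yhat) == pytest.approx(
                    balanced_accuracy_score(y, yhat), abs=1e-10)
            assert pc.log_loss(y, p) == pytest.approx(
                sk_log_loss(y, p, labels=[0, 1]), abs=1e-10)
            assert pc.auc(y, p) == pytest.approx(roc_auc_score(y, p), abs=1e-10)


class TestStratifiedSplit:
    def test_140_subjects_at_070_gives_98_42(self):
        y = np.array([0] * 87 + [1] * 53)
        train, test = pc.stratified_split(y, 0.70, seed=0)
        assert len(train) == 98 and len(test) == 42
        assert set(train) | set(test) == set(range(140))
        assert set(train).isdisjoint(test)
        # stratification preserves the class ratio on both sides
        assert np.bincount(y[train]).tolist() == [61, 37]
        assert np.bincount(y[test]).tolist() == [26, 16]

    def test_largest_remainder_small_case(self):
        y = np.repeat([0, 1], 5)
        train, test = pc.stratified_split(y, 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2
        assert np.bincount(y[test]).tolist() == [1, 1]

    def test_same_seed_identical_partition(self):
        y = np.repeat([0, 1], [30, 20])
        a = pc.stratified_split(y, 0.7, seed=3)
        b = pc.stratified_split(y, 0.7, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_test_class_rejected(self):
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError):
            pc.stratified_split(y, 0.9, seed=0)


class TestGrid:
    def test_full_grid_counts(self):
        grid = pc.enumerate_grid(GridConfig())
        assert len(grid) == 2592
        assert len(set(grid)) == 2592
        baseline = pc.enumerate_baseline_grid()
        assert len(baseline) == 24
        assert len(grid) + len(baseline) == 2616

    def test_singleton_factors_give_one_spec(self):
        g = GridConfig(parcellations=("p",), measures=("dtw",),
                       architectures=("ann4brains",), learning_rates=(0.01,),
                       dropouts=(0.5,), l1_lambdas=(0.0,), l2_lambdas=(0.0,))
        assert len(pc.enumerate_grid(g)) == 1

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pc.enumerate_grid(GridConfig(measures=()))


@pytest.fixture(scope="module")
def effect_features():
    """Correlation features from a small effect-bearing cohort."""
    edges = pc.choose_affected_edges(8, 0.25, seed=2)
    cfg = pc.CohortConfig(n_subjects=60, n_regions=8, n_timepoints=100,
                          affected_edges=edges, base_coupling=0.4,
                          corr_effect=0.5, artifact_rate=0.0, seed=13)
    recs = pc.generate_cohort(cfg)
    return pc.cohort_features(recs, "correlation")


class TestRunExperiment:
    def test_rerun_reproduces_metrics_exactly(self, effect_features):
        fs = effect_features
        split = pc.stratified_split(fs.group_labels, 0.7, seed=1)
        spec = pc.ExperimentSpec("toy", "correlation", "ann4brains",
                                 0.01, 0.0, 0.0, 0.0, seed=3)
        kw = dict(aug_cfg=AugmentationConfig(n_synthetic=200, seed=0),
                  train_cfg=TrainConfig(epochs=10),
                  arch_overrides=SMALL_ARCH)
        a = pc.run_experiment(spec, fs, split, **kw)
        b = pc.run_experiment(spec, fs, split, **kw)
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy, abs=1e-6)
        assert a.log_loss == pytest.approx(b.log_loss, abs=1e-6)
        assert a.auc == pytest.approx(b.auc, abs=1e-6)

    def test_overlapping_folds_are_a_hard_error(self, effect_features):
        fs = effect_features
        spec = pc.ExperimentSpec("toy", "correlation", "ann4brains",
                                 0.01, 0.0, 0.0, 0.0)
        with pytest.raises(RuntimeError, match="provenance"):
            pc.run_experiment(spec, fs, (np.arange(40), np.arange(30, 60)),
                              aug_cfg=AugmentationConfig(n_synthetic=50),
                              train_cfg=TrainConfig(epochs=2),
                              arch_overrides=SMALL_ARCH)


class TestClassicalSearch:
    def test_single_candidate_space_returns_it(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(2, 1, (20, 5))])
        y = np.repeat([0, 1], 20)
        space = {"scaler": [True], "select_k": [0],
                 "classifier": [("logreg", (("C", 1.0),))]}
        res = classical_baseline_search(x, y, folds=3, population=4,
                                        generations=1, seed=0, space=space)
        assert res.genome == (True, 0, ("logreg", (("C", 1.0),)))
        assert res.evaluations == 1

    def test_separable_data_reaches_high_cv_score(self, rng):
        x = np.vstack([rng.normal(0, 1, (30, 8)), rng.normal(5, 1, (30, 8))])
        y = np.repeat([0, 1], 30)
        res = classical_baseline_search(x, y, metric="balanced_accuracy",
                                        folds=5, population=8, generations=2,
                                        seed=1)
        assert res.cv_score >= 0.9
        assert res.evaluations <= len(default_search_space()["classifier"]) * 8

    def test_log_loss_metric_is_minimized(self, rng):
        x = np.vstack([rng.normal(0, 1, (25, 6)), rng.normal(4, 1, (25, 6))])
        y = np.repeat([0, 1], 25)
        res = classical_baseline_search(x, y, metric="log_loss", folds=3,
                                        population=6, generations=2, seed=2)
        assert res.cv_score >= 0.0  # natural scale: a loss
        assert res.cv_score < 0.4  # separable data: near-certain predictions

    def test_bad_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            classical_baseline_search(rng.standard_normal((10, 3)),
                                      np.repeat([0, 1], 5), folds=1)


def test_sex_control_rejects_single_sex_fold(effect_features):
    fs = effect_features
    fs_bad = pc.FeatureSet(fs.vectors, fs.group_labels,
                           np.ones_like(fs.sex_labels), fs.subject_ids,
                           fs.n_regions, fs.parcellation_id, fs.measure)
    split = pc.stratified_split(fs.group_labels, 0.7, seed=1)
    spec = pc.ExperimentSpec("toy", "correlation", "ann4brains", 0.01, 0, 0, 0)
    with pytest.raises(ValueError, match="single-sex"):
        pc.sex_control_analysis([spec], fs_bad, split)
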