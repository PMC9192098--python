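import itertools

import numpy as np
import pytest

from sttkit.model import (
    ECG_FEATURES,
    VCG_FEATURES,
    ModelConfig,
    auc_rank,
    compute_metrics,
    cross_validate,
    grid_search_subsets,
    pca_baseline,
    screen_single_features,
    select_and_evaluate,
    train_svm,
)


def _blobs(rng, n=100, d=3, sep=5.0):
    # noise truncated at 2 SD so a 5-SD shift leaves a genuine margin
    X = np.clip(rng.normal(size=(n, d)), -2.0, 2.0)
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, 0] += sep
    return X, y


class TestComputeMetrics:
    def test_confusion_substitution(self):
        # TP=90, TN=90, FP=10, FN=10
        y_true = np.array([1] * 100 + [0] * 100)
        y_pred = np.array([1] * 90 + [0] * 10 + [1] * 10 + [0] * 90)
        scores = y_pred.astype(float)
        m = compute_metrics(y_true, y_pred, scores)
        assert m["accuracy"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.90)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["f1"] == pytest.approx(0.90)
        assert (m["tp"], m["tn"], m["fp"], m["fn"]) == (90, 90, 10, 10)

    def test_perfect_separation_auc(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_random_scores_auc_half(self, rng):
        y = np.tile([0, 1], 1000)
        scores = rng.normal(size=2000)
        assert auc_rank(y, scores) == pytest.approx(0.5, abs=0.03)

    def test_single_class_auc_error(self):
        with pytest.raises(ValueError, match="single class"):
            auc_rank(np.ones(10, dtype=int), np.arange(10.0))

    def test_accuracy_identity(self, rng):
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        m = compute_metrics(y_true, y_pred, rng.normal(size=200))
        p, n = (y_true == 1).sum(), (y_true == 0).sum()
        identity = (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
        assert m["accuracy"] == pytest.approx(identity, abs=1e-12)


class TestTrainSvm:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X, y = _blobs(rng)
        est = train_svm(X, y)
        assert (est.predict(X) == y).mean() == 1.0

    def test_single_class_error(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            train_svm(rng.normal(size=(20, 2)), np.zeros(20, dtype=int))

    def test_missing_values_error(self, rng):
        X, y = _blobs(rng, n=20)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train_svm(X, y)

    def test_constant_column_warns_and_is_inert(self, rng):
        X, y = _blobs(rng)
        Xc = np.column_stack([X, np.full(len(X), 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            est = train_svm(Xc, y)
        base = train_svm(X, y)
        test = rng.normal(size=(30, 3))
        test_c = np.column_stack([test, np.full(30, 7.0)])
        np.testing.assert_array_equal(est.predict(test_c), base.predict(test))


class TestCrossValidate:
    def test_partition_property(self, rng):
        X, y = _blobs(rng, n=50)
        cfg = ModelConfig(seed=3)
        from sttkit.model import _stratified_folds
        folds = _stratified_folds(y, cfg)
        tested = np.concatenate([te for _, te in folds])
        assert sorted(tested) == list(range(50))
        assert len(set(map(tuple, (np.sort(te) for _, te in folds)))) == 5

    def test_separable_high_auc(self, rng):
        X, y = _blobs(rng, n=60)
        rep = cross_validate(X, y, ModelConfig(seed=0))
        assert rep.mean["auc"] >= 0.95

    def test_permuted_labels_near_chance(self, rng):
        X, y = _blobs(rng, n=100)
        y_perm = rng.permutation(y)
        rep = cross_validate(X, y_perm, ModelConfig(seed=1))
        assert 0.3 <= rep.mean["auc"] <= 0.7

    def test_reproducible(self, rng):
        X, y = _blobs(rng, n=40)
        a = cross_validate(X, y, ModelConfig(seed=5))
        b = cross_validate(X, y, ModelConfig(seed=5))
        assert a.to_dict() == b.to_dict()

    def test_confusion_counts_sum_to_fold_size(self, rng):
        X, y = _blobs(rng, n=47)
        rep = cross_validate(X, y, ModelConfig(seed=2))
        sizes = sorted(sum(c.values()) for c in rep.confusion)
        assert sum(sizes) == 47

    def test_too_few_samples(self, rng):
        X, y = _blobs(rng, n=4)
        with pytest.raises(ValueError):
            cross_validate(X, y, ModelConfig(cv_folds=5))


class TestScreening:
    def test_informative_feature_kept_noise_dropped(self, rng):
        n = 200
        y = (np.arange(n) % 2).astype(int)
        X = np.column_stack([
            y + rng.normal(scale=0.1, size=n),
            rng.normal(size=n),
            rng.normal(size=n),
        ])
        kept = screen_single_features(X, y, ["good", "noise1", "noise2"],
                                      ModelConfig(seed=0))
        assert [name for name, _ in kept] == ["good"]

    def test_all_noise_empty(self, rng):
        n = 200
        y = (np.arange(n) % 2).astype(int)
        X = rng.normal(size=(n, 3))
        kept = screen_single_features(X, y, ["a", "b", "c"], ModelConfig(seed=0))
        assert kept == []

    def test_zero_threshold_keeps_all(self, rng):
        n = 60
        y = (np.arange(n) % 2).astype(int)
        X = np.column_stack([y + rng.normal(scale=0.5, size=n),
                             rng.normal(size=n)])
        kept = screen_single_features(X, y, ["a", "b"],
                                      ModelConfig(seed=0, screen_threshold=0.0))
        assert sorted(name for name, _ in kept) == ["a", "b"]


class TestGridSearch:
    def test_noise_candidate_excluded(self, rng):
        n = 120
        y = (np.arange(n) % 2).astype(int)
        X = np.column_stack([y * 4 + rng.normal(scale=0.1, size=n),
                             rng.normal(size=n)])
        names = ["informative", "noise"]
        best, rep = grid_search_subsets(X, y, names, names, ModelConfig(seed=0))
        assert best == ["informative"]

    def test_single_candidate(self, rng):
        X, y = _blobs(rng, n=40, d=1)
        best, _ = grid_search_subsets(X, y, ["only"], ["only"], ModelConfig(seed=0))
        assert best == ["only"]

    def test_winner_report_reproducible(self, rng):
        X, y = _blobs(rng, n=60, d=4)
        names = ["f0", "f1", "f2", "f3"]
        cfg = ModelConfig(seed=9)
        best, rep = grid_search_subsets(X, y, names, names, cfg)
        cols = [names.index(nm) for nm in best]
        rerun = cross_validate(X[:, cols], y, cfg, feature_names=best)
        assert rep.to_dict() == rerun.to_dict()

    def test_matches_independent_exhaustive_rescan(self, rng):
        X, y = _blobs(rng, n=50, d=4)
        X[:, 2] += 0.5 * y
        names = ["f0", "f1", "f2", "f3"]
        cfg = ModelConfig(seed=4)
        best, rep = grid_search_subsets(X, y, names, names, cfg)
        # independent re-scan over the power set with the same ranking rule
        results = []
        for size in range(1, 5):
            for sub in itertools.combinations(names, size):
                cols = [names.index(nm) for nm in sub]
                r = cross_validate(X[:, cols], y, cfg)
                results.append(((-r.mean["accuracy"], size, -r.mean["auc"]), list(sub)))
        expected = min(results)[1]
        assert best == expected

    def test_no_candidates_error(self, rng):
        X, y = _blobs(rng, n=20)
        with pytest.raises(ValueError, match="no candidate"):
            grid_search_subsets(X, y, [], ["a"], ModelConfig())

    def test_candidate_cap(self, rng):
        X, y = _blobs(rng, n=20, d=13)
        names = [f"f{i}" for i in range(13)]
        with pytest.raises(ValueError, match="cap"):
            grid_search_subsets(X, y, names, names, ModelConfig())


class TestPcaBaseline:
    def test_dominant_axis_alignment(self, rng):
        n = 200
        y = (np.arange(n) % 2).astype(int)
        X = rng.normal(size=(n, 4))
        X[:, 1] += 20.0 * y  # dominant informative axis
        from sklearn.decomposition import PCA
        pca = PCA(n_components=1).fit(X)
        axis = np.zeros(4)
        axis[1] = 1.0
        assert abs(np.dot(pca.components_[0], axis)) > 0.99
        Z, rep = pca_baseline(X, y, ModelConfig(seed=0))
        assert rep.mean["accuracy"] > 0.9

    def test_isotropic_noise_smoke(self, rng):
        n, d = 100, 5
        y = (np.arange(n) % 2).astype(int)
        Z, rep = pca_baseline(rng.normal(size=(n, d)), y, ModelConfig(seed=0))
        assert Z.shape[0] == n and Z.shape[1] <= d
        assert set(rep.mean) == {"accuracy", "specificity", "sensitivity", "f1", "auc"}

    def test_full_rank_projection_preserves_distances(self, rng):
        # orthogonal-transform property, checked with an independent SVD
        X = rng.normal(size=(50, 4))
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Z = Xc @ vt.T
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(Z), pdist(Xc), atol=1e-9)

    def test_requires_n_greater_than_d(self, rng):
        X = rng.normal(size=(4, 5))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="n > d"):
            pca_baseline(X, y, ModelConfig())


class TestModelFlavours:
    def test_triple_not_dominated_by_single_families(self, cohort_features):
        # on the frozen synthetic cohort the combined (S_I, THI, SHI) triple
        # stays within 0.05 AUC of each single-family selected model
        X, y, names = cohort_features
        cfg = ModelConfig(seed=7)
        cols = [names.index(k) for k in ("S_I", "THI", "SHI")]
        triple_auc = cross_validate(X[:, cols], y, cfg).mean["auc"]
        for flavour in ("ecg_only", "vcg_only"):
            _, rep = select_and_evaluate(X, y, names, flavour, cfg)
            assert triple_auc >= rep.mean["auc"] - 0.05


    def test_feature_pools(self):
        assert len(ECG_FEATURES) == 12
        assert len(VCG_FEATURES) == 5
        assert set(ECG_FEATURES).isdisjoint(VCG_FEATURES)

    def test_unknown_flavour(self, rng):
        X, y = _blobs(rng, n=20)
        with pytest.raises(Exception, match="feature_set"):
            select_and_evaluate(X, y, ["S_I", "S_II", "S_III"], "bogus")

    def test_config_validation(self):
        with pytest.raises(Exception):
            ModelConfig(C=-1.0)
        with pytest.raises(Exception):
            ModelConfig(cv_folds=1)
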