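import numpy as np
import pytest

from bladekit import dfa
from bladekit.dfa import (
    BackboneSpec,
    FeatureMatrix,
    anova_f_scores,
    chi2_scores,
    confusion_metrics,
    extract_deep_features,
    kruskal_wallis_scores,
    mrmr_select,
    relieff_scores,
    roc_auc,
    train_eval,
)
from bladekit.errors import ConfigError, InsufficientDataError


def two_group_fm(a, b):
    vals = np.concatenate([a, b]).astype(float)[:, None]
    y = np.array([0] * len(a) + [1] * len(b))
    return FeatureMatrix(X=vals, y=y)


class TestStubBackbone:
    def test_deterministic_for_same_image(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 40))
        spec = BackboneSpec()
        f1 = extract_deep_features([img], spec).X
        f2 = extract_deep_features([img], spec).X
        np.testing.assert_array_equal(f1, f2)

    def test_shape_contract(self):
        rng = np.random.default_rng(1)
        imgs = [rng.random((30, 30)) for _ in range(5)]
        spec = BackboneSpec(n_features=64)
        fm = extract_deep_features(imgs, spec)
        assert fm.X.shape == (5, 64)

    def test_single_pixel_change_changes_features(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        img2 = img.copy()
        img2[10, 10] += 0.5
        spec = BackboneSpec()
        f1 = extract_deep_features([img], spec, preprocess=False).X
        f2 = extract_deep_features([img2], spec, preprocess=False).X
        assert not np.array_equal(f1, f2)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError):
            extract_deep_features([np.zeros((4, 4))], BackboneSpec(name="vgg19x"))


class TestAnovaF:
    def test_identical_groups_zero(self):
        fm = two_group_fm([1, 2, 3], [1, 2, 3])
        assert anova_f_scores(fm).scores[0] == pytest.approx(0.0)

    def test_hand_computed_f(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, MSW = 1 -> F = 13.5
        fm = two_group_fm([1, 2, 3], [4, 5, 6])
        assert anova_f_scores(fm).scores[0] == pytest.approx(13.5)

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        fm = two_group_fm(rng.normal(0, 1, 10), rng.normal(1, 1, 10))
        shifted = FeatureMatrix(X=fm.X + 100.0, y=fm.y)
        np.testing.assert_allclose(anova_f_scores(fm).scores,
                                   anova_f_scores(shifted).scores)

    def test_zero_within_variance_sentinel(self):
        fm = two_group_fm([1, 1, 1], [2, 2, 2])
        assert anova_f_scores(fm).scores[0] == dfa.F_SENTINEL


class TestKruskalWallis:
    def test_identical_distributions_zero(self):
        fm = two_group_fm([1, 2, 3], [1, 2, 3])
        assert kruskal_wallis_scores(fm).scores[0] == pytest.approx(0.0)

    def test_hand_computed_h(self):
        # ranks 1..6, no ties: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 3.857...
        fm = two_group_fm([1, 2, 3], [4, 5, 6])
        assert kruskal_wallis_scores(fm).scores[0] == pytest.approx(27 / 7, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        fm = two_group_fm(a, b)
        fm_t = two_group_fm(np.exp(a), np.exp(b))  # strictly monotone map
        np.testing.assert_allclose(kruskal_wallis_scores(fm).scores,
                                   kruskal_wallis_scores(fm_t).scores)


class TestChi2:
    def test_balanced_sums_zero(self):
        fm = two_group_fm([2, 2], [1, 3])  # class sums 4 and 4, equal sizes
        assert chi2_scores(fm).scores[0] == pytest.approx(0.0)

    def test_hand_computed_statistic(self):
        # observed per-class sums {2, 6}, expected {4, 4} -> (4/4) + (4/4) = 2
        fm = two_group_fm([1, 1], [3, 3])
        assert chi2_scores(fm).scores[0] == pytest.approx(2.0)

    def test_scale_doubles_score(self):
        rng = np.random.default_rng(5)
        fm = two_group_fm(rng.random(8), rng.random(8) + 0.5)
        doubled = FeatureMatrix(X=2 * fm.X, y=fm.y)
        np.testing.assert_allclose(chi2_scores(doubled).scores,
                                   2 * chi2_scores(fm).scores)

    def test_negative_values_rejected(self):
        fm = two_group_fm([-1, 0], [1, 2])
        with pytest.raises(ValueError, match="non-negative"):
            chi2_scores(fm)


def brute_force_relieff(X, y, k):
    """Independent straight-from-definition ReliefF (exhaustive, tiny n)."""
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    Xn = (X - X.min(axis=0)) / rng_
    n, p = Xn.shape
    w = np.zeros(p)
    for i in range(n):
        dists = [(sum(abs(Xn[j] - Xn[i])), j) for j in range(n) if j != i]
        hits = sorted([dj for dj in dists if y[dj[1]] == y[i]])[:k]
        misses = sorted([dj for dj in dists if y[dj[1]] != y[i]])[:k]
        for _, j in hits:
            w -= np.abs(Xn[j] - Xn[i])
        for _, j in misses:
            w += np.abs(Xn[j] - Xn[i])
    return w / (n * k)


class TestReliefF:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.full(12, 3.0), rng.random(12)])
        y = np.array([0, 1] * 6)
        fm = FeatureMatrix(X=X, y=y)
        w = relieff_scores(fm, k_neighbors=2).scores
        assert w[0] == 0.0

    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(7)
        sep = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        noise = rng.random(6)
        fm = FeatureMatrix(X=np.column_stack([sep, noise]),
                           y=np.array([0, 0, 0, 1, 1, 1]))
        w = relieff_scores(fm, k_neighbors=1).scores
        assert w[0] > w[1]

    def test_exhaustive_equals_brute_force(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            X = rng.random((10, 4))
            y = np.array([0] * 5 + [1] * 5)
            fm = FeatureMatrix(X=X, y=y)
            w = relieff_scores(fm, k_neighbors=2).scores
            np.testing.assert_allclose(w, brute_force_relieff(X, y, 2), atol=1e-12)

    def test_feature_permutation_symmetry(self):
        rng = np.random.default_rng(9)
        X = rng.random((20, 5))
        y = np.array([0, 1] * 10)
        w = relieff_scores(FeatureMatrix(X=X, y=y), k_neighbors=3).scores
        perm = [4, 2, 0, 3, 1]
        w_p = relieff_scores(FeatureMatrix(X=X[:, perm], y=y), k_neighbors=3).scores
        np.testing.assert_allclose(w_p, w[perm])

    def test_small_class_rejected(self):
        fm = two_group_fm([1, 2], [3, 4, 5, 6])
        with pytest.raises(ValueError):
            relieff_scores(fm, k_neighbors=3)


class TestMRMR:
    def test_first_pick_is_max_relevance(self):
        rng = np.random.default_rng(10)
        y = np.array([0] * 50 + [1] * 50)
        X = np.column_stack([rng.random(100), y + rng.normal(0, 0.1, 100),
                             rng.random(100)])
        sel = mrmr_select(FeatureMatrix(X=X, y=y), n_select=3)
        assert sel.selected_order[0] == int(np.argmax(sel.scores))
        assert sel.selected_order[0] == 1

    def test_redundant_copy_deferred(self):
        # feature 1 duplicates feature 0 (most relevant); feature 2 is weakly
        # relevant but independent -> greedy order must be (0, 2, 1)
        rng = np.random.default_rng(11)
        y = np.array([0] * 60 + [1] * 60)
        strong = y + rng.normal(0, 0.3, 120)
        weak = 0.4 * y + rng.normal(0, 1.0, 120)
        X = np.column_stack([strong, strong, weak])
        sel = mrmr_select(FeatureMatrix(X=X, y=y), n_select=3)
        assert list(sel.selected_order) == [0, 2, 1]

    def test_self_mi_is_maximal(self):
        from bladekit.dfa import _binned_mi, _discretize

        rng = np.random.default_rng(12)
        X = rng.random((80, 4))
        d = [_discretize(X[:, j], 10) for j in range(4)]
        for j in range(4):
            self_mi = _binned_mi(d[j], d[j])
            for k in range(4):
                assert self_mi >= _binned_mi(d[j], d[k]) - 1e-12

    def test_without_redundancy_reduces_to_relevance_order(self):
        # independent features: redundancy ~ equal, order tracks relevance
        rng = np.random.default_rng(13)
        y = np.array([0] * 100 + [1] * 100)
        X = np.column_stack([y + rng.normal(0, s, 200) for s in (0.2, 0.6, 2.0, 8.0)])
        sel = mrmr_select(FeatureMatrix(X=X, y=y), n_select=4)
        assert sel.selected_order[0] == int(np.argmax(sel.scores))
        rel_order = np.argsort(-sel.scores, kind="stable")
        assert sel.selected_order[0] == rel_order[0]


class TestROC:
    def test_perfect_separation(self):
        auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_three_of_four_pairs_concordant(self):
        auc, _ = roc_auc([0.9, 0.3, 0.4, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(14)
        scores = rng.random(50)
        labels = (rng.random(50) > 0.5).astype(int)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(scores, 1 - labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_trapezoid_equals_pair_count_with_ties(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            scores = rng.integers(0, 5, 30).astype(float)  # forced ties
            labels = (rng.random(30) > 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            auc, pts = roc_auc(scores, labels)
            fpr = np.array([p[0] for p in pts])
            tpr = np.array([p[1] for p in pts])
            assert abs(np.trapezoid(tpr, fpr) - auc) < 1e-12

    def test_single_class_undefined(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([0.1, 0.2], [1, 1])


class TestConfusionMetrics:
    def test_hand_computed(self):
        m = confusion_metrics({"TP": 3, "FP": 1, "FN": 2, "TN": 4})
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["f1"] == pytest.approx(0.6667, abs=1e-4)

    def test_perfect_classifier(self):
        m = confusion_metrics({"TP": 5, "FP": 0, "FN": 0, "TN": 5})
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "precision", "f1"))

    def test_zero_denominator_flagged_nan(self):
        m = confusion_metrics({"TP": 0, "FP": 2, "FN": 0, "TN": 3})
        assert np.isnan(m["sensitivity"])
        assert "sensitivity" in m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics({"TP": -1, "FP": 0, "FN": 0, "TN": 1})


class TestTrainEval:
    @pytest.fixture
    def separable(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 0.2, (40, 3)), rng.normal(3, 0.2, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        return FeatureMatrix(X=X, y=y)

    @pytest.mark.parametrize("clf", ["svm", "decision_tree", "knn"])
    def test_separable_blobs_perfect(self, separable, clf):
        rep = train_eval(separable, classifier=clf, seed=0)
        assert rep.auc == 1.0 and rep.accuracy == 1.0

    def test_same_seed_identical_report(self, separable):
        r1 = train_eval(separable, classifier="svm", selection="anova_f",
                        k_features=2, seed=5)
        r2 = train_eval(separable, classifier="svm", selection="anova_f",
                        k_features=2, seed=5)
        assert r1.to_dict() == r2.to_dict()

    def test_permuted_labels_null_auc(self):
        rng = np.random.default_rng(17)
        # average over independently generated null datasets: dataset-level
        # spurious correlations make a single dataset's AUC too variable
        aucs = []
        for ds in range(8):
            X = rng.standard_normal((200, 10))
            y = np.array([0] * 100 + [1] * 100)
            fm = FeatureMatrix(X=X, y=rng.permutation(y))
            aucs.append(train_eval(fm, classifier="knn", seed=ds).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_selection_uses_training_fold_only(self):
        # the selected features must be reproducible from the training fold
        # alone — no information from held-out rows enters the scorer
        rng = np.random.default_rng(18)
        X = rng.standard_normal((60, 8))
        y = np.array([0, 1] * 30)
        fm = FeatureMatrix(X=X, y=y)
        rep = train_eval(fm, classifier="knn", selection="anova_f", k_features=3, seed=3)
        from sklearn.model_selection import train_test_split

        X_tr, _, y_tr, _ = train_test_split(X, y, test_size=0.3, random_state=3,
                                            stratify=y)
        expected = anova_f_scores(FeatureMatrix(X=X_tr, y=y_tr)).ranking[:3]
        assert rep.selected_features == list(expected)

    def test_k_features_required_with_selection(self, separable):
        with pytest.raises(ConfigError):
            train_eval(separable, selection="anova_f")

    def test_too_many_features_requested(self, separable):
        with pytest.raises(ValueError):
            train_eval(separable, selection="anova_f", k_features=99)
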