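"""Fréchet distance against closed forms and a brute-force oracle;
confusion-matrix metrics against hand counts and scikit-learn."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import sqrtm

from somnogan.evaluation import (
    ConfusionCounts, FeatureStats, PixelFeatures, RandomConvFeatures,
    classification_metrics, confusion_matrix, extract_features, f1_score,
    frechet_distance, frechet_from_images,
)


def _stats(u, S, n=10):
    return FeatureStats(u=np.atleast_1d(np.asarray(u, float)),
                        S=np.atleast_2d(np.asarray(S, float)), n=n)


class TestFrechet:
    def test_identical_stats_zero(self):
        s = _stats([0.5, -1.0], [[2.0, 0.3], [0.3, 1.0]])
        assert frechet_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_mean_shift(self):
        # (mu1-mu2)^2 + (s1-s2)^2 = 1 + 0
        assert frechet_distance(_stats(0.0, 1.0), _stats(1.0, 1.0)) == \
            pytest.approx(1.0, abs=1e-8)

    def test_univariate_variance_change(self):
        # 0 + 1 + 4 - 2*sqrt(4) = 1
        assert frechet_distance(_stats(0.0, 1.0), _stats(0.0, 4.0)) == \
            pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("d", [2, 3, 4, 5])
    def test_matches_sqrtm_oracle_on_random_psd(self, d):
        """Independent route: scipy.linalg.sqrtm of the (non-symmetric)
        product matrix."""
        rng = np.random.default_rng(d)
        for _ in range(5):
            a = rng.normal(size=(d + 3, d))
            b = rng.normal(size=(d + 3, d))
            sx, sg = a.T @ a, b.T @ b
            ux, ug = rng.normal(size=d), rng.normal(size=d)
            expected = (np.sum((ux - ug) ** 2) + np.trace(sx) + np.trace(sg)
                        - 2 * np.trace(np.real(sqrtm(sx @ sg))))
            got = frechet_distance(_stats(ux, sx), _stats(ug, sg))
            assert got == pytest.approx(max(expected, 0.0), rel=1e-6, abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3)) + 1.0
        sa = FeatureStats.from_features(a)
        sb = FeatureStats.from_features(b)
        assert frechet_distance(sa, sb) == pytest.approx(
            frechet_distance(sb, sa), rel=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            frechet_distance(_stats([0.0], [[1.0]]),
                             _stats([0.0, 0.0], np.eye(2)))

    def test_from_features_uses_unbiased_covariance(self):
        x = np.array([[1.0], [3.0]])
        s = FeatureStats.from_features(x)
        assert s.u[0] == 2.0
        assert s.S[0, 0] == 2.0  # ddof=1: ((1-2)^2+(3-2)^2)/(2-1)
        with pytest.raises(ValueError):
            FeatureStats.from_features(np.array([[1.0]]))


class TestExtractors:
    def test_row_count_and_identity_rows(self):
        rng = np.random.default_rng(0)
        imgs = rng.normal(size=(10, 8, 8, 3))
        ext = RandomConvFeatures()
        feats = extract_features(imgs, ext)
        assert feats.shape[0] == 10
        same = np.repeat(imgs[:1], 4, axis=0)
        f2 = extract_features(same, ext)
        assert np.allclose(f2, f2[0])

    def test_pixel_extractor_reproduces_raw_pixels(self):
        imgs = np.arange(8.0).reshape(2, 2, 2, 1)
        feats = extract_features(imgs, PixelFeatures())
        assert np.array_equal(feats, imgs.reshape(2, 4))

    def test_random_conv_deterministic_across_instances(self):
        imgs = np.random.default_rng(1).normal(size=(3, 16, 16, 3))
        a = RandomConvFeatures(seed=0)(imgs)
        b = RandomConvFeatures(seed=0)(imgs)
        assert np.array_equal(a, b)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.empty((0, 8, 8, 3)), PixelFeatures())

    def test_frechet_from_images_smaller_for_closer_sets(self):
        rng = np.random.default_rng(2)
        real = rng.normal(0, 0.2, size=(40, 8, 8, 3))
        near = rng.normal(0, 0.2, size=(40, 8, 8, 3))
        far = rng.normal(2.0, 0.2, size=(40, 8, 8, 3))
        ext = RandomConvFeatures()
        assert frechet_from_images(real, near, ext) < \
            frechet_from_images(real, far, ext)


class TestConfusion:
    def test_hand_count(self):
        cm = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"],
                              ["A", "B"])
        assert np.array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_perfect_predictions_normalise_to_identity(self):
        y = ["A", "B", "C", "A", "C"]
        cm = confusion_matrix(y, y, ["A", "B", "C"])
        assert np.allclose(cm.normalized(), np.eye(3))

    def test_empty_inputs(self):
        cm = confusion_matrix([], [], ["A", "B"])
        assert np.array_equal(cm.counts, np.zeros((2, 2)))

    def test_validation(self):
        with pytest.raises(ValueError):
            confusion_matrix(["A"], ["A", "B"], ["A", "B"])
        with pytest.raises(ValueError):
            confusion_matrix(["A"], ["Z"], ["A", "B"])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        classes = list("ABCD")
        y_true = rng.choice(classes, 200).tolist()
        y_pred = rng.choice(classes, 200).tolist()
        cm = confusion_matrix(y_true, y_pred, classes)
        sums = cm.normalized().sum(axis=1)
        nonempty = cm.counts.sum(axis=1) > 0
        assert np.allclose(sums[nonempty], 1.0, atol=1e-9)


class TestMetrics:
    def test_f1_reproduces_reported_stager_values(self):
        """Published N1 precision/recall before/after augmentation give
        F1 = 0.52 and 0.69 at two decimals."""
        assert round(f1_score(0.65, 0.44), 2) == 0.52
        assert round(f1_score(0.74, 0.64), 2) == 0.69

    def test_binary_accuracy(self):
        # TP=3, FN=1 / FP=1, TN=5 -> Acc 0.8
        cm = ConfusionCounts(np.array([[3, 1], [1, 5]]), ["pos", "neg"])
        rep = classification_metrics(cm)
        assert rep.accuracy == pytest.approx(0.8)

    @given(st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=25)
    def test_equal_precision_recall_gives_f1_equal(self, p):
        assert f1_score(p, p) == pytest.approx(p)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_f1_between_min_and_max(self, p, r):
        f = f1_score(p, r)
        assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_zero_support_class_reports_nan(self):
        cm = ConfusionCounts(np.array([[5, 0, 0], [0, 3, 0], [0, 0, 0]]),
                             ["A", "B", "C"])
        rep = classification_metrics(cm)
        assert np.isnan(rep.per_class["C"]["recall"])
        assert np.isnan(rep.per_class["C"]["f1"])
        assert rep.accuracy == pytest.approx(1.0)

    def test_all_zero_counts_give_nan_not_exception(self):
        cm = ConfusionCounts(np.zeros((2, 2), dtype=int), ["A", "B"])
        rep = classification_metrics(cm)
        assert np.isnan(rep.accuracy)

    def test_micro_accuracy_is_support_weighted_recall(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, size=(4, 4))
        cm = ConfusionCounts(counts, list("WXYZ"))
        rep = classification_metrics(cm)
        support = counts.sum(axis=1)
        recalls = np.array([rep.per_class[c]["recall"] for c in "WXYZ"])
        weighted = np.nansum(recalls * support) / counts.sum()
        assert rep.accuracy == pytest.approx(weighted)

    def test_against_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(3)
        classes = list("ABC")
        y_true = rng.choice(classes, 100).tolist()
        y_pred = rng.choice(classes, 100).tolist()
        rep = classification_metrics(confusion_matrix(y_true, y_pred, classes))
        p, r, f, s = precision_recall_fscore_support(y_true, y_pred,
                                                     labels=classes,
                                                     zero_division=np.nan)
        for i, c in enumerate(classes):
            assert rep.per_class[c]["precision"] == pytest.approx(p[i])
            assert rep.per_class[c]["recall"] == pytest.approx(r[i])
            assert rep.per_class[c]["f1"] == pytest.approx(f[i])
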