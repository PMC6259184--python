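import numpy as np
import pytest

from pathwaykit import ConfigurationError, distance, ifs, jackknife, nn_predict

from oracles import brute_loocv_nn


class TestDistance:
    def test_cosine_identical_direction_is_zero(self):
        assert distance(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == pytest.approx(0.0)

    def test_cosine_scale_invariance(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.4, 0.1, 2.0])
        assert distance(a, b) == pytest.approx(distance(5 * a, 0.3 * b))

    def test_cosine_orthogonal_is_one_and_opposite_is_two(self):
        assert distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)
        assert distance(np.array([1.0, 0.0]), np.array([-1.0, 0.0])) == pytest.approx(2.0)

    def test_zero_vector_convention(self):
        assert distance(np.zeros(3), np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)
        assert distance(np.zeros(3), np.zeros(3)) == pytest.approx(1.0)

    def test_euclidean_switch(self):
        got = distance(np.array([0.0, 0.0]), np.array([3.0, 4.0]), metric="euclidean")
        assert got == pytest.approx(5.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            distance(np.zeros(2), np.zeros(3))


class TestNNPredict:
    def test_nearest_label_returned(self):
        train = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert nn_predict(np.array([0.9, 0.1]), train, np.array([1, 0])) == 1
        assert nn_predict(np.array([0.1, 0.9]), train, np.array([1, 0])) == 0

    def test_tie_breaks_to_lower_sample_index(self):
        train = np.array([[1.0, 0.0], [2.0, 0.0]])   # same direction: both distance 0
        assert nn_predict(np.array([3.0, 0.0]), train, np.array([0, 1])) == 0

    def test_empty_training_set_raises(self):
        with pytest.raises(ConfigurationError):
            nn_predict(np.zeros(2), np.zeros((0, 2)), np.zeros(0, dtype=int))


class TestJackknife:
    def test_twin_clusters_classified_perfectly(self):
        x = np.array([[1.0, 0.0], [1.0, 0.01], [0.0, 1.0], [0.01, 1.0]])
        y = np.array([1, 1, 0, 0])
        assert jackknife(x, y) == pytest.approx((1.0, 1.0, 1.0))

    def test_lone_positive_always_missed(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.9]])
        y = np.array([1, 0, 0])
        pos_acc, neg_acc, total = jackknife(x, y)
        assert pos_acc == 0.0
        assert neg_acc == 1.0
        assert total == pytest.approx(2 / 3)

    def test_feature_restriction_changes_outcome(self):
        # feature 0 separates the classes; feature 1 is anti-informative
        x = np.array([[1.0, 0.0, 5.0], [1.1, 0.0, 0.1], [0.0, 1.0, 5.1], [0.0, 1.1, 0.0]])
        y = np.array([1, 1, 0, 0])
        assert jackknife(x, y, feature_idx=[0, 1], metric="euclidean")[2] == 1.0
        assert jackknife(x, y, feature_idx=[2], metric="euclidean")[2] == 0.0

    @pytest.mark.parametrize("metric", ["cosine", "euclidean"])
    def test_matches_brute_loocv(self, metric):
        rng = np.random.default_rng(31)
        for _ in range(10):
            m = int(rng.integers(6, 50))
            x = rng.normal(size=(m, 4))
            y = (rng.random(m) < 0.4).astype(int)
            if y.sum() in (0, m):
                y[0] = 1 - y[0]
            got = jackknife(x, y, metric=metric)
            want = brute_loocv_nn(x, y, lambda a, b: distance(a, b, metric=metric))
            assert got == pytest.approx(want)


class TestIFS:
    def _separable(self):
        rng = np.random.default_rng(12)
        y = np.array([0] * 12 + [1] * 12)
        signal = np.where(y == 1, 5.0, -5.0)[:, None]
        noise = rng.normal(size=(24, 3))
        x = np.hstack([signal + 0.1 * rng.normal(size=(24, 1)), noise])
        return x, y

    def test_optimal_is_smallest_maximizing_prefix(self):
        x, y = self._separable()
        res = ifs(x, y, order=[0, 1, 2, 3], metric="euclidean",
                  feature_names=["sig", "n1", "n2", "n3"])
        assert res.optimal_size == 1
        assert res.optimal_features == ["sig"]
        assert res.optimal_metrics[0] == 1.0
        assert len(res.prefix_sizes) == 4

    def test_max_prefix_truncates(self):
        x, y = self._separable()
        res = ifs(x, y, order=[1, 0, 2, 3], max_prefix=2, metric="euclidean")
        assert list(res.prefix_sizes) == [1, 2]

    def test_prefix_metrics_match_direct_jackknife(self):
        x, y = self._separable()
        order = [2, 0, 3, 1]
        res = ifs(x, y, order=order, metric="euclidean")
        for i, size in enumerate(res.prefix_sizes):
            direct = jackknife(x, y, feature_idx=order[:size], metric="euclidean")
            assert (res.positive_accuracy[i], res.negative_accuracy[i],
                    res.total_accuracy[i]) == pytest.approx(direct)

    def test_to_frame_columns(self):
        x, y = self._separable()
        frame = ifs(x, y, order=[0, 1], metric="euclidean").to_frame()
        assert list(frame.columns) == ["prefix_size", "pos_acc", "neg_acc", "total_acc"]
        assert len(frame) == 2

    def test_invalid_max_prefix_rejected(self):
        x, y = self._separable()
        with pytest.raises(ConfigurationError):
            ifs(x, y, order=[0], max_prefix=0)
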