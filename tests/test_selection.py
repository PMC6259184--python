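import numpy as np
import pytest

from pathwaykit import (
    ConfigurationError,
    build_registry,
    discretize,
    maxrel_slice,
    mrmr_rank,
    mutual_information,
)


class TestMutualInformation:
    def test_identical_binary_vectors_give_ln2(self):
        x = np.array([0, 1] * 10)
        assert mutual_information(x, x) == pytest.approx(np.log(2))

    def test_independent_vectors_give_zero(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_plugin_value_matches_direct_summation(self):
        # joint counts: (x=0,y=0)=30, (0,1)=20, (1,0)=20, (1,1)=30
        x = np.array([0] * 50 + [1] * 50)
        y = np.array([0] * 30 + [1] * 20 + [0] * 20 + [1] * 30)
        expected = sum(
            (c / 100) * np.log((c / 100) / 0.25)
            for c in (30, 20, 20, 30)
        )
        assert mutual_information(x, y) == pytest.approx(expected)
        assert expected == pytest.approx(0.6 * np.log(1.2) + 0.4 * np.log(0.8))

    def test_shape_validation(self):
        with pytest.raises(ConfigurationError):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))


class TestDiscretize:
    def test_three_bins_around_mean(self):
        m = np.array([[0.0], [10.0], [20.0]])
        table = discretize(m, ["f"], np.array([0, 0, 1]))
        # mu = 10, sigma = sqrt(200/3) ~ 8.16
        assert table.bins[:, 0].tolist() == [-1, 0, 1]

    def test_constant_column_is_all_zero(self):
        m = np.array([[5.0], [5.0], [5.0]])
        table = discretize(m, ["f"], np.array([0, 1, 1]))
        assert np.all(table.bins == 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize(np.array([[np.nan]]), ["f"], np.array([1]))


def _toy_table():
    """Two duplicated strong features plus one weaker independent one.

    All three are noisy copies of the labels; the flip sets are disjoint,
    so the duplicates are fully redundant with each other while the
    weaker feature carries partly independent evidence.
    """
    y = np.array([0] * 30 + [1] * 30)
    f0 = y.copy()
    f0[[0, 1, 2, 30, 31, 32]] ^= 1        # 6 flips, balanced across classes
    f1 = f0.copy()                        # exact duplicate (fully redundant)
    f2 = y.copy()
    f2[[10, 11, 12, 13, 14, 40, 41, 42, 43, 44]] ^= 1   # 10 disjoint flips
    bins = np.stack([f0, f1, f2], axis=1).astype(np.int8)
    from pathwaykit.selection import DiscretizedTable

    return DiscretizedTable(bins=bins, labels=y, feature_names=["dup_a", "dup_b", "noisy"])


class TestMrmr:
    def test_round_one_is_argmax_relevance_and_duplicate_deferred(self):
        table = _toy_table()
        ranking = mrmr_rank(table)
        # dup_a and dup_b tie on relevance; tie breaks to the lower index
        assert ranking.mrmr_order[0] == 0
        # the exact duplicate is fully redundant, so the noisy feature
        # outranks it in round 2 even though its relevance is lower
        assert ranking.mrmr_order[1] == 2
        assert ranking.mrmr_order[2] == 1
        # MaxRel, by contrast, keeps the duplicates adjacent
        assert ranking.maxrel_order[:2] == [0, 1]

    def test_full_ordering_is_a_permutation(self):
        ranking = mrmr_rank(_toy_table())
        assert sorted(ranking.mrmr_order) == [0, 1, 2]
        assert sorted(ranking.maxrel_order) == [0, 1, 2]
        assert len(ranking.mrmr_scores) == 3

    def test_sample_permutation_invariance(self):
        table = _toy_table()
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(table.labels))
        from pathwaykit.selection import DiscretizedTable

        shuffled = DiscretizedTable(
            bins=table.bins[perm], labels=table.labels[perm], feature_names=table.feature_names
        )
        a, b = mrmr_rank(table), mrmr_rank(shuffled)
        assert a.mrmr_order == b.mrmr_order
        assert a.maxrel_order == b.maxrel_order
        assert a.relevance == pytest.approx(b.relevance)

    def test_quotient_criterion_runs_and_differs_in_scores(self):
        table = _toy_table()
        diff = mrmr_rank(table, criterion="difference")
        quot = mrmr_rank(table, criterion="quotient")
        assert sorted(quot.mrmr_order) == [0, 1, 2]
        assert quot.mrmr_scores != diff.mrmr_scores

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ConfigurationError):
            mrmr_rank(_toy_table(), criterion="product")


class TestMaxrelSlice:
    def test_full_registry_slice_is_35(self, registry):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(40, 352))
        y = np.array([0, 1] * 20)
        table = discretize(m, list(registry.names), y)
        names = maxrel_slice(mrmr_rank(table), fraction=0.10)
        assert len(names) == 35

    def test_floor_of_fraction_times_n(self):
        table = _toy_table()
        assert len(maxrel_slice(mrmr_rank(table), fraction=0.9)) == 2
        with pytest.raises(ConfigurationError):
            maxrel_slice(mrmr_rank(table), fraction=0.0)
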