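"""Contribution scoring, normalization, channel selection and stability arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eegcam.attribution import (
    ChannelSubset,
    ContributionVector,
    aggregate,
    channel_means,
    class_contributions,
    normalize,
    pearson,
    select_channels,
    subset_stability,
    task_contribution,
)
from eegcam.io import MontageMap


class TestChannelMeans:
    def test_constant_map(self):
        np.testing.assert_allclose(channel_means(np.full((128, 32), 0.4)), 0.4)

    def test_linear_ramp_column(self):
        m = np.zeros((128, 32))
        m[:, 5] = np.arange(128) / 127.0
        assert channel_means(m)[5] == pytest.approx(0.5)

    def test_zero_map(self):
        np.testing.assert_array_equal(channel_means(np.zeros((128, 32))), np.zeros(32))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="map"):
            channel_means(np.zeros((128, 30)))


class TestAggregate:
    def test_single_sample_per_class(self):
        vecs = np.arange(64, dtype=float).reshape(2, 32)
        out = aggregate(vecs, np.array([0, 1]))
        np.testing.assert_array_equal(out[0], vecs[0])
        np.testing.assert_array_equal(out[1], vecs[1])

    def test_duplication_invariance(self):
        rng = np.random.default_rng(0)
        vecs = rng.random((6, 32))
        labels = np.array([0, 0, 1, 1, 2, 2])
        once = aggregate(vecs, labels)
        twice = aggregate(np.vstack([vecs, vecs]), np.concatenate([labels, labels]))
        for c in once:
            np.testing.assert_allclose(once[c], twice[c])

    def test_two_sample_mean(self):
        vecs = np.vstack([np.zeros(32), np.ones(32)])
        out = aggregate(vecs, np.array([0, 0]))
        np.testing.assert_allclose(out[0], 0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="zero samples"):
            aggregate(np.zeros((2, 32)), np.array([0, 0]), classes=[0, 1])


class TestNormalize:
    def test_min_max_example(self):
        raw = np.linspace(2.0, 6.0, 32)
        cv = normalize(raw)
        assert cv.scores.min() == 0.0 and cv.scores.max() == 1.0
        assert cv.scores[np.argmin(np.abs(raw - 4.0))] == pytest.approx(0.5, abs=0.02)

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(1)
        x = rng.random(32)
        x[0], x[1] = 0.0, 1.0
        np.testing.assert_allclose(normalize(x).scores, x)

    def test_constant_input_degenerate(self):
        cv = normalize(np.full(32, 3.3))
        assert cv.degenerate
        np.testing.assert_array_equal(cv.scores, np.zeros(32))

    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_positive_affine_invariance(self, a, b):
        x = np.random.default_rng(42).random(32) * 10.0
        np.testing.assert_allclose(normalize(a * x + b).scores, normalize(x).scores, atol=1e-9)


class TestSelectChannels:
    def test_zero_scores_empty_subset(self):
        cv = ContributionVector(np.zeros(32))
        assert len(select_channels(cv, 0.3)) == 0

    def test_threshold_zero_keeps_strictly_positive(self):
        scores = np.zeros(32)
        scores[[4, 9]] = 0.7
        subset = select_channels(ContributionVector(scores), 0.0)
        assert subset.channels == (MontageMap.default().name(4), MontageMap.default().name(9))

    def test_strict_inequality_at_threshold(self):
        scores = np.zeros(32)
        scores[10] = 0.5
        scores[11] = 0.51
        subset = select_channels(ContributionVector(scores), 0.5)
        assert subset.channels == (MontageMap.default().name(11),)

    def test_montage_order_and_names(self):
        scores = np.zeros(32)
        scores[[19, 21, 8]] = 1.0
        subset = select_channels(ContributionVector(scores), 0.5)
        assert subset.channels == ("CP5", "F4", "FC6")  # montage (index) order


class TestPearson:
    def test_self_correlation(self):
        v = np.random.default_rng(2).random(32)
        assert pearson(v, v) == pytest.approx(1.0)

    def test_anticorrelation(self):
        v = np.random.default_rng(3).random(32)
        assert pearson(v, -v + 4.2) == pytest.approx(-1.0)

    def test_hand_value_four_decimals(self):
        assert pearson(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])) == pytest.approx(
            0.9820, abs=5e-5
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(5), np.arange(5.0))

    @given(a=st.floats(min_value=0.01, max_value=10.0), b=st.floats(min_value=-5.0, max_value=5.0))
    def test_positive_affine_invariance_and_bounds(self, a, b):
        rng = np.random.default_rng(7)
        v1, v2 = rng.random(16), rng.random(16)
        r = pearson(v1, v2)
        assert -1.0 <= r <= 1.0
        assert pearson(a * v1 + b, v2) == pytest.approx(r, abs=1e-9)


class TestSubsetStability:
    @pytest.fixture()
    def planted_vectors(self):
        """Per-sample channel vectors with channels 19/21 systematically hotter."""
        rng = np.random.default_rng(8)
        vecs = rng.random((400, 32)) * 0.2
        labels = np.arange(400) % 4
        vecs[:, 19] += 0.8 + 0.1 * labels / 3.0
        vecs[:, 21] += 0.7
        return vecs, labels

    def test_full_population_row_is_exact(self, planted_vectors):
        vecs, labels = planted_vectors
        report = subset_stability(vecs, labels, [100], seed=0, threshold=0.5)
        full_row = report.rows[-1]
        assert full_row.subset_size == 400
        assert full_row.pcc == 1.0
        assert "F4" in full_row.channels and "FC6" in full_row.channels

    def test_planted_channels_survive_subsampling(self, planted_vectors):
        vecs, labels = planted_vectors
        report = subset_stability(vecs, labels, [50, 100, 200], seed=1, threshold=0.5)
        sizes = [r.subset_size for r in report.rows]
        assert sizes == sorted(sizes)
        for row in report.rows:
            assert "F4" in row.channels and "FC6" in row.channels
            assert row.pcc >= 0.8

    def test_deterministic_under_seed(self, planted_vectors):
        vecs, labels = planted_vectors
        r1 = subset_stability(vecs, labels, [64], seed=5)
        r2 = subset_stability(vecs, labels, [64], seed=5)
        assert [(r.subset_size, r.channels, r.pcc) for r in r1.rows] == [
            (r.subset_size, r.channels, r.pcc) for r in r2.rows
        ]

    def test_oversized_subset_rejected(self, planted_vectors):
        vecs, labels = planted_vectors
        with pytest.raises(ValueError, match="exceeds"):
            subset_stability(vecs, labels, [500], seed=0)


class TestTaskContribution:
    def test_per_class_and_task_vectors_normalized(self, planted_vectors=None):
        rng = np.random.default_rng(9)
        vecs = rng.random((40, 32))
        labels = np.arange(40) % 4
        per_class = class_contributions(vecs, labels)
        assert set(per_class) == {0, 1, 2, 3}
        for cv in per_class.values():
            assert cv.scores.min() == 0.0 and cv.scores.max() == 1.0
            assert cv.n_samples_used == 10
        tc = task_contribution(vecs, labels)
        assert tc.scores.min() == 0.0 and tc.scores.max() == 1.0
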