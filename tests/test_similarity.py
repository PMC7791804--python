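"""Background-model histograms and histogram-intersection similarity maps."""

import numpy as np
import pytest

from pulsemaps import Histogram, SimilarityConfig, histogram_intersection, model_histogram, similarity_map


def brute_force_similarity(qmap, h_m, cfg):
    """Independent per-pixel recomputation (plain loops, no shared code path)."""
    r = cfg.n_kernel_hist // 2
    padded = np.pad(qmap, r, mode="symmetric")
    out = np.zeros(qmap.shape)
    for i in range(qmap.shape[0]):
        for j in range(qmap.shape[1]):
            counts = np.zeros(cfg.n_bins)
            for di in range(cfg.n_kernel_hist):
                for dj in range(cfg.n_kernel_hist):
                    counts[padded[i + di, j + dj]] += 1
            hp = counts / counts.sum()
            out[i, j] = np.minimum(h_m.masses, hp).sum()
    return out


class TestModelHistogram:
    def test_constant_region_single_mass(self):
        qmap = np.full((6, 6), 7, dtype=int)
        h = model_histogram(qmap, np.ones((6, 6), dtype=bool), n_bins=16)
        assert h.masses[7] == 1.0
        assert h.masses.sum() == pytest.approx(1.0)

    def test_half_half_region(self):
        qmap = np.zeros((4, 4), dtype=int)
        qmap[:, 2:] = 1
        h = model_histogram(qmap, np.ones((4, 4), dtype=bool), n_bins=4)
        assert np.allclose(h.masses, [0.5, 0.5, 0.0, 0.0])

    def test_union_is_count_weighted_mixture(self):
        rng = np.random.default_rng(3)
        qmap = rng.integers(0, 8, size=(10, 12))
        m1 = np.zeros_like(qmap, dtype=bool)
        m2 = np.zeros_like(qmap, dtype=bool)
        m1[:4] = True
        m2[7:] = True
        h_union = model_histogram(qmap, m1 | m2, n_bins=8)
        n1, n2 = m1.sum(), m2.sum()
        mix = (n1 * model_histogram(qmap, m1, 8).masses + n2 * model_histogram(qmap, m2, 8).masses) / (n1 + n2)
        assert np.allclose(h_union.masses, mix)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            model_histogram(np.zeros((3, 3), dtype=int), np.zeros((3, 3), dtype=bool), 4)


class TestHistogramIntersection:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(1)
        m = rng.random(16)
        h = Histogram(masses=m / m.sum())
        assert histogram_intersection(h, h) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        a = Histogram(masses=np.array([0.5, 0.5, 0.0, 0.0]))
        b = Histogram(masses=np.array([0.0, 0.0, 0.3, 0.7]))
        assert histogram_intersection(a, b) == 0.0

    def test_three_bin_worked_example(self):
        a = Histogram(masses=np.array([0.5, 0.5, 0.0]))
        b = Histogram(masses=np.array([0.25, 0.25, 0.5]))
        assert histogram_intersection(a, b) == pytest.approx(0.5)

    def test_symmetry_and_total_variation_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.random(16), rng.random(16)
            ha = Histogram(masses=a / a.sum())
            hb = Histogram(masses=b / b.sum())
            eta = histogram_intersection(ha, hb)
            assert eta == pytest.approx(histogram_intersection(hb, ha))
            tv = 0.5 * np.abs(ha.masses - hb.masses).sum()
            assert eta == pytest.approx(1.0 - tv)

    def test_bin_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            histogram_intersection(
                Histogram(masses=np.array([1.0])), Histogram(masses=np.array([0.5, 0.5]))
            )


class TestSimilarityMap:
    def test_matches_brute_force_on_toy_map(self):
        rng = np.random.default_rng(4)
        qmap = rng.integers(0, 8, size=(12, 12))
        cfg = SimilarityConfig(n_bins=8, n_kernel_hist=5)
        h_m = model_histogram(qmap, qmap < 4, n_bins=8)
        out = similarity_map(qmap, h_m, cfg)
        assert np.array_equal(out, brute_force_similarity(qmap, h_m, cfg))

    def test_constant_map_from_model_level_all_ones(self):
        qmap = np.full((8, 8), 3, dtype=int)
        cfg = SimilarityConfig(n_bins=8, n_kernel_hist=5)
        h_m = model_histogram(qmap, np.ones_like(qmap, dtype=bool), 8)
        assert np.all(similarity_map(qmap, h_m, cfg) == 1.0)

    def test_level_absent_from_model_scores_zero(self):
        qmap = np.full((8, 8), 5, dtype=int)
        cfg = SimilarityConfig(n_bins=8, n_kernel_hist=5)
        h_m = Histogram(masses=np.eye(8)[2])  # all model mass at level 2
        assert np.all(similarity_map(qmap, h_m, cfg) == 0.0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        qmap = rng.integers(0, 16, size=(10, 14))
        cfg = SimilarityConfig(n_bins=16, n_kernel_hist=7)
        h_m = model_histogram(qmap, qmap >= 0, 16)
        out = similarity_map(qmap, h_m, cfg)
        assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12

    def test_patch_exceeding_reflection_rejected(self):
        cfg = SimilarityConfig(n_bins=4, n_kernel_hist=31)
        h_m = Histogram(masses=np.full(4, 0.25))
        with pytest.raises(ValueError):
            similarity_map(np.zeros((6, 6), dtype=int), h_m, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimilarityConfig(n_kernel_hist=4)
        with pytest.raises(ValueError):
            SimilarityConfig(padding="zero")
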