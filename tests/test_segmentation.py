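"""Threshold assignment, region decomposition, fitness criteria, K-Means
seeding and the firefly search."""

import numpy as np
import pytest

from gliofire.phantom import PhantomSpec, generate_slice
from gliofire.preprocessing import preprocess_slice
from gliofire.segmentation import (
    FFOConfig,
    _Evaluator,
    assign_clusters,
    decompose_regions,
    fitness,
    firefly_move,
    init_population,
    inter_cluster_distance,
    intra_cluster_distance,
    kmeans_seed,
    optimize_segmentation,
    quantize_intensities,
    segment_entropy,
    segment_image,
)

from conftest import make_fg


def segs_from(values, thresholds, min_fraction=0.05, mask=None):
    fg = make_fg(values, mask)
    labels = assign_clusters(fg, thresholds)
    return decompose_regions(labels, quantize_intensities(fg), fg.brain_area, min_fraction)


class TestAssignClusters:
    def test_nearest_threshold_wins(self):
        fg = make_fg([[100]])
        assert assign_clusters(fg, [90, 120])[0, 0] == 1

    def test_tie_goes_to_lowest_index(self):
        fg = make_fg([[105]])
        assert assign_clusters(fg, [100, 110])[0, 0] == 1

    def test_duplicate_thresholds_are_inert(self):
        fg = make_fg(np.random.default_rng(0).integers(0, 256, (6, 6)))
        labels = assign_clusters(fg, [50, 50])
        assert set(np.unique(labels)) == {1}

    def test_background_pixels_stay_zero(self, hgg_fg):
        labels = assign_clusters(hgg_fg, [50, 150, 250])
        assert np.all(labels[~hgg_fg.brain_mask] == 0)
        assert np.all(labels[hgg_fg.brain_mask] > 0)


class TestDecompose:
    def test_two_bands_two_segments(self):
        values = np.array([[10] * 3, [200] * 3])
        cs = segs_from(values, [10, 200])
        assert cs.L == 2
        assert sorted(s.area for s in cs.segments) == [3, 3]

    def test_disjoint_blobs_same_intensity_become_separate_segments(self):
        # 5x5: two 4-px corner blobs of value 10 within a 200-valued rest;
        # 0.05 x 25 = 1.25 so both blobs exceed the area rule -> L = 3
        values = np.full((5, 5), 200)
        values[:2, :2] = 10
        values[3:, 3:] = 10
        cs = segs_from(values, [10, 200])
        assert cs.L == 3

    def test_uniform_brain_is_single_segment(self):
        cs = segs_from(np.full((6, 6), 77), [77])
        assert cs.L == 1

    def test_small_components_share_residual_id(self):
        # single off-pixels of cluster 1 scattered in cluster 2 territory
        values = np.full((10, 10), 200)
        values[0, 0] = 10
        values[9, 9] = 10
        cs = segs_from(values, [10, 200])
        residuals = [s for s in cs.segments if s.residual]
        assert len(residuals) == 1 and residuals[0].area == 2
        # every brain pixel is covered by exactly one segment
        assert np.all(cs.label_image > 0)


class TestFitnessCriteria:
    def test_intra_zero_for_pure_segments(self):
        cs = segs_from(np.array([[10] * 4, [200] * 4]), [10, 200])
        assert intra_cluster_distance(cs) == 0.0

    def test_intra_hand_value(self):
        # one segment {10,10,20,20}: center 15, mean abs dev 5
        cs = segs_from(np.array([[10, 10, 20, 20]]), [15])
        assert intra_cluster_distance(cs) == pytest.approx(5.0)

    def test_inter_two_centers(self):
        cs = segs_from(np.array([[10] * 4, [200] * 4]), [10, 200])
        assert inter_cluster_distance(cs) == pytest.approx(190.0)

    def test_inter_three_centers_hand_value(self):
        values = np.array([[10] * 6, [50] * 6, [200] * 6])
        cs = segs_from(values, [10, 50, 200])
        assert inter_cluster_distance(cs) == pytest.approx((40 + 40 + 150) / 3)

    def test_inter_single_segment_is_zero(self):
        cs = segs_from(np.full((4, 4), 99), [99])
        assert inter_cluster_distance(cs) == 0.0

    def test_entropy_uniform_segment_zero(self):
        cs = segs_from(np.full((4, 4), 50), [50])
        assert segment_entropy(cs) == 0.0

    def test_entropy_half_half_one_bit(self):
        cs = segs_from(np.array([[10, 10, 20, 20]]), [15])
        assert segment_entropy(cs) == pytest.approx(1.0)

    def test_entropy_four_levels_two_bits(self):
        cs = segs_from(np.array([[10, 20], [30, 40]]), [25])
        assert segment_entropy(cs) == pytest.approx(2.0)

    def test_fitness_zero_for_exact_two_band_solution(self, two_band_fg):
        parts = fitness(two_band_fg, [40, 220])
        assert parts.d_w == 0.0 and parts.e_y == 0.0 and parts.value == 0.0
        assert parts.d_b == pytest.approx(180.0)

    def test_fitness_formula_arithmetic(self):
        from gliofire.segmentation import FitnessParts

        parts = FitnessParts(d_w=5.0, d_b=190.0, e_y=1.0, alpha=1.0,
                             value=(5.0 + 1.0) / (1.0 + 190.0))
        assert parts.value == pytest.approx(0.031414, abs=1e-6)

    def test_misassignment_scores_strictly_worse(self, two_band_fg):
        exact = fitness(two_band_fg, [40, 220]).value
        for s in ([10, 25], [100, 240], [40, 41], [200, 220]):
            labels = assign_clusters(two_band_fg, s)
            brain = two_band_fg.brain_mask
            if len(np.unique(labels[brain])) == 1 or fitness(two_band_fg, s).value > exact:
                continue
            # any split matching the bands exactly ties the optimum
            top = np.unique(labels[:8]); bottom = np.unique(labels[8:])
            assert set(top) != set(bottom)

    def test_components_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(3)
        fg = make_fg(rng.integers(0, 256, (12, 12)))
        for _ in range(10):
            parts = fitness(fg, np.sort(rng.uniform(0, 255, 3)))
            assert parts.d_w >= 0 and parts.d_b >= 0 and parts.e_y >= 0

    def test_fitness_invariant_to_threshold_order(self, two_band_fg):
        a = fitness(two_band_fg, [220, 40]).value
        b = fitness(two_band_fg, [40, 220]).value
        assert a == b

    def test_fast_evaluator_matches_reference_fitness(self, hgg_fg):
        ev = _Evaluator(hgg_fg, 1.0, 0.05)
        rng = np.random.default_rng(4)
        for _ in range(6):
            x = np.sort(rng.uniform(0, 255, 5))
            assert ev(x) == pytest.approx(fitness(hgg_fg, x).value, abs=1e-12)


class TestKMeansSeed:
    def test_recovers_separated_band_means(self, two_band_fg):
        centers = kmeans_seed(two_band_fg, K=2, seed=0)
        np.testing.assert_allclose(centers, [40.0, 220.0], atol=0.5)

    def test_constant_image_jittered(self):
        fg = make_fg(np.full((6, 6), 128))
        centers = kmeans_seed(fg, K=3, seed=0)
        assert centers.size == 3
        np.testing.assert_allclose(centers, 128.0, atol=1.0)

    def test_deterministic(self, hgg_fg):
        a = kmeans_seed(hgg_fg, K=5, seed=11)
        b = kmeans_seed(hgg_fg, K=5, seed=11)
        np.testing.assert_array_equal(a, b)


class TestPopulationAndMoves:
    def test_seeded_fraction_floor(self, two_band_fg):
        cfg = FFOConfig(population_size=150, iterations=1, K=2, seed=0)
        pop = init_population(two_band_fg, cfg)
        assert len(pop) == 150
        seeded = kmeans_seed(two_band_fg, 2, 0)  # all k-means members are near band means
        near = sum(1 for x in pop if np.allclose(np.sort(x), seeded, atol=2.0))
        assert near >= 37  # floor(150/4) seeded members

    def test_small_population_split(self, two_band_fg):
        pop = init_population(two_band_fg, FFOConfig(population_size=4, iterations=1, K=2, seed=0))
        assert len(pop) == 4

    def test_population_reproducible(self, two_band_fg):
        cfg = FFOConfig(population_size=10, iterations=1, K=2, seed=5)
        a = init_population(two_band_fg, cfg)
        b = init_population(two_band_fg, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_full_attraction_limit(self):
        cfg = FFOConfig(population_size=2, iterations=1, K=3, beta0=1.0, gamma=0.0,
                        alpha_rand=0.0, seed=0)
        rng = np.random.default_rng(0)
        x = firefly_move(np.array([0.0, 100.0, 200.0]), np.array([10.0, 90.0, 210.0]),
                         1.0, 0.5, cfg, rng)
        np.testing.assert_allclose(x, [10.0, 90.0, 210.0])

    def test_no_force_limit(self):
        cfg = FFOConfig(population_size=2, iterations=1, K=2, beta0=0.0,
                        alpha_rand=0.0, seed=0)
        rng = np.random.default_rng(0)
        x = firefly_move(np.array([30.0, 70.0]), np.array([10.0, 90.0]), 1.0, 0.5, cfg, rng)
        np.testing.assert_allclose(x, [30.0, 70.0])

    def test_move_output_clamped_and_sorted(self):
        cfg = FFOConfig(population_size=2, iterations=1, K=4, alpha_rand=3.0, seed=0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = firefly_move(rng.uniform(0, 255, 4), rng.uniform(0, 255, 4),
                             2.0, 1.0, cfg, rng)
            assert np.all((x >= 0) & (x <= 255))
            assert np.all(np.diff(x) >= 0)


class TestOptimize:
    def test_trace_monotone_and_best_beats_kmeans_seed(self, two_band_fg):
        cfg = FFOConfig(population_size=10, iterations=20, K=2, seed=1)
        best, trace = optimize_segmentation(two_band_fg, cfg)
        assert all(trace[i + 1] <= trace[i] for i in range(len(trace) - 1))
        seed_fit = fitness(two_band_fg, kmeans_seed(two_band_fg, 2, 0)).value
        assert trace[-1] <= seed_fit + 1e-12

    def test_deterministic_for_fixed_seed(self, two_band_fg):
        cfg = FFOConfig(population_size=8, iterations=10, K=2, seed=3)
        a = optimize_segmentation(two_band_fg, cfg)
        b = optimize_segmentation(two_band_fg, cfg)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_noiseless_three_band_recovers_tissue_partition(self):
        spec = PhantomSpec(image_height=64, image_width=64, noise_sd=0.0,
                           tumor_count=0, band_intensities=(60.0, 130.0, 200.0), seed=2)
        sample = generate_slice(spec)
        fg = preprocess_slice(sample.image, out_shape=(64, 64), equalize=False)
        cfg = FFOConfig(population_size=12, iterations=25, K=3, seed=4)
        segs = segment_image(fg, cfg)
        # compare partitions restricted to the recovered brain mask
        m = fg.brain_mask & sample.brain_mask
        got = segs.label_image[m]
        truth = sample.tissue_labels[m]
        # best label permutation agreement
        agree = 0
        for g in np.unique(got):
            vals, counts = np.unique(truth[got == g], return_counts=True)
            agree += counts.max()
        assert agree / m.sum() >= 0.99

    def test_every_brain_pixel_labeled(self, hgg_fg):
        cfg = FFOConfig(population_size=8, iterations=10, K=4, seed=0)
        segs = segment_image(hgg_fg, cfg)
        assert np.all(segs.label_image[hgg_fg.brain_mask] > 0)
        assert np.all(segs.label_image[~hgg_fg.brain_mask] == 0)

    def test_k1_single_segment(self, two_band_fg):
        cfg = FFOConfig(population_size=4, iterations=3, K=1, seed=0)
        segs = segment_image(two_band_fg, cfg)
        assert segs.L == 1
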