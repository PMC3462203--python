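"""Tests for the probabilistic region-merging segmenter."""

import numpy as np
import pytest

from cepel.kde1d import ValidationError
from cepel.segmentation import (MergeModel, PairFeatures, RegionGraph,
                                ReliabilityCurve, TrainingError,
                                boundary_f_measure, boundary_posterior_map,
                                compute_pair_features, merge_posterior,
                                sample_training_pairs, segment,
                                single_feature_posterior, train_merge_model)
from cepel.synthetic import gen_images, gen_nested_image


@pytest.fixture(scope="module")
def trained_model():
    train = gen_images(5, size=32, n_rects=4, noise_sigma=10.0, seed=42)
    return train_merge_model(train, n_pairs=600, seed=42)


def _two_tone(size=16, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full((size, size), 60.0)
    img[:, size // 2:] = 200.0
    labels = np.zeros((size, size), dtype=np.int64)
    labels[:, size // 2:] = 1
    if noise:
        img = img + noise * rng.standard_normal(img.shape)
    return img, labels


class TestPairFeatures:
    def test_identical_means_zero_brightness(self):
        img = np.tile(np.array([[10.0, 10.0]]), (4, 1))
        labels = np.tile(np.array([[0, 1]]), (4, 1))
        f = compute_pair_features(RegionGraph(img, labels), (0, 1))
        assert f.brightness == 0.0

    def test_equal_variance_zero_texture(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 5, 8)
        img = np.column_stack([col + 10, col + 50])  # same spread, shifted
        labels = np.column_stack([np.zeros(8, int), np.ones(8, int)])
        f = compute_pair_features(RegionGraph(img, labels), (0, 1))
        assert f.texture == pytest.approx(0.0, abs=1e-9)

    def test_nested_regions_zero_arrangement(self):
        img, labels = gen_nested_image(seed=0)
        f = compute_pair_features(RegionGraph(img, labels), (0, 1))
        assert f.arrangement == 0.0

    def test_corner_region_frame_counts_as_outside(self):
        # 2x2 region in the image corner: its corner pixel touches only the
        # frame and its own region, so it is an outside-border pixel, while
        # the other three boundary pixels touch the partner
        img = np.zeros((4, 4))
        labels = np.zeros((4, 4), dtype=np.int64)
        labels[0:2, 0:2] = 1
        f = compute_pair_features(RegionGraph(img, labels), (0, 1))
        assert f.arrangement == pytest.approx(25.0)

    def test_non_adjacent_raises(self):
        labels = np.array([[0, 1, 2]] * 3)
        img = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            compute_pair_features(RegionGraph(img, labels), (0, 2))


class TestRegionGraph:
    def test_merge_bookkeeping_exact(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        labels = (np.arange(64) % 4).reshape(8, 8)
        g = RegionGraph(img, labels)
        g.merge(0, 1, 0.9)
        for rid, reg in g.regions.items():
            vals = img.ravel()[reg.pixels]
            assert reg.mean == pytest.approx(vals.mean(), abs=1e-9)
            assert reg.variance == pytest.approx(vals.var(), abs=1e-9)
            assert reg.size == vals.size

    def test_adjacency_symmetric(self, rng):
        img = rng.uniform(0, 255, (10, 10))
        labels = (np.arange(100) % 7).reshape(10, 10)
        g = RegionGraph(img, labels)
        for a, nbrs in g.adjacency.items():
            for b in nbrs:
                assert a in g.adjacency[b]


class TestMergeModel:
    def test_prior_is_empirical_merge_fraction(self):
        train = gen_images(3, size=32, n_rects=4, noise_sigma=10.0, seed=5)
        model = train_merge_model(train, n_pairs=400, seed=5)
        _, labels = sample_training_pairs(train, 400, seed=5)
        assert model.prior == pytest.approx(labels.mean(), abs=1e-12)

    def test_brightness_separates_when_classes_are_separable(self):
        # huge level gaps and almost no noise: brightness alone decides
        train = gen_images(4, size=32, n_rects=4, gray_step=60,
                           noise_sigma=2.0, texture_sigmas=(0.0,), seed=3)
        model = train_merge_model(train, n_pairs=400, seed=3)
        assert single_feature_posterior(model, "brightness", 0.0) >= 0.95

    def test_label_swap_inverts_posterior(self, trained_model):
        m = trained_model
        swapped = MergeModel(
            class_conditionals={f: (s, d) for f, (d, s)
                                in m.class_conditionals.items()},
            prior=1.0 - m.prior,
            reliability=m.reliability,
        )
        for v in (0.0, 10.0, 30.0):
            p = single_feature_posterior(m, "brightness", v)
            q = single_feature_posterior(swapped, "brightness", v)
            assert q == pytest.approx(1.0 - p, abs=1e-6)

    def test_too_few_pairs_raises(self):
        train = gen_images(1, size=32, n_rects=4, seed=0)
        with pytest.raises(ValidationError):
            train_merge_model(train, n_pairs=50)

    def test_json_round_trip(self, trained_model):
        clone = MergeModel.from_json(trained_model.to_json())
        f = PairFeatures(12.0, 5.0, 40.0, (30, 60))
        assert merge_posterior(f, clone) == pytest.approx(
            merge_posterior(f, trained_model), abs=1e-12)


class TestReliabilityGating:
    @pytest.fixture
    def gated_model(self, trained_model):
        m = trained_model
        return MergeModel(class_conditionals=m.class_conditionals,
                          prior=m.prior,
                          reliability={
                              "brightness": ReliabilityCurve.constant(1.0),
                              "texture": ReliabilityCurve.step(8),
                              "arrangement": ReliabilityCurve.constant(1.0),
                          })

    def test_texture_excluded_below_its_size_threshold(self, gated_model):
        assert gated_model.active_features(7) == ["brightness", "arrangement"]
        assert gated_model.active_features(8) == ["brightness", "texture",
                                                  "arrangement"]

    def test_brightness_only_for_tiny_regions(self, trained_model):
        m = MergeModel(class_conditionals=trained_model.class_conditionals,
                       prior=trained_model.prior,
                       reliability={"brightness": ReliabilityCurve.constant(1.0),
                                    "texture": ReliabilityCurve.step(4),
                                    "arrangement": ReliabilityCurve.step(4)})
        assert m.active_features(3) == ["brightness"]

    def test_all_reliable_equals_full_product(self, gated_model):
        f = PairFeatures(brightness=5.0, texture=2.0, arrangement=50.0,
                         sizes=(20, 30))
        m = gated_model
        lm, ls = m.prior, 1.0 - m.prior
        for feat in ("brightness", "texture", "arrangement"):
            dm, ds = m.class_conditionals[feat]
            lm *= max(float(dm(f.value(feat))), 1e-12)
            ls *= max(float(ds(f.value(feat))), 1e-12)
        assert merge_posterior(f, m) == pytest.approx(lm / (lm + ls), abs=1e-12)


class TestSegment:
    def test_constant_image_single_region(self, trained_model):
        img = np.full((8, 8), 128.0)
        res = segment(img, trained_model)
        assert res.n_regions == 1

    def test_two_tone_image_two_regions(self):
        train = [(np.where(lab == lab[0, 0], 60.0, 200.0)
                  + np.random.default_rng(i).normal(0, 2, lab.shape), lab)
                 for i, (_, lab) in enumerate(
                     gen_images(4, size=24, n_rects=2, seed=9))]
        model = train_merge_model(train, n_pairs=300, seed=9)
        img, truth = _two_tone(16)
        res = segment(img, model)
        assert res.n_regions == 2
        assert boundary_f_measure(res.labels, truth) == 1.0

    def test_merge_count_identity(self, trained_model):
        img, _ = gen_images(1, size=16, noise_sigma=10.0, seed=2)[0]
        res = segment(img, trained_model)
        assert len(res.history) == img.size - res.n_regions
        assert len(res.history) <= img.size - 1

    def test_termination_all_posteriors_below_half(self, trained_model):
        img, _ = gen_images(1, size=16, noise_sigma=10.0, seed=3)[0]
        res = segment(img, trained_model)
        assert all(p < 0.5 for p in res.final_posteriors.values())

    def test_final_posterior_cache_coherent(self, trained_model):
        img, _ = gen_images(1, size=16, noise_sigma=10.0, seed=4)[0]
        res = segment(img, trained_model)
        graph = RegionGraph(img, res.labels)
        for (a, b), cached in res.final_posteriors.items():
            fresh = merge_posterior(compute_pair_features(graph, (a, b)),
                                    trained_model)
            assert fresh == pytest.approx(cached, abs=1e-12)

    def test_homogeneous_first_merge_ordering(self, trained_model):
        img, _ = gen_images(1, size=24, noise_sigma=10.0, seed=6)[0]
        res = segment(img, trained_model)
        post = np.array([h["posterior"] for h in res.history])
        deciles = np.array_split(post, 10)
        means = [d.mean() for d in deciles if d.size]
        assert all(b <= a + 0.05 for a, b in zip(means, means[1:]))


class TestBoundaryMap:
    def test_values_and_threshold_consistency(self, trained_model):
        img, _ = gen_images(1, size=16, noise_sigma=10.0, seed=5)[0]
        res = segment(img, trained_model)
        bmap = boundary_posterior_map(res)
        assert bmap.min() >= 0.0 and bmap.max() <= 1.0
        from skimage.segmentation import find_boundaries
        expected = find_boundaries(res.labels, connectivity=1, mode="thick")
        assert np.array_equal(bmap > 0.5, expected)

    def test_certain_merges_leave_no_trace(self, trained_model):
        img = np.full((8, 8), 77.0)
        res = segment(img, trained_model)
        high = [h for h in res.history if h["posterior"] >= 0.999]
        assert high  # constant image merges are near-certain
        bmap = boundary_posterior_map(res)
        assert bmap.max() <= 1 - min(h["posterior"] for h in res.history) + 1e-12


class TestBoundaryF:
    def test_identical_partitions(self):
        _, labels = gen_images(1, seed=0)[0]
        assert boundary_f_measure(labels, labels) == 1.0

    def test_no_predicted_boundaries(self):
        _, labels = gen_images(1, seed=0)[0]
        assert boundary_f_measure(np.zeros_like(labels), labels) == 0.0

    def test_one_pixel_shift_within_tolerance(self):
        img = np.zeros((20, 20), dtype=np.int64)
        img[:, 10:] = 1
        shifted = np.zeros((20, 20), dtype=np.int64)
        shifted[:, 11:] = 1
        assert boundary_f_measure(shifted, img, tolerance_px=2) == 1.0
        assert boundary_f_measure(shifted, img, tolerance_px=0.5) < 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            boundary_f_measure(np.zeros((4, 4), dtype=int),
                               np.zeros((5, 5), dtype=int))
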