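"""Otsu criterion, exhaustive and CBO thresholding, region extraction."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from lungcbo import segment
from lungcbo.cbo import CBOConfig
from lungcbo.preprocess import compute_histogram


def direct_sigma_b(hist, thresholds, levels=256):
    """Independent per-class summation oracle for the between-class variance."""
    p = np.asarray(hist, float)
    p = p / p.sum()
    edges = [-1] + list(thresholds) + [levels - 1]
    mu_t = sum(n * p[n] for n in range(levels))
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = sum(p[n] for n in range(lo + 1, hi + 1))
        if w > 0:
            mu = sum(n * p[n] for n in range(lo + 1, hi + 1)) / w
            total += w * (mu - mu_t) ** 2
    return total


class TestBetweenClassVariance:
    def test_constant_histogram_zero(self):
        hist = np.zeros(256)
        hist[77] = 1.0
        assert segment.between_class_variance(hist, [100]) == 0.0

    def test_two_delta_symmetry(self):
        hist = np.zeros(256)
        hist[50] = hist[200] = 0.5
        assert segment.between_class_variance(hist, [50]) == pytest.approx(0.25 * 150**2)

    def test_matches_direct_oracle_all_bilevel_thresholds(self):
        rng = np.random.default_rng(0)
        hist = np.zeros(16)
        hist[: 16] = rng.random(16)
        for t in range(15):
            assert segment.between_class_variance(hist, [t]) == pytest.approx(
                direct_sigma_b(hist, [t], levels=16)
            )

    def test_bounded_by_total_variance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            hist = rng.random(256)
            p = hist / hist.sum()
            lv = np.arange(256)
            sigma_t = float(p @ (lv - p @ lv) ** 2)
            t = np.sort(rng.choice(254, size=2, replace=False))
            assert segment.between_class_variance(hist, t) <= sigma_t + 1e-9


class TestOtsuBilevel:
    def test_two_delta_tiebreak_smallest(self):
        hist = np.zeros(256)
        hist[50] = hist[200] = 0.5
        assert segment.otsu_bilevel_exhaustive(hist) == 50

    def test_bimodal_gaussian_mixture(self):
        rng = np.random.default_rng(2)
        samples = np.concatenate([rng.normal(60, 10, 5000), rng.normal(180, 10, 5000)])
        img = np.clip(np.rint(samples), 0, 255).astype(int).reshape(100, 100)
        t = segment.otsu_bilevel_exhaustive(compute_histogram(img))
        assert 90 <= t <= 150

    def test_invariant_to_histogram_scaling(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, 256).astype(float)
        counts[[10, 200]] += 100
        assert segment.otsu_bilevel_exhaustive(counts) == segment.otsu_bilevel_exhaustive(
            counts / counts.sum()
        )

    def test_agrees_with_skimage_reference(self):
        rng = np.random.default_rng(4)
        samples = np.concatenate([rng.normal(70, 15, 2000), rng.normal(190, 12, 2000)])
        img = np.clip(np.rint(samples), 0, 255).astype(np.uint8)
        ours = segment.otsu_bilevel_exhaustive(compute_histogram(img.reshape(-1, 1)))
        assert abs(ours - threshold_otsu(img)) <= 1

    def test_single_level_rejected(self):
        hist = np.zeros(256)
        hist[5] = 1.0
        with pytest.raises(ValueError):
            segment.otsu_bilevel_exhaustive(hist)


class TestCBOThreshold:
    def test_three_delta_matches_exhaustive_pair_scan(self):
        img = np.concatenate([np.full(400, 30), np.full(300, 120), np.full(324, 220)])
        rng = np.random.default_rng(5)
        rng.shuffle(img)
        img = img.reshape(32, 32).astype(np.uint8)
        hist = compute_histogram(img)
        best = max(
            ((t1, t2) for t1 in range(254) for t2 in range(t1 + 1, 255)),
            key=lambda t: segment.between_class_variance(hist, t),
        )
        thr = segment.cbo_multilevel_threshold(
            img, k=2,
            config=CBOConfig(n=20, dims=2, bounds=((0.0, 254.0),) * 2, max_iters=100, seed=0),
        )
        assert segment.between_class_variance(hist, thr) == pytest.approx(
            segment.between_class_variance(hist, best)
        )
        assert 30 <= thr[0] < 120 <= thr[1] < 220

    def test_thresholds_strictly_increasing_in_range(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        thr = segment.cbo_multilevel_threshold(
            img, k=3,
            config=CBOConfig(n=12, dims=3, bounds=((0.0, 254.0),) * 3, max_iters=30, seed=1),
        )
        assert np.all(np.diff(thr) > 0) and thr.min() >= 0 and thr.max() <= 254

    def test_beats_random_threshold_sets(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        hist = compute_histogram(img)
        thr = segment.cbo_multilevel_threshold(img, k=2)
        ours = segment.between_class_variance(hist, thr)
        for _ in range(1000):
            t = np.sort(rng.choice(255, size=2, replace=False))
            assert ours >= segment.between_class_variance(hist, t) - 1e-12

    def test_degenerate_level_count_rejected(self):
        img = np.full((8, 8), 7, dtype=np.uint8)
        img[0, 0] = 200
        with pytest.raises(ValueError):
            segment.cbo_multilevel_threshold(img, k=2)


class TestApplyThresholds:
    def test_two_class_labeling(self):
        img = np.array([[50, 150]])
        assert np.array_equal(segment.apply_thresholds(img, [100]), [[0, 1]])

    def test_label_range(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 256, (16, 16))
        labels = segment.apply_thresholds(img, [60, 120, 200])
        assert set(np.unique(labels)) <= set(range(4))

    def test_boundary_level_belongs_to_lower_class(self):
        assert segment.apply_thresholds(np.array([[100, 101]]), [100]).tolist() == [[0, 1]]


class TestExtractNodules:
    def test_empty_foreground(self):
        assert segment.extract_nodules(np.zeros((8, 8), dtype=int), 1) == []

    def test_solid_square_descriptor(self):
        lab = np.zeros((12, 12), dtype=int)
        lab[2:7, 3:8] = 1
        (region,) = segment.extract_nodules(lab, 1)
        assert region.area == 25
        assert region.centroid == (4.0, 5.0)
        assert region.bbox == (2, 3, 7, 8)
        assert region.equivalent_diameter == pytest.approx(np.sqrt(100 / np.pi))

    def test_diagonal_blobs_merge_under_8_connectivity(self):
        lab = np.zeros((6, 6), dtype=int)
        lab[1, 1] = lab[2, 2] = 1  # touching only diagonally
        assert len(segment.extract_nodules(lab, 1)) == 1

    def test_min_area_filter_and_sorting(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[1:3, 1:3] = 1   # area 4
        lab[10:16, 10:16] = 1  # area 36
        lab[18, 18] = 1     # area 1
        regions = segment.extract_nodules(lab, 1, min_area=2)
        assert [r.area for r in regions] == [36, 4]

    def test_total_area_equals_foreground_when_unfiltered(self):
        rng = np.random.default_rng(9)
        lab = (rng.random((32, 32)) < 0.3).astype(int)
        regions = segment.extract_nodules(lab, 1, min_area=1)
        assert sum(r.area for r in regions) == lab.sum()

    def test_mean_intensity_from_intensity_image(self):
        lab = np.zeros((5, 5), dtype=int)
        lab[1:3, 1:3] = 1
        img = np.arange(25).reshape(5, 5)
        (region,) = segment.extract_nodules(lab, 1, intensity_image=img)
        assert region.mean_intensity == pytest.approx(np.mean([6, 7, 11, 12]))
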