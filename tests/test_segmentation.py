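import numpy as np
import pytest
from scipy import ndimage

from fric import (AnalysisConfig, ImageStack, SyntheticParams,
                  generate_nucleus_pair, label_and_filter, segment_nuclei,
                  select_equatorial_slice, smooth_channel, threshold_auto)
from fric.segmentation import NucleusMask

from conftest import disc_mask


class TestSmoothChannel:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 7.0)
        np.testing.assert_allclose(smooth_channel(img, 5), img)

    def test_point_source_spreads_but_conserves_intensity(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1000.0
        out = smooth_channel(img, 5)
        assert out.max() < 1000.0
        assert out.sum() == pytest.approx(1000.0, rel=1e-6)
        # symmetric blob
        np.testing.assert_allclose(out, out[::-1, :], atol=1e-9)
        np.testing.assert_allclose(out, out[:, ::-1], atol=1e-9)

    def test_matches_direct_convolution_oracle(self):
        """Separable Gaussian filtering equals brute-force 2-D convolution."""
        rng = np.random.default_rng(3)
        img = rng.normal(100, 10, (32, 32))
        sigma = 5 / 2.35
        half = int(4 * sigma + 0.5)
        x = np.arange(-half, half + 1)
        k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
        kernel = np.outer(k1, k1)
        kernel /= kernel.sum()
        expected = ndimage.convolve(img, kernel, mode="reflect")
        np.testing.assert_allclose(smooth_channel(img, 5), expected, atol=1e-9)

    def test_white_noise_variance_decreases(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0, 1, (64, 64))
        assert smooth_channel(img, 5).var() < img.var()

    def test_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            smooth_channel(np.zeros((8, 8)), 0.5)


class TestThresholdAuto:
    def test_separates_two_classes(self):
        img = np.concatenate([np.full(512, 0.2), np.full(512, 0.8)]).reshape(32, 32)
        t = threshold_auto(img)
        assert 0.2 < t < 0.8

    def test_bimodal_matches_between_class_variance_scan(self):
        """Otsu equals an exhaustive scan maximizing between-class variance."""
        rng = np.random.default_rng(42)
        img = np.concatenate([rng.normal(30, 10, 3000),
                              rng.normal(200, 10, 3000)])
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        t = threshold_auto(img.reshape(60, 100))
        assert 60 <= t <= 170
        # brute-force oracle: between-class variance over all 256 thresholds;
        # the returned threshold must attain (numerically) the maximum —
        # within the near-empty gap between modes the objective is flat
        hist = np.bincount(img, minlength=256).astype(float)
        p = hist / hist.sum()

        def between_class_variance(k):
            w0, w1 = p[:k].sum(), p[k:].sum()
            if w0 == 0 or w1 == 0:
                return 0.0
            mu0 = (np.arange(k) * p[:k]).sum() / w0
            mu1 = (np.arange(k, 256) * p[k:]).sum() / w1
            return w0 * w1 * (mu0 - mu1) ** 2

        best_v = max(between_class_variance(k) for k in range(1, 256))
        assert between_class_variance(int(t) + 1) >= best_v * (1 - 1e-3)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_auto(np.full((16, 16), 3.0))


class TestLabelAndFilter:
    def test_diameter_60_kept_40_rejected(self):
        for radius, expected in ((30, 1), (20, 0)):
            mask = disc_mask(radius, pad=10)
            assert len(label_and_filter(mask, min_diameter=50)) == expected

    def test_border_touching_disc_rejected(self):
        mask = disc_mask(30, pad=0)
        assert len(label_and_filter(mask, min_diameter=50)) == 0

    def test_fill_holes_restores_full_area(self):
        mask = disc_mask(30, pad=5)
        holey = mask.copy()
        holey[33:38, 33:38] = False
        kept = label_and_filter(holey, min_diameter=50, fill_holes=True)
        assert len(kept) == 1
        assert kept[0].area == mask.sum()

    def test_min_diameter_monotonicity(self):
        rng = np.random.default_rng(5)
        binary = ndimage.binary_opening(rng.random((128, 128)) > 0.4,
                                        np.ones((5, 5)))
        counts = [len(label_and_filter(binary, d, border_exclude=False))
                  for d in (2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_labels_in_scan_order(self):
        mask = np.zeros((200, 200), bool)
        mask[20:90, 20:90] = True    # upper-left first in scan order
        mask[110:180, 110:180] = True
        kept = label_and_filter(mask, min_diameter=50)
        assert [m.label for m in kept] == [1, 2]
        assert kept[0].centroid[0] < kept[1].centroid[0]


class TestEquatorialSlice:
    def _stack_masks(self, areas):
        """One tracked nucleus: concentric discs of given areas per slice."""
        out = []
        for z, area in enumerate(areas):
            radius = int(np.sqrt(area / np.pi))
            m = np.zeros((160, 160), bool)
            yy, xx = np.mgrid[0:160, 0:160]
            m[(yy - 80) ** 2 + (xx - 80) ** 2 <= radius ** 2] = True
            out.append([NucleusMask(label=1, mask=m, slice_index=z)])
        return out

    def test_largest_area_slice_selected(self):
        selected = select_equatorial_slice(self._stack_masks([800, 1200, 900]))
        assert len(selected) == 1
        assert selected[0].slice_index == 1  # 0-based; the second slice

    def test_single_slice(self):
        selected = select_equatorial_slice(self._stack_masks([1000]))
        assert selected[0].slice_index == 0

    def test_tie_breaks_to_lower_slice(self):
        selected = select_equatorial_slice(self._stack_masks([1000, 1000]))
        assert selected[0].slice_index == 0


class TestSegmentNuclei:
    def _disc_image(self, centers, radius, shape=(300, 300)):
        img = np.full(shape, 20.0)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        for cy, cx in centers:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = 2000.0
        return img

    def test_three_well_separated_discs(self, channel_map, config):
        img = self._disc_image([(70, 70), (70, 220), (220, 150)], 40)
        stack = ImageStack({"euchromatin": img, "total": img})
        res = segment_nuclei(stack, channel_map, config)
        assert len(res.masks) == 3

    def test_small_disc_filtered_by_50px_rule(self, channel_map, config):
        img = self._disc_image([(70, 70), (70, 220)], 40)
        small = self._disc_image([(220, 150)], 15)
        img = np.maximum(img, small)
        stack = ImageStack({"euchromatin": img, "total": img})
        assert len(segment_nuclei(stack, channel_map, config).masks) == 2

    def test_blank_image_gives_empty_result(self, channel_map, config):
        stack = ImageStack({"euchromatin": np.full((128, 128), 5.0),
                            "total": np.full((128, 128), 5.0)})
        assert segment_nuclei(stack, channel_map, config).masks == []

    def test_noiseless_disc_recovered_with_high_jaccard(self, channel_map, config):
        truth = disc_mask(40, pad=30)
        img = np.where(truth, 2000.0, 20.0)
        stack = ImageStack({"euchromatin": img, "total": img})
        res = segment_nuclei(stack, channel_map, config)
        assert len(res.masks) == 1
        seg = res.masks[0].mask
        jaccard = (seg & truth).sum() / (seg | truth).sum()
        assert jaccard >= 0.95
        assert (seg & truth).sum() / truth.sum() >= 0.98

    def test_determinism(self, channel_map, config):
        stack, _ = generate_nucleus_pair(SyntheticParams(), 3)
        a = segment_nuclei(stack, channel_map, config)
        b = segment_nuclei(stack, channel_map, config)
        assert len(a.masks) == len(b.masks)
        for ma, mb in zip(a.masks, b.masks):
            assert ma.label == mb.label
            np.testing.assert_array_equal(ma.mask, mb.mask)
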