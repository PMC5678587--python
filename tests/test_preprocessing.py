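"""Contracts of the crop / downscale / GrabCut / watershed pipeline."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu
from skimage.transform import resize

from leafbench import preprocessing as pp
from leafbench.grabcut import grabcut
from leafbench.preprocessing import (BoundingBox, Marker, crop,
                                     downscale_for_segmentation,
                                     init_rect_from_focus, refine_fullres,
                                     simulate_user)
from leafbench.synthetic import GeneratorConfig

from conftest import make_single_record


class TestCrop:
    def test_full_image_is_identity(self, rng):
        img = rng.integers(0, 255, (50, 80, 3), dtype=np.uint8)
        assert np.array_equal(crop(img, BoundingBox(0, 0, 80, 50)), img)

    def test_output_dimensions(self, rng):
        img = rng.integers(0, 255, (200, 200, 3), dtype=np.uint8)
        out = crop(img, BoundingBox(10, 20, 110, 70))
        assert out.shape == (50, 100, 3)
        assert np.array_equal(out, img[20:70, 10:110])

    def test_gt_bbox_crop_keeps_all_foreground(self, observation_small):
        rec = observation_small[0]
        n_fg = rec.gt_mask.sum()
        cropped_mask = crop(rec.gt_mask.astype(np.uint8), BoundingBox(*rec.gt_bbox))
        assert cropped_mask.sum() == n_fg

    def test_idempotent(self, rng):
        img = rng.integers(0, 255, (60, 90, 3), dtype=np.uint8)
        b = BoundingBox(5, 10, 50, 40)
        once = crop(img, b)
        again = crop(once, BoundingBox(0, 0, b.width, b.height))
        assert np.array_equal(once, again)

    def test_out_of_bounds_rejected(self, rng):
        img = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            crop(img, BoundingBox(0, 0, 41, 40))
        with pytest.raises(ValueError):
            BoundingBox(10, 10, 10, 20)


class TestDownscale:
    @pytest.mark.parametrize("shape,expected", [
        ((600, 800), (300, 400)),
        ((300, 400), (300, 400)),
        ((200, 1000), (80, 400)),
    ])
    def test_longest_side_rule(self, shape, expected):
        img = np.zeros((*shape, 3), dtype=np.uint8)
        low, scale = downscale_for_segmentation(img)
        assert low.shape[:2] == expected
        if shape == expected:
            assert scale == 1.0

    def test_bbox_scale_round_trip(self, observation):
        rec = observation[0]
        low, s = downscale_for_segmentation(rec.pixels)
        x0, y0, x1, y1 = rec.gt_bbox
        mapped = [round(v * s) for v in rec.gt_bbox]
        back = [round(v / s) for v in mapped]
        for orig, rt in zip((x0, y0, x1, y1), back):
            assert abs(orig - rt) <= 1


class TestInitRect:
    def test_centered_fraction(self):
        rect = init_rect_from_focus((200, 150), (400, 300), fraction=0.5)
        assert (rect.width, rect.height) == (200, 150)
        assert (rect.x0 + rect.x1) // 2 == 200

    def test_corner_focus_clipped(self):
        rect = init_rect_from_focus((0, 0), (400, 300), fraction=0.5)
        rect.validate_for((300, 400))
        assert rect.x0 >= 1 and rect.y0 >= 1

    def test_corners_always_outside(self):
        w, h = 400, 300
        for fx in (0, 57, w // 2, w - 1):
            for fy in (0, 33, h // 2, h - 1):
                r = init_rect_from_focus((fx, fy), (w, h), fraction=0.9)
                for cx, cy in ((0, 0), (w - 1, 0), (0, h - 1), (w - 1, h - 1)):
                    inside = r.x0 <= cx < r.x1 and r.y0 <= cy < r.y1
                    assert not inside


def _disc_image(h=300, w=400, r=90):
    yy, xx = np.mgrid[0:h, 0:w]
    gt = ((yy - h // 2) ** 2 + (xx - w // 2) ** 2) < r * r
    img = np.full((h, w, 3), 235, dtype=np.uint8)
    img[gt] = (60, 90, 40)
    noise = np.random.default_rng(0).normal(0, 3, (h, w, 3))
    return np.clip(img + noise, 0, 255).astype(np.uint8), gt


class TestGrabCut:
    def test_high_contrast_disc(self):
        img, gt = _disc_image()
        res = grabcut(img, (100, 50, 300, 250), seed=0)
        assert not res.degenerate
        assert pp.iou(res.mask, gt) >= 0.90

    def test_foreground_marker_is_hard_constraint(self):
        img, gt = _disc_image()
        # a marker in the background corner area, labeled foreground,
        # must come out foreground regardless of the color evidence
        res = grabcut(img, (100, 50, 300, 250),
                      markers=[((40, 150), "foreground")], seed=0)
        assert res.mask[150, 40]

    def test_uniform_image_flagged(self):
        img = np.full((200, 260, 3), 127, dtype=np.uint8)
        res = grabcut(img, (60, 50, 200, 150), seed=0)
        assert res.degenerate

    def test_deterministic(self):
        img, _ = _disc_image()
        a = grabcut(img, (100, 50, 300, 250), seed=3)
        b = grabcut(img, (100, 50, 300, 250), seed=3)
        assert np.array_equal(a.mask, b.mask)

    def test_threshold_oracle_on_binary_contrast(self):
        """On a two-tone fixture the cut agrees with Otsu thresholding up
        to a 2-px boundary band."""
        from scipy import ndimage

        img, gt = _disc_image()
        res = grabcut(img, (100, 50, 300, 250), seed=0)
        lum = img.astype(float).mean(axis=2)
        thresh_mask = lum < threshold_otsu(lum)
        band = ndimage.binary_dilation(gt, iterations=2) & ~ndimage.binary_erosion(
            gt, iterations=2)
        disagree = (res.mask != thresh_mask) & ~band
        assert disagree.mean() < 0.005


class TestSimulateUser:
    def test_accurate_mask_needs_no_markers(self):
        img, gt = _disc_image()
        res = grabcut(img, (100, 50, 300, 250), seed=0)
        markers, mask, final = simulate_user(
            img, BoundingBox(100, 50, 300, 250), res, gt, max_markers=10,
            iou_target=0.9, seed=0)
        assert markers == []
        assert final >= 0.9

    def test_zero_budget_returns_initial(self):
        img, gt = _disc_image()
        res = grabcut(img, (100, 50, 300, 250), seed=0)
        markers, mask, _ = simulate_user(
            img, BoundingBox(100, 50, 300, 250), res, gt, max_markers=0,
            iou_target=1.0, seed=0)
        assert markers == []
        assert np.array_equal(mask, res.mask)

    def test_refinement_never_decreases_iou(self, bank5):
        """On cluttered natural-background fixtures the accepted mask is
        monotone in overlap: final IoU >= initial IoU."""
        import dataclasses

        for i, k in enumerate((0, 3, 4)):
            spec = dataclasses.replace(bank5[k], compoundness=3 if i == 0 else 1)
            rec = make_single_record(spec, "natural", "flash_off", seed=60 + i,
                                     distractors=bank5)
            low, s = downscale_for_segmentation(rec.pixels)
            gt = resize(rec.gt_mask.astype(float), low.shape[:2], order=0) > 0.5
            fx = int(round(rec.focus_point[0] * s))
            fy = int(round(rec.focus_point[1] * s))
            rect = init_rect_from_focus((fx, fy), (low.shape[1], low.shape[0]))
            res = pp.grabcut_iterate(low, rect, [], seed=0)
            initial = pp.iou(res.mask, gt)
            _, _, final = simulate_user(low, rect, res, gt, max_markers=5,
                                        iou_target=0.95, seed=0, iters=2)
            assert final >= initial


class TestRefineFullres:
    def test_identity_at_full_resolution_radius_zero(self, observation_small):
        rec = observation_small[0]
        out = refine_fullres(rec.gt_mask, rec.pixels, erosion_radius=0)
        assert np.array_equal(out, rec.gt_mask)

    def test_output_within_seed_basins(self, observation):
        rec = next(r for r in observation if r.background == "plain")
        low, _ = downscale_for_segmentation(rec.gt_mask.astype(np.uint8) * 255)
        low_mask = low[..., 0] > 127 if low.ndim == 3 else low > 127
        out = refine_fullres(low_mask, rec.pixels, erosion_radius=3)
        assert out.dtype == bool
        assert out.any() and not out.all()


class TestSegment:
    def test_deterministic(self, bank5):
        rec = make_single_record(bank5[2], "plain", "flash_off", seed=70,
                                 distractors=bank5)
        a = pp.segment(rec, seed=5)
        b = pp.segment(rec, seed=5)
        assert np.array_equal(a.mask, b.mask)
        assert a.marker_count == b.marker_count
        assert np.array_equal(a.cropped_image, b.cropped_image)

    def test_crop_matches_mask_bounds_and_fill(self, bank5):
        rec = make_single_record(bank5[1], "plain", "flash_off", seed=71,
                                 distractors=bank5)
        res = pp.segment(rec, seed=0)
        ys, xs = np.nonzero(res.mask)
        assert res.cropped_image.shape[:2] == (ys.max() + 1 - ys.min(),
                                               xs.max() + 1 - xs.min())
        inner = crop(res.mask.astype(np.uint8),
                     BoundingBox(xs.min(), ys.min(), xs.max() + 1, ys.max() + 1))
        outside = res.cropped_image[inner == 0]
        assert (outside == 128).all()

    def test_marker_count_logged(self, bank5):
        rec = make_single_record(bank5[1], "plain", "flash_off", seed=72,
                                 distractors=bank5)
        res = pp.segment(rec, seed=0)
        assert res.marker_count == len(res.markers)
        assert res.marker_count >= 0
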