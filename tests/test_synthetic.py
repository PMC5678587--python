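"""Generator contracts: determinism, ground-truth consistency, and the
photometric orderings the study conditions rely on."""

import numpy as np
import pytest
from scipy import ndimage

from leafbench import synthetic
from leafbench.synthetic import (GeneratorConfig, composite, generate_dataset,
                                 generate_observation, generate_species_bank,
                                 render_backlight, render_leaf, separability,
                                 shape_descriptor, venation_contrast)

from conftest import make_single_record


class TestSpeciesBank:
    def test_bank_size_and_determinism(self):
        bank = generate_species_bank(17, seed=1)
        assert len(bank) == 17
        again = generate_species_bank(17, seed=1)
        assert bank == again

    def test_different_seeds_differ_per_species(self):
        a = generate_species_bank(5, seed=1)
        b = generate_species_bank(5, seed=2)
        for sa, sb in zip(a, b):
            assert sa.shape_params() != sb.shape_params()

    def test_pairwise_distinct_shapes(self):
        bank = generate_species_bank(8, seed=3)
        shapes = {s.shape_params() for s in bank}
        assert len(shapes) == 8

    def test_rejects_tiny_bank(self):
        with pytest.raises(ValueError):
            generate_species_bank(1, seed=0)

    def test_parameter_ranges(self):
        for spec in generate_species_bank(10, seed=5):
            assert 0 <= spec.lobe_depth <= 1
            assert 0 <= spec.serration <= 1
            assert spec.lobe_count >= 0
            assert spec.compoundness >= 1
            assert 0 <= spec.vein_contrast <= 1


class TestRenderLeaf:
    def test_simple_leaf_single_component(self, bank5):
        spec = next(s for s in bank5 if s.compoundness == 1)
        layer = render_leaf(spec, "top", jitter_seed=5, size=(256, 192))
        assert ndimage.label(layer.alpha)[1] == 1

    @pytest.mark.parametrize("k", [3, 5])
    def test_compound_component_count(self, bank5, k):
        import dataclasses

        spec = dataclasses.replace(bank5[0], compoundness=k)
        layer = render_leaf(spec, "top", jitter_seed=6, size=(320, 240))
        assert ndimage.label(layer.alpha)[1] == k

    def test_render_deterministic(self, bank5):
        a = render_leaf(bank5[2], "back", jitter_seed=9, size=(256, 192))
        b = render_leaf(bank5[2], "back", jitter_seed=9, size=(256, 192))
        assert np.array_equal(a.color, b.color)
        assert np.array_equal(a.alpha, b.alpha)

    def test_back_is_mirrored_top_geometry(self, bank5):
        top = render_leaf(bank5[0], "top", jitter_seed=3, size=(256, 192), jitter=0.0)
        back = render_leaf(bank5[0], "back", jitter_seed=3, size=(256, 192), jitter=0.0)
        assert np.array_equal(back.alpha, top.alpha[:, ::-1])


class TestComposite:
    def test_plain_background_near_white(self, bank5, small_config):
        layer = render_leaf(bank5[0], "top", 1, size=(256, 192))
        img = composite(layer, "plain", "flash_off", seed=2, config=small_config)
        bg = img[~layer.alpha]
        assert abs(bg.mean() / 255.0 - small_config.white_level) < 0.05

    def test_natural_budget_zero_is_clutter_free(self, bank5, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, distractor_budget=0)
        layer = render_leaf(bank5[0], "top", 1, size=(256, 192))
        img = composite(layer, "natural", "flash_off", bank5, seed=2, config=cfg)
        # without distractors the background is a smooth field: no high-
        # contrast connected blobs darker/lighter than their surroundings
        bg_lum = img[..., 1][~layer.alpha].astype(float)
        assert bg_lum.std() < 45

    def test_plain_reduces_leaf_contrast(self, bank5, small_config):
        layer = render_leaf(bank5[3], "top", 4, size=(256, 192))
        plain = composite(layer, "plain", "flash_off", seed=3, config=small_config)
        nat = composite(layer, "natural", "flash_off", bank5, seed=3,
                        config=small_config)

        def leaf_contrast(img):
            vals = img[layer.alpha].astype(float).mean(axis=1)
            return vals.std()

        assert leaf_contrast(plain) < leaf_contrast(nat)

    def test_invalid_arguments(self, bank5, small_config):
        layer = render_leaf(bank5[0], "top", 1, size=(256, 192))
        with pytest.raises(ValueError):
            composite(layer, "sky", "flash_off", config=small_config)
        with pytest.raises(ValueError):
            composite(layer, "plain", "strobe", config=small_config)


class TestBacklight:
    def test_background_brighter_than_leaf_boundary(self, bank5):
        pixels, mask = render_backlight(bank5[1], jitter_seed=8, size=(256, 192))
        lum = pixels.astype(float).mean(axis=2)
        boundary = mask & ~ndimage.binary_erosion(mask)
        outside = ndimage.binary_dilation(mask, iterations=2) & ~mask
        assert lum[boundary].max() < lum[outside].min() + 30
        assert lum[boundary].mean() < lum[outside].mean() - 60

    def test_venation_contrast_exceeds_natural(self, bank5):
        for spec in bank5:
            bl_pix, bl_mask = render_backlight(spec, jitter_seed=3, size=(256, 192))
            rec = make_single_record(spec, "natural", "flash_off", seed=3,
                                     config=GeneratorConfig(width=256, height=192),
                                     distractors=bank5)
            assert (venation_contrast(bl_pix, bl_mask)
                    > venation_contrast(rec.pixels, rec.gt_mask))

    def test_deterministic(self, bank5):
        a, _ = render_backlight(bank5[0], jitter_seed=11, size=(256, 192))
        b, _ = render_backlight(bank5[0], jitter_seed=11, size=(256, 192))
        assert np.array_equal(a, b)


class TestObservation:
    def test_nine_records_with_expected_factors(self, observation):
        assert len(observation) == 9
        triples = {(r.perspective, r.illumination, r.background)
                   for r in observation}
        assert len(triples) == 9
        assert ("backlight", "n/a", "n/a") in triples
        reflected = [t for t in triples if t[0] != "backlight"]
        assert len(reflected) == 8

    def test_ground_truth_consistency(self, observation):
        for rec in observation:
            assert rec.gt_mask.any()
            ys, xs = np.nonzero(rec.gt_mask)
            assert rec.gt_bbox == (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
            fx, fy = rec.focus_point
            assert rec.gt_mask[fy, fx]

    def test_shared_geometry_without_jitter(self, bank5):
        cfg = GeneratorConfig(width=256, height=192, jitter=0.0)
        recs = generate_observation(bank5[0], "nojit", seed=5, config=cfg,
                                    distractor_specs=bank5)
        w = cfg.width
        ref = next(r for r in recs if r.perspective == "top")
        for rec in recs:
            if rec.perspective == "back":
                x0, y0, x1, y1 = rec.gt_bbox
                assert (w - x1, y0, w - x0, y1) == ref.gt_bbox
            else:
                assert rec.gt_bbox == ref.gt_bbox

    def test_deterministic(self, bank5, small_config):
        a = generate_observation(bank5[2], "d", 5, small_config, bank5)
        b = generate_observation(bank5[2], "d", 5, small_config, bank5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pixels, rb.pixels)
            assert np.array_equal(ra.gt_mask, rb.gt_mask)


class TestDataset:
    def test_forced_observation_count(self, tmp_path):
        cfg = GeneratorConfig(width=128, height=96)
        manifest = generate_dataset(2, (3, 3), seed=1, out_dir=tmp_path, config=cfg)
        assert len(manifest) == 2 * 3 * 9

    def test_counts_within_range_and_reproducible(self, tmp_path):
        cfg = GeneratorConfig(width=128, height=96)
        m1 = generate_dataset(3, (2, 4), seed=9, out_dir=tmp_path / "a", config=cfg)
        counts = m1.groupby("species_id")["observation_id"].nunique()
        assert counts.between(2, 4).all()
        generate_dataset(3, (2, 4), seed=9, out_dir=tmp_path / "b", config=cfg)
        assert ((tmp_path / "a" / "manifest.csv").read_bytes()
                == (tmp_path / "b" / "manifest.csv").read_bytes())

    def test_records_round_trip(self, tmp_path):
        cfg = GeneratorConfig(width=128, height=96)
        manifest = generate_dataset(2, (2, 2), seed=4, out_dir=tmp_path, config=cfg)
        bank = generate_species_bank(2, seed=4)
        row = manifest.iloc[5]
        loaded = synthetic.load_record(row, tmp_path)
        fresh = generate_observation(
            bank[0] if row["species_id"] == "sp00" else bank[1],
            row["observation_id"], seed=4, config=cfg, distractor_specs=bank)
        orig = next(r for r in fresh if r.image_type == row["image_type"])
        assert np.array_equal(loaded.pixels, orig.pixels)
        assert np.array_equal(loaded.gt_mask, orig.gt_mask)
        assert loaded.gt_bbox == orig.gt_bbox

    def test_rejects_bad_obs_range(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(2, (1, 3), seed=0, out_dir=tmp_path)


class TestMetrics:
    def test_separability_ordering(self, bank5, small_config):
        """Back light >= plain >= natural under the boundary-contrast
        metric, averaged over >= 50 records."""
        by_kind = {"backlight": [], "plain": [], "natural": []}
        for i in range(6):
            recs = generate_observation(bank5[i % 5], f"sep{i}", seed=100 + i,
                                        config=small_config,
                                        distractor_specs=bank5)
            for r in recs:
                kind = "backlight" if r.perspective == "backlight" else r.background
                by_kind[kind].append(separability(r.pixels, r.gt_mask))
        assert sum(len(v) for v in by_kind.values()) >= 50
        means = {k: np.mean(v) for k, v in by_kind.items()}
        assert means["backlight"] >= means["plain"] >= means["natural"]

    def test_species_distinct_by_shape(self, small_config):
        """1-NN on mask shape descriptors beats chance on 5 species."""
        bank = generate_species_bank(5, seed=21)
        descs, labels = [], []
        for si, spec in enumerate(bank):
            for j in range(10):
                layer = render_leaf(spec, "top", jitter_seed=1000 + si * 10 + j,
                                    size=(256, 192))
                descs.append(shape_descriptor(layer.alpha))
                labels.append(si)
        descs = np.asarray(descs)
        labels = np.asarray(labels)
        d2 = ((descs[:, None] - descs[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        acc = float(np.mean(labels[d2.argmin(1)] == labels))
        assert acc > 1 / 5
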