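"""Synthetic scene generator: determinism, spectral calibration, corruption."""

import numpy as np
import pytest

from lufor.scenes import (
    ClassSpec,
    CorruptionConfig,
    SceneConfig,
    UNLABELED,
    corrupt_annotations,
    default_classes,
    generate_dataset,
    generate_scene,
)


class TestGenerateScene:
    def test_determinism_bit_identical(self):
        cfg = SceneConfig(height=64, width=64, seed=11)
        a, b = generate_scene(cfg), generate_scene(cfg)
        assert np.array_equal(a.bands, b.bands)
        assert np.array_equal(a.truth_mask, b.truth_mask)
        assert np.array_equal(a.loss_year, b.loss_year)

    def test_single_class_scene_is_constant(self):
        water = [ClassSpec(0, "water", (0.16, 0.20, 0.10, 0.04), 0.005, "meander"),
                 ClassSpec(1, "pasture", (0.08, 0.52, 0.20, 0.42), 0.005, "blob")]
        cfg = SceneConfig(height=32, width=32, classes=water, n_objects_per_class=(0, 0),
                          background_class_id=0, seed=1)
        s = generate_scene(cfg)
        assert (s.truth_mask == 0).all()
        assert np.allclose(s.bands.mean(axis=(0, 1)), water[0].band_means, atol=0.01)

    def test_every_class_present_and_spectral_means_calibrated(self, ):
        cfg = SceneConfig(height=256, width=256, seed=7)
        s = generate_scene(cfg)
        present = set(np.unique(s.truth_mask))
        assert present == set(range(15))
        for spec in cfg.classes:
            sel = s.truth_mask == spec.class_id
            n = int(sel.sum())
            if n < 30:
                continue
            sample_mean = s.bands[sel].mean(axis=0)
            # clipping to [0,1] and lattice ripple shift means slightly;
            # 3 SE plus a small bias allowance
            tol = 3 * spec.band_sd / np.sqrt(n) + 0.01
            assert np.abs(sample_mean - np.array(spec.band_means)).max() < tol, spec.name

    def test_loss_year_support_and_mask_consistency(self, scene_128):
        s = scene_128
        assert ((s.loss_year > 0) == s.loss_mask).all()
        years = s.loss_year[s.loss_mask]
        assert years.min() >= 2001 and years.max() <= 2020

    def test_bands_bounded(self, scene_128):
        assert scene_128.bands.min() >= 0.0 and scene_128.bands.max() <= 1.0

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            SceneConfig(height=16, width=64)
        with pytest.raises(ValueError):
            SceneConfig(classes=default_classes()[:1])
        with pytest.raises(ValueError):
            SceneConfig(pixel_size=0.0)

    def test_nearest_centroid_separability_at_low_noise(self):
        """With vanishing noise the 4-band signatures identify every pixel."""
        cfg = SceneConfig(height=128, width=128, seed=5,
                          classes=default_classes(band_sd=1e-5))
        s = generate_scene(cfg)
        means = np.array([c.band_means for c in cfg.classes])
        d = ((s.bands[..., None, :] - means[None, None]) ** 2).sum(-1)
        assert (d.argmin(-1) == s.truth_mask).all()


class TestCorruptAnnotations:
    def test_zero_corruption_is_identity(self, scene_128):
        out = corrupt_annotations(scene_128.truth_mask, CorruptionConfig())
        assert np.array_equal(out, scene_128.truth_mask)

    def test_mislabel_rate_calibrated(self):
        s = generate_scene(SceneConfig(height=256, width=256, seed=2))
        out = corrupt_annotations(s.truth_mask,
                                  CorruptionConfig(mislabel_fraction=0.25, seed=9))
        rate = (out != s.truth_mask).mean()
        assert 0.23 <= rate <= 0.27

    def test_full_drop(self, scene_128):
        out = corrupt_annotations(scene_128.truth_mask,
                                  CorruptionConfig(drop_fraction=1.0))
        assert (out == UNLABELED).all()

    def test_drop_fraction_exact(self, scene_128):
        out = corrupt_annotations(scene_128.truth_mask,
                                  CorruptionConfig(drop_fraction=0.4, seed=4))
        assert abs((out == UNLABELED).mean() - 0.4) < 1e-3

    def test_deterministic_per_seed(self, scene_128):
        cc = CorruptionConfig(mislabel_fraction=0.1, drop_fraction=0.1,
                              boundary_shift_px=1, seed=13)
        a = corrupt_annotations(scene_128.truth_mask, cc)
        b = corrupt_annotations(scene_128.truth_mask, cc)
        assert np.array_equal(a, b)

    def test_boundary_shift_changes_only_boundaries(self, scene_128):
        out = corrupt_annotations(scene_128.truth_mask,
                                  CorruptionConfig(boundary_shift_px=2, seed=1))
        changed = out != scene_128.truth_mask
        # interiors of large homogeneous areas survive
        assert 0 < changed.mean() < 0.5

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            CorruptionConfig(mislabel_fraction=1.5)
        with pytest.raises(ValueError):
            CorruptionConfig(drop_fraction=-0.1)


class TestGenerateDataset:
    def test_pool_counts_and_disjointness(self):
        pools = generate_dataset(10, SceneConfig(height=32, width=32),
                                 CorruptionConfig(), annotated_fraction=0.5, seed=0)
        assert len(pools.annotated) == 5
        ids = [set(pools.annotated), set(pools.unannotated), set(pools.test)]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        assert sum(map(len, ids)) == 10

    def test_floor_arithmetic(self):
        pools = generate_dataset(100, SceneConfig(height=32, width=32),
                                 CorruptionConfig(), annotated_fraction=0.38, seed=1)
        assert len(pools.annotated) == 38

    def test_deterministic_membership(self):
        kw = dict(scene_config=SceneConfig(height=32, width=32),
                  corruption=CorruptionConfig(), annotated_fraction=0.5, seed=77)
        a = generate_dataset(8, **kw)
        b = generate_dataset(8, **kw)
        assert set(a.annotated) == set(b.annotated)
        assert set(a.test) == set(b.test)

    def test_label_visibility_contract(self):
        pools = generate_dataset(6, SceneConfig(height=32, width=32),
                                 CorruptionConfig(mislabel_fraction=0.5, seed=2),
                                 annotated_fraction=0.5, seed=2)
        for rec in pools.annotated.values():
            assert rec.labels is not None
        for rec in pools.unannotated.values():
            assert rec.labels is None  # truth hidden from the learner
        for rec in pools.test.values():
            assert np.array_equal(rec.labels, rec.scene.truth_mask)

    def test_too_few_scenes_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(2, SceneConfig(height=32, width=32),
                             CorruptionConfig(), annotated_fraction=0.5)
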