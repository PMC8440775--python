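from __future__ import annotations

import numpy as np
import pytest

from redica import (Blob, DiscSpec, SceneSpec, Vessel, generate_scene,
                    scene_battery)
from redica.synthetic import SceneValidationError


def _one_blob_spec(**kwargs):
    defaults = dict(
        shape=(80, 80),
        blobs=(Blob(center=(40.0, 40.0), radius=8.0, depth=0.8),),
        noise_sd=0.0,
        seed=7,
    )
    defaults.update(kwargs)
    return SceneSpec(**defaults)


class TestGenerateScene:
    def test_empty_scene_is_constant_background(self):
        truth = generate_scene(SceneSpec(shape=(40, 50), noise_sd=0.0))
        assert truth.image.shape == (40, 50)
        assert np.all(truth.image == 0.85)
        assert len(truth.lesion_regions) == 0
        assert not truth.vessel_mask.any()
        assert truth.disc_zone is None

    def test_blob_center_value(self):
        truth = generate_scene(_one_blob_spec())
        # full coverage at the center: background minus depth
        assert truth.noiseless[40, 40] == pytest.approx(0.85 - 0.8)
        # far corner untouched
        assert truth.noiseless[0, 0] == pytest.approx(0.85)

    def test_antialiased_rim_is_intermediate(self):
        truth = generate_scene(_one_blob_spec())
        # one pixel outside the radius along a row through the center
        rim = truth.noiseless[40, 40 + 8]
        assert 0.05 < rim < 0.85

    def test_truth_regions_are_dark_blob_pixels(self):
        truth = generate_scene(_one_blob_spec())
        (region,) = truth.lesion_regions.regions
        for (r, c) in region.pixels:
            assert truth.noiseless[r, c] < truth.spec.t_dp_ref
            assert np.hypot(r - 40, c - 40) <= 8.0 + 0.5

    def test_noise_is_seed_deterministic(self):
        spec = _one_blob_spec(noise_sd=0.02)
        a = generate_scene(spec)
        b = generate_scene(spec)
        assert np.array_equal(a.image, b.image)

    def test_different_seed_changes_noise_not_truth(self):
        a = generate_scene(_one_blob_spec(noise_sd=0.02, seed=1))
        b = generate_scene(_one_blob_spec(noise_sd=0.02, seed=2))
        assert not np.array_equal(a.image, b.image)
        assert np.array_equal(a.noiseless, b.noiseless)
        assert a.lesion_regions.regions[0].pixels == \
            b.lesion_regions.regions[0].pixels

    def test_image_range_clipped(self):
        truth = generate_scene(_one_blob_spec(noise_sd=0.04, seed=3))
        assert truth.image.min() >= 0.0 and truth.image.max() <= 1.0

    def test_vessel_mask_follows_strip(self):
        spec = SceneSpec(
            shape=(60, 60), noise_sd=0.0,
            vessels=(Vessel(control_points=((30.0, 0.0), (30.0, 59.0)),
                            width=6.0, depth=0.8),))
        truth = generate_scene(spec)
        assert truth.vessel_mask[30, 30]
        assert not truth.vessel_mask[5, 30]
        assert truth.noiseless[30, 30] == pytest.approx(0.05)

    def test_disc_zone_reported(self):
        spec = SceneSpec(shape=(120, 120), noise_sd=0.0,
                         disc=DiscSpec(center=(60.0, 60.0), side=40))
        truth = generate_scene(spec)
        assert truth.disc_zone is not None
        assert (truth.disc_zone.top_row, truth.disc_zone.left_col) == (40, 40)
        # bright plateau away from the crossing lines
        assert truth.noiseless[42, 42] > 0.9


class TestValidation:
    def test_blob_out_of_bounds(self):
        with pytest.raises(SceneValidationError, match="out of bounds"):
            generate_scene(_one_blob_spec(
                blobs=(Blob(center=(2.0, 40.0), radius=8.0, depth=0.8),)))

    def test_shallow_blob_rejected(self):
        with pytest.raises(SceneValidationError, match="too shallow"):
            generate_scene(_one_blob_spec(
                blobs=(Blob(center=(40.0, 40.0), radius=8.0, depth=0.3),)))

    def test_overlapping_blobs_rejected(self):
        with pytest.raises(SceneValidationError, match="overlap"):
            generate_scene(_one_blob_spec(blobs=(
                Blob(center=(40.0, 40.0), radius=8.0, depth=0.8),
                Blob(center=(44.0, 40.0), radius=8.0, depth=0.8),
            )))

    def test_blob_on_vessel_rejected(self):
        with pytest.raises(SceneValidationError, match="vessel"):
            generate_scene(_one_blob_spec(
                vessels=(Vessel(control_points=((40.0, 0.0), (40.0, 79.0)),
                                width=6.0, depth=0.8),)))

    def test_disc_outside_image_rejected(self):
        with pytest.raises(SceneValidationError, match="disc"):
            generate_scene(SceneSpec(
                shape=(60, 60), disc=DiscSpec(center=(5.0, 30.0), side=40)))


class TestSceneBattery:
    def test_bitwise_reproducible(self):
        a = scene_battery(3, master_seed=99, shape=(200, 260))
        b = scene_battery(3, master_seed=99, shape=(200, 260))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.image, tb.image)
            assert ta.spec == tb.spec

    def test_structure_counts(self, battery):
        assert len(battery) == 20
        for truth in battery:
            assert len(truth.spec.blobs) == 5
            assert len(truth.spec.vessels) == 1
            assert truth.disc_zone is not None

    def test_radii_within_requested_range(self, battery):
        radii = [b.radius for t in battery for b in t.spec.blobs]
        assert min(radii) >= 3.0 and max(radii) <= 12.0
        # both the sub- and supra-detectable regimes are exercised
        assert any(r < 5.0 for r in radii) and any(r > 8.0 for r in radii)

    def test_scenes_differ(self, battery):
        assert not np.array_equal(battery[0].image, battery[1].image)

    def test_blob_clearance_from_vessels(self, battery):
        for truth in battery:
            for blob in truth.spec.blobs:
                r0, c0 = int(round(blob.center[0])), int(round(blob.center[1]))
                r = int(np.ceil(blob.radius)) + 10
                lo_r, hi_r = max(0, r0 - r), min(truth.vessel_mask.shape[0], r0 + r)
                lo_c, hi_c = max(0, c0 - r), min(truth.vessel_mask.shape[1], c0 + r)
                assert not truth.vessel_mask[lo_r:hi_r, lo_c:hi_c].any()

    def test_invalid_count(self):
        with pytest.raises(ValueError, match="n_scenes"):
            scene_battery(0, master_seed=1)
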