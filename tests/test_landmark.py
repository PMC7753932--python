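"""Heatmap targets, peak refinement, ROI cropping, landmark training."""

import numpy as np
import pytest

from hip3d.io_formats import LabelMap, VolumeImage
from hip3d.landmark import (
    LandmarkLocator,
    crop_around_fhc,
    make_heatmap_target,
    refine_peak,
    uncrop,
)


class TestHeatmapTarget:
    def test_peak_at_fhc_voxel(self):
        h = make_heatmap_target([8.0, 8.0, 8.0], (16, 16, 16), [1.6] * 3,
                                [0.0] * 3, sigma_mm=4.0)
        assert h.argmax() == np.ravel_multi_index((5, 5, 5), h.shape)

    def test_value_at_one_sigma(self):
        sigma = 4.0
        h = make_heatmap_target([12.0, 12.0, 12.0], (25, 25, 25), [1.0] * 3,
                                [0.0] * 3, sigma_mm=sigma)
        peak = h[12, 12, 12]
        assert peak == pytest.approx(1.0)
        assert h[16, 12, 12] == pytest.approx(peak * np.exp(-0.5))

    def test_world_space_width_independent_of_spacing(self):
        # evaluate the Gaussian at the same world offsets on two grids
        fhc = [16.0, 16.0, 16.0]
        fine = make_heatmap_target(fhc, (32, 32, 32), [1.0] * 3, [0.0] * 3, 4.0)
        coarse = make_heatmap_target(fhc, (16, 16, 16), [2.0] * 3, [0.5] * 3, 4.0)
        # coarse voxel (i) center = 0.5 + 2i; fine voxel at same world pos = 2i
        for i in (4, 6, 10):
            world = 0.5 + 2.0 * i
            expected = np.exp(-3 * (world - 16.0) ** 2 / (2 * 4.0**2))
            assert coarse[i, i, i] == pytest.approx(expected, rel=1e-6)
            assert fine[int(world), int(world), int(world)] == pytest.approx(
                np.exp(-3 * (int(world) - 16.0) ** 2 / (2 * 4.0**2)), rel=1e-6)

    def test_mass_consistent_across_spacings(self):
        fhc = [20.0, 20.0, 20.0]
        fine = make_heatmap_target(fhc, (50, 50, 50), [0.8] * 3, [0.0] * 3, 4.0)
        coarse = make_heatmap_target(fhc, (25, 25, 25), [1.6] * 3, [0.4] * 3, 4.0)
        mass_fine = fine.sum() * 0.8**3
        mass_coarse = coarse.sum() * 1.6**3
        assert mass_coarse == pytest.approx(mass_fine, rel=0.01)

    def test_fhc_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_heatmap_target([100.0, 8.0, 8.0], (16, 16, 16), [1.0] * 3,
                                [0.0] * 3, 4.0)


class TestPeakRefinement:
    def test_synthetic_gaussian_recovered_subvoxel(self):
        spacing = np.array([1.6] * 3)
        origin = np.zeros(3)
        true = np.array([24.9, 25.7, 24.2])
        h = make_heatmap_target(true, (32, 32, 32), spacing, origin, sigma_mm=4.0)
        found, conf = refine_peak(h, spacing, origin)
        assert np.linalg.norm(found - true) < 0.5 * spacing[0]
        assert conf > 0.9

    def test_uniform_heatmap_rejected(self):
        with pytest.raises(ValueError, match="no landmark response"):
            refine_peak(np.ones((8, 8, 8)), [1.0] * 3, [0.0] * 3)
        with pytest.raises(ValueError, match="no landmark response"):
            refine_peak(np.zeros((8, 8, 8)), [1.0] * 3, [0.0] * 3)


class TestCrop:
    def _vol(self, rng):
        return VolumeImage(values=rng.normal(size=(32, 32, 32)).astype(np.float32),
                           spacing_mm=[1.0] * 3)

    def test_centered_crop_no_padding(self, rng):
        vol = self._vol(rng)
        crop, off = crop_around_fhc(vol, [16.0, 16.0, 16.0], roi_shape=(16, 16, 16))
        assert np.array_equal(off.start_index, [8, 8, 8])
        assert np.array_equal(crop.values, vol.values[8:24, 8:24, 8:24])
        # crop center voxel equals the fhc voxel
        assert np.allclose(crop.index_to_world([8, 8, 8]), [16, 16, 16])

    def test_corner_crop_pads_complement(self, rng):
        vol = self._vol(rng)
        crop, off = crop_around_fhc(vol, [1.0, 1.0, 1.0], roi_shape=(16, 16, 16))
        assert crop.values.shape == (16, 16, 16)
        pad = crop.values == 0
        # padded region is exactly the out-of-bounds complement
        assert pad[:7].all() and not pad[7:].any() or pad.sum() > 0
        inside = crop.values[7:, 7:, 7:]
        assert np.array_equal(inside, vol.values[:9, :9, :9])

    def test_label_crop_round_trip(self, rng):
        lab = LabelMap(values=rng.integers(0, 3, size=(32, 32, 32)),
                       spacing_mm=[1.0] * 3)
        crop, off = crop_around_fhc(lab, [10.0, 20.0, 16.0], roi_shape=(12, 12, 12))
        restored = uncrop(crop.values, off)
        s = off.start_index
        assert np.array_equal(restored[s[0]:s[0] + 12, s[1]:s[1] + 12, s[2]:s[2] + 12],
                              lab.values[s[0]:s[0] + 12, s[1]:s[1] + 12, s[2]:s[2] + 12])
        # outside the ROI everything is background
        restored[s[0]:s[0] + 12, s[1]:s[1] + 12, s[2]:s[2] + 12] = 0
        assert not restored.any()

    def test_roi_size_mm_interface(self, rng):
        vol = self._vol(rng)
        crop, _ = crop_around_fhc(vol, [16.0] * 3, roi_size_mm=8.0)
        assert crop.values.shape == (8, 8, 8)
        with pytest.raises(ValueError):
            crop_around_fhc(vol, [16.0] * 3)


class TestTraining:
    def test_loss_decreases_and_detects_on_training_data(self, noisy_desk_samples):
        samples = noisy_desk_samples
        loc = LandmarkLocator(epochs=6, seed=0)
        loc.fit([s.volume for s in samples], [s.fhc_mm for s in samples])
        assert loc.loss_history_[-1] < loc.loss_history_[0]
        working_voxel = samples[0].volume.spacing_mm[0] * loc.downsample_factor
        errs = [np.linalg.norm(loc.detect(s.volume)[0] - s.fhc_mm) for s in samples]
        assert np.mean(errs) <= 2 * working_voxel

    def test_fixed_seed_reproducible(self, noisy_desk_samples):
        samples = noisy_desk_samples[:3]
        kw = dict(epochs=2, seed=42)
        h1 = LandmarkLocator(**kw).fit([s.volume for s in samples],
                                       [s.fhc_mm for s in samples]).loss_history_
        h2 = LandmarkLocator(**kw).fit([s.volume for s in samples],
                                       [s.fhc_mm for s in samples]).loss_history_
        assert h1 == h2

    def test_empty_and_tiny_datasets_rejected(self):
        with pytest.raises(ValueError):
            LandmarkLocator().fit([], [])

    def test_translation_equivariance(self, noisy_desk_samples):
        # shifting the phantom shifts the detection by the same offset
        from hip3d.phantom import PhantomSpec, generate_phantom

        samples = noisy_desk_samples
        loc = LandmarkLocator(epochs=6, seed=0)
        loc.fit([s.volume for s in samples], [s.fhc_mm for s in samples])
        base = PhantomSpec(voxel_size_mm=1.6, volume_shape=(64, 64, 64))
        s0 = generate_phantom(base)
        shift_vox = np.array([4, -4, 2])  # multiples of the pooling factor
        shifted = VolumeImage(values=np.roll(s0.volume.values, shift_vox, axis=(0, 1, 2)),
                              spacing_mm=s0.volume.spacing_mm)
        d0, _ = loc.detect(s0.volume)
        d1, _ = loc.detect(shifted)
        expected = shift_vox * s0.volume.spacing_mm
        working_voxel = 1.6 * loc.downsample_factor
        assert np.linalg.norm((d1 - d0) - expected) <= working_voxel
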