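"""Synthetic shadow-frame generator: physics sanity, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

import shadowcyte as sc
from shadowcyte import detect, shadowstats
from shadowcyte.simshadow import SamplingError, first_ring_radius_px


CFG_NOISELESS = sc.OpticalConfig(frame_shape=(256, 256), noise_sigma=0.0)


def center_crop(patch, size=30):
    c = patch.shape[0] // 2
    half = size // 2 - 1
    return patch[c - half : c - half + size, c - half : c - half + size]


class TestRenderCellPattern:
    def test_no_object_gives_uniform_background(self):
        cell = sc.CellSpec(center=(0, 0), radius_um=4.0, phase_shift=0.0,
                           amplitude_transmittance=1.0)
        patch = sc.render_cell_pattern(CFG_NOISELESS, cell)
        assert np.all(patch == CFG_NOISELESS.background_level)

    def test_centered_cell_rotation_invariant(self):
        patch = sc.render_cell_pattern(
            CFG_NOISELESS, sc.CellSpec(center=(0, 0), radius_um=5.0)
        )
        # the pattern center sits on pixel n//2: crop an odd window around it
        c = patch.shape[0] // 2
        win = patch[c - 15 : c + 16, c - 15 : c + 16]
        assert np.allclose(win, np.rot90(win), rtol=1e-6)

    def test_pattern_is_center_bright_with_dark_ring(self):
        patch = sc.render_cell_pattern(
            CFG_NOISELESS, sc.CellSpec(center=(0, 0), radius_um=4.2)
        )
        params = shadowstats.analyze_crop(center_crop(patch))
        assert params.valid
        assert params.cmv > CFG_NOISELESS.background_level
        assert params.ppd > 0

    def test_ppd_monotone_in_radius(self):
        ppds = []
        for radius in np.linspace(3.0, 10.0, 8):
            patch = sc.render_cell_pattern(
                CFG_NOISELESS, sc.CellSpec(center=(0, 0), radius_um=float(radius))
            )
            ppds.append(shadowstats.analyze_crop(center_crop(patch)).ppd)
        assert all(b >= a for a, b in zip(ppds, ppds[1:]))

    def test_undersampled_geometry_raises(self):
        coarse = sc.OpticalConfig(frame_shape=(256, 256), pixel_pitch=15e-6)
        assert first_ring_radius_px(coarse) < 2
        with pytest.raises(SamplingError, match="pixel_pitch"):
            sc.render_cell_pattern(coarse, sc.CellSpec(center=(0, 0), radius_um=5.0))

    def test_first_ring_adequately_sampled_at_defaults(self):
        assert first_ring_radius_px(sc.OpticalConfig()) >= 2


class TestRenderFrame:
    def test_empty_cell_list_gives_background_noise(self):
        cfg = sc.OpticalConfig(frame_shape=(256, 256), noise_sigma=2.0, seed=3)
        frame = sc.render_frame(cfg, [])
        n = frame.image.size
        tol = 3 * cfg.noise_sigma / np.sqrt(n)
        assert abs(frame.image.mean() - cfg.background_level) < tol + 0.5  # quantization
        assert frame.cells == []

    def test_default_frame_shape(self):
        frame = sc.render_frame(sc.OpticalConfig(), [])
        assert frame.image.shape == (1944, 2592)

    def test_pixel_range_respects_bit_depth(self):
        cells = [sc.CellSpec(center=(128, 128), radius_um=8.0)]
        frame = sc.render_frame(CFG_NOISELESS, cells)
        assert frame.image.dtype == np.uint8
        assert frame.image.min() >= 0 and frame.image.max() <= 255

    def test_determinism_bit_identical(self):
        cfg = sc.OpticalConfig(frame_shape=(256, 256), noise_sigma=2.0, seed=11)
        cells = [sc.CellSpec(center=(100, 100), radius_um=5.0)]
        a = sc.render_frame(cfg, cells).image
        b = sc.render_frame(cfg, cells).image
        assert np.array_equal(a, b)

    def test_linearity_without_noise(self):
        cell = sc.CellSpec(center=(128, 128), radius_um=5.0)
        frame = sc.render_frame(CFG_NOISELESS, [cell]).image.astype(float)
        patch = sc.render_cell_pattern(CFG_NOISELESS, cell)
        expected = np.full((256, 256), CFG_NOISELESS.background_level)
        expected[96:160, 96:160] += patch - CFG_NOISELESS.background_level
        expected = np.clip(expected, 0, 255)
        assert np.abs(frame - expected).max() <= 0.5 + 1e-9  # quantization only

    def test_out_of_bounds_center_names_cell_index(self):
        cells = [sc.CellSpec(center=(100, 100), radius_um=5.0),
                 sc.CellSpec(center=(300, 100), radius_um=5.0)]
        with pytest.raises(ValueError, match="cell 1"):
            sc.render_frame(CFG_NOISELESS, cells)

    def test_overlapping_cells_rejected(self):
        cells = [sc.CellSpec(center=(100, 100), radius_um=5.0),
                 sc.CellSpec(center=(104, 104), radius_um=5.0)]
        with pytest.raises(ValueError, match="separation"):
            sc.render_frame(CFG_NOISELESS, cells)

    def test_planted_cells_recovered_by_detection(self):
        cells = [sc.CellSpec(center=(60, 60), radius_um=4.2),
                 sc.CellSpec(center=(60, 180), radius_um=6.0),
                 sc.CellSpec(center=(130, 120), radius_um=5.0),
                 sc.CellSpec(center=(200, 60), radius_um=4.5),
                 sc.CellSpec(center=(200, 190), radius_um=6.5)]
        frame = sc.render_frame(CFG_NOISELESS, cells)
        found = detect.find_cells(frame.image)
        assert len(found) == len(cells)
        for cell in cells:
            d = min(np.hypot(c.center[0] - cell.center[0],
                             c.center[1] - cell.center[1]) for c in found)
            assert d <= 2.0


class TestGenerateCohort:
    def test_zero_cells_empty_manifest(self):
        frames, manifest = sc.generate_cohort(CFG_NOISELESS, n_per_class=0, seed=0)
        assert frames == [] and len(manifest) == 0

    def test_manifest_counts_and_ground_truth(self):
        cfg = sc.OpticalConfig(frame_shape=(384, 384), noise_sigma=1.0, seed=5)
        frames, manifest = sc.generate_cohort(cfg, n_per_class=40, seed=5)
        assert len(manifest) == 80
        assert (manifest["class_label"].value_counts() == 40).all()
        assert {"frame_index", "cell_id", "row", "col", "radius_um",
                "phase_rad", "class_label"} <= set(manifest.columns)
        total_planted = sum(len(f.cells) for f in frames)
        assert total_planted == len(manifest)

    def test_reproducible_under_seed(self):
        cfg = sc.OpticalConfig(frame_shape=(384, 384), noise_sigma=1.0)
        f1, m1 = sc.generate_cohort(cfg, n_per_class=10, seed=42)
        f2, m2 = sc.generate_cohort(cfg, n_per_class=10, seed=42)
        pd.testing.assert_frame_equal(m1, m2)
        assert all(np.array_equal(a.image, b.image) for a, b in zip(f1, f2))

    def test_class_regimes_separate_in_ppd(self, cohort_small):
        _, manifest, crops = cohort_small
        ppd = np.array([shadowstats.analyze_crop(c).ppd for c in crops])
        pos = manifest["class_label"] == sc.CD34_POS
        med_pos = np.median(ppd[pos])
        med_neg = np.median(ppd[~pos])
        assert abs(med_neg - med_pos) >= 20.0
        assert 40 <= med_pos <= 60

    def test_write_cohort_roundtrip(self, tmp_path):
        cfg = sc.OpticalConfig(frame_shape=(384, 384), noise_sigma=1.0, seed=2)
        frames, manifest = sc.generate_cohort(cfg, n_per_class=5, seed=2)
        csv_path = sc.simshadow.write_cohort(frames, manifest, tmp_path)
        written = pd.read_csv(csv_path)
        assert len(written) == len(manifest)
        assert (tmp_path / "config.json").exists()
        assert sorted(tmp_path.glob("frame_*.png"))
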