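"""Background subtraction, vessel surfaces, split objects, spots, down-sampling."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from vesselniche.image import ImageVolume, LabelVolume
from vesselniche.segmentation import (
    PipelineConfig,
    detect_spots,
    downsample,
    segment_vessels,
    split_objects,
    subtract_background,
)
from vesselniche.synthetic import SyntheticScene, AffinityLaw, place_cells, rasterize_scene

from conftest import SPACING, rolling_ball_background


def _vol(data, spacing=SPACING):
    return ImageVolume(np.asarray(data, dtype=float), spacing)


class TestBackgroundSubtraction:
    def test_constant_volume_becomes_zero(self):
        out = subtract_background(_vol(np.full((20, 20, 20), 37.0)), 10.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_radius_below_voxel_size_rejected(self):
        with pytest.raises(ValueError, match="smaller than one voxel"):
            subtract_background(_vol(np.zeros((8, 8, 8))), 2.0)  # axial voxel is 2.5 μm

    def test_small_blob_peak_retained_vs_rolling_ball_oracle(self):
        # bright blob of diameter << 10 μm radius on zero background: both the
        # Gaussian surrogate and the morphological oracle must keep >= 80 % peak
        shape = (64, 64, 64)
        zz, yy, xx = np.indices(shape).astype(float)
        s = np.asarray(SPACING[::-1])
        c = 32.0
        r2 = (((zz - c) * s[0]) ** 2 + ((yy - c) * s[1]) ** 2 + ((xx - c) * s[2]) ** 2)
        blob = 1000.0 * np.exp(-0.5 * r2 / 1.0**2)  # sigma 1 μm
        out = subtract_background(_vol(blob), 10.0)
        peak = tuple(np.unravel_index(blob.argmax(), shape))
        assert out.data[peak] >= 0.8 * blob[peak]
        oracle = blob - rolling_ball_background(blob, 10.0, SPACING)
        assert oracle[peak] >= 0.8 * blob[peak]

    def test_linear_ramp_mostly_removed(self):
        shape = (32, 32, 64)
        ramp = np.broadcast_to(np.linspace(0, 100, shape[2]), shape).astype(float)
        out = subtract_background(_vol(ramp), 10.0)
        assert out.data.max() < 0.1 * 100
        # oracle judged away from the boundary (flat-SE opening has a
        # one-SE-radius edge effect by construction)
        oracle = ramp - rolling_ball_background(ramp, 10.0, SPACING)
        assert oracle[:, :, 8:-8].max() < 0.1 * 100


class TestVesselSurfaces:
    def test_volume_filter_keeps_exactly_one_object(self):
        # blocks of 2000 and 4641 voxels at 4.225 μm³/voxel = 8450 and
        # 19608.2 μm³; the 10^4 μm³ filter must keep only the second
        data = np.zeros((48, 48, 48))
        data[2:12, 2:12, 2:22] = 200.0          # 10*10*20 = 2000 voxels
        data[20:41, 20:37, 20:33] = 200.0       # 21*17*13 = 4641 voxels
        lv = segment_vessels(_vol(data), threshold=100.0, min_vessel_volume_um3=1e4)
        assert lv.n_objects == 1
        assert lv.table["voxel_count"].iloc[0] == 4641
        assert lv.table["volume_um3"].iloc[0] == pytest.approx(4641 * 4.225)

    def test_threshold_above_max_yields_empty_labeling(self):
        lv = segment_vessels(_vol(np.random.default_rng(0).random((10, 10, 10))), threshold=2.0)
        assert lv.n_objects == 0 and not lv.labels.any()

    def test_rasterized_cylinder_volume_close_form(self, straight_tube_scene):
        vols, _ = rasterize_scene(straight_tube_scene, SPACING)
        lv = segment_vessels(vols["CD31"], threshold=100.0, min_vessel_volume_um3=1e4)
        assert lv.n_objects == 1
        assert lv.table["volume_um3"].iloc[0] == pytest.approx(np.pi * 64 * 200, rel=0.05)

    @pytest.mark.parametrize("min_volume", [0, 5e3, 1e4, 2e4, 1e6])
    def test_volume_filter_monotone(self, min_volume):
        rng = np.random.default_rng(3)
        data = ndi.gaussian_filter(rng.random((32, 32, 32)), 1.5)
        n = segment_vessels(_vol(data), threshold="otsu", min_vessel_volume_um3=min_volume).n_objects
        n_loose = segment_vessels(_vol(data), threshold="otsu", min_vessel_volume_um3=0).n_objects
        assert n <= n_loose


def _sphere_mask(shape, center_zyx, radius_um, spacing=SPACING):
    zz, yy, xx = np.indices(shape).astype(float)
    s = np.asarray(spacing[::-1])
    return (
        ((zz - center_zyx[0]) * s[0]) ** 2
        + ((yy - center_zyx[1]) * s[1]) ** 2
        + ((xx - center_zyx[2]) * s[2]) ** 2
    ) <= radius_um**2


class TestSplitObjects:
    def test_small_sphere_unchanged(self):
        # 9 μm diameter sphere: all interior maxima within one 10 μm seed diameter
        mask = _sphere_mask((20, 30, 30), (10, 15, 15), 4.5)
        lv = LabelVolume.from_labels(mask.astype(np.int32), SPACING)
        out = split_objects(lv, 10.0)
        assert out.n_objects == 1
        np.testing.assert_array_equal(out.mask(), mask)

    def test_dumbbell_splits_into_two_matched_spheres(self):
        # two 10 μm-radius spheres joined by a thin neck -> 2 objects, each
        # within 10 % of an isolated sphere's voxel count
        shape = (24, 40, 60)
        c1, c2 = (12, 20, 18), (12, 20, 42)  # centres 24*1.3=31.2 μm apart
        m1 = _sphere_mask(shape, c1, 10.0)
        m2 = _sphere_mask(shape, c2, 10.0)
        zz, yy, xx = np.indices(shape).astype(float)
        s = np.asarray(SPACING[::-1])
        neck = (
            (np.abs(xx - 30) * s[2] <= 16)
            & (np.sqrt(((zz - 12) * s[0]) ** 2 + ((yy - 20) * s[1]) ** 2) <= 2.0)
        )
        dumbbell = m1 | m2 | neck
        lv = LabelVolume.from_labels(dumbbell.astype(np.int32), SPACING)
        out = split_objects(lv, 10.0)
        assert out.n_objects == 2
        iso = int(m1.sum())
        counts = sorted(out.table["voxel_count"])
        for c in counts:
            assert c == pytest.approx(iso, rel=0.10)
        # partition conservation: union of children bit-identical to parent
        np.testing.assert_array_equal(out.mask(), dumbbell)

    def test_split_preserves_every_label_voxel(self):
        rng = np.random.default_rng(7)
        blob = ndi.gaussian_filter(rng.random((24, 24, 24)), 2.0) > 0.52
        labels, _ = ndi.label(blob, structure=np.ones((3, 3, 3)))
        lv = LabelVolume.from_labels(labels.astype(np.int32), SPACING)
        out = split_objects(lv, 10.0)
        np.testing.assert_array_equal(out.mask(), lv.mask())


class TestSpotDetection:
    def _render_cells(self, n, seed, extent=(300.0, 300.0, 150.0), marker="Osterix"):
        scene = SyntheticScene(rng_seed=0, extent_um=extent)
        aff = AffinityLaw(target_phenotype="CD31hi_EmcnHi", law="uniform", fraction_background=1.0)
        scene = place_cells(scene, n, marker, aff, rng_seed=seed)
        vols, _ = rasterize_scene(scene, SPACING)
        return scene, vols[marker]

    def test_single_blob_found_within_one_voxel(self):
        scene, vol = self._render_cells(1, seed=5)
        spots = detect_spots(vol, "Osterix")
        assert len(spots) == 1
        err = np.abs(spots[0].center - scene.cells[0].center)
        assert (err <= np.asarray(SPACING)).all()

    def test_empty_volume_gives_no_spots(self):
        vol = ImageVolume(np.zeros((20, 20, 20)), SPACING)
        assert detect_spots(vol, "Gli1") == []

    def test_translation_equivariance(self):
        from vesselniche.synthetic import CellGT

        scene = SyntheticScene(rng_seed=0, extent_um=(300.0, 300.0, 150.0))
        scene.cells.append(CellGT(1, np.array([150.0, 150.0, 75.0]), "Osterix", 6.0, 18.0))
        vols, _ = rasterize_scene(scene, SPACING)
        vol = vols["Osterix"]
        spots = detect_spots(vol, "Osterix")
        shifted = ImageVolume(np.roll(vol.data, (2, 3, -4), axis=(0, 1, 2)), SPACING)
        spots2 = detect_spots(shifted, "Osterix")
        expected = spots[0].center + np.array([-4 * SPACING[0], 3 * SPACING[1], 2 * SPACING[2]])
        np.testing.assert_allclose(spots2[0].center, expected, atol=1e-9)

    def test_unknown_marker_rejected(self):
        vol = ImageVolume(np.zeros((5, 5, 5)), SPACING)
        with pytest.raises(ValueError, match="spot size"):
            detect_spots(vol, "CD45")


class TestDownsample:
    def test_shape_and_spacing_halve(self):
        vol = ImageVolume(np.zeros((50, 100, 100)), SPACING)
        out = downsample(vol, 2)
        assert out.data.shape == (25, 50, 50)
        assert out.spacing_um == pytest.approx((2.6, 2.6, 5.0))

    def test_factor_one_is_identity(self):
        vol = ImageVolume(np.arange(8.0).reshape(2, 2, 2), SPACING)
        assert downsample(vol, 1) is vol

    def test_constant_volume_preserved(self):
        vol = ImageVolume(np.full((8, 8, 8), 3.25), SPACING)
        np.testing.assert_allclose(downsample(vol, 2).data, 3.25)

    def test_factor_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample(ImageVolume(np.zeros((3, 8, 8)), SPACING), 4)

    def test_label_block_mode_matches_manual_count(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[:2, :2, :2] = 1          # block (0,0,0): 8/8 -> 1
        labels[0, 0, 2] = 2             # block (0,0,1): one vote of 2 vs 7 of 0 -> 0
        labels[2:, 2:, 2:] = 3          # block (1,1,1): 8/8 -> 3
        lv = LabelVolume.from_labels(labels, SPACING)
        out = downsample(lv, 2)
        assert out.labels[0, 0, 0] == 1
        assert out.labels[0, 0, 1] == 0
        assert out.labels[1, 1, 1] == 3

    def test_invariants_on_config(self):
        with pytest.raises(ValueError):
            PipelineConfig(bg_radius_um=-1)
        with pytest.raises(ValueError):
            PipelineConfig(downsample_factor=0)
        with pytest.raises(ValueError):
            PipelineConfig(colocalization_fraction=1.5)
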