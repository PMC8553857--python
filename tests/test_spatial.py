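"""Anisotropic distance transform, nearest distances, proximity statistics, VOIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselniche.segmentation import CellSpot
from vesselniche.spatial import (
    VOI,
    anisotropic_edt,
    apply_voi,
    distance_histogram,
    fit_exponential_scale,
    nearest_distances,
    proximity_fraction,
)
from vesselniche.synthetic import rasterize_scene

from conftest import SPACING, brute_force_edt


def _spot(i, x, y, z, marker="Osterix"):
    return CellSpot(i, (x, y, z), marker, 6.0, 18.0, 1.0)


class TestAnisotropicEDT:
    def test_lateral_step_closed_form(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        d = anisotropic_edt(mask, SPACING)
        assert d[4, 4, 7] == pytest.approx(3 * 1.3)  # 3 lateral steps -> 3.9 μm
        assert d[6, 4, 4] == pytest.approx(2 * 2.5)  # 2 axial steps -> 5.0 μm
        assert d[4, 4, 4] == 0.0

    def test_empty_mask_gives_infinite_map(self, caplog):
        d = anisotropic_edt(np.zeros((4, 4, 4), dtype=bool), SPACING)
        assert np.isinf(d).all()

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_exact_agreement_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 33, size=3))
        mask = rng.random(shape) < 0.02
        if not mask.any():
            mask[tuple(rng.integers(0, s) for s in shape)] = True
        d = anisotropic_edt(mask, SPACING)
        np.testing.assert_allclose(d, brute_force_edt(mask, SPACING), atol=1e-9)


class TestNearestDistances:
    def test_touching_cell_gets_exact_zero(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        recs = nearest_distances([_spot(1, 3 * 1.3, 3 * 1.3, 3 * 2.5)], {"CD31hi_EmcnHi": mask}, SPACING)
        assert recs[0].distances_um["CD31hi_EmcnHi"] == 0.0
        assert recs[0].nearest_phenotype == "CD31hi_EmcnHi"

    def test_absent_phenotype_reported_infinite(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1, 1, 1] = True
        masks = {"a": mask, "b": np.zeros_like(mask)}
        recs = nearest_distances([_spot(1, 4.0, 4.0, 4.0)], masks, SPACING)
        assert np.isinf(recs[0].distances_um["b"])
        assert np.isfinite(recs[0].distances_um["a"])

    def test_out_of_bounds_cell_is_flagged(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        recs = nearest_distances([_spot(1, 999.0, 1.0, 1.0)], {"a": mask}, SPACING)
        assert not recs[0].in_bounds
        with pytest.raises(ValueError):
            proximity_fraction(recs, 5.0, "a")

    def test_tube_distance_matches_analytic_geometry(self, straight_tube_scene):
        # tube radius 8 μm, axis at (y, z) = (30, 30); a cell 13 μm from the
        # axis is 5 μm from the surface (tolerance: half a voxel diagonal)
        _, gt = rasterize_scene(straight_tube_scene, SPACING)
        cell = _spot(1, 110.0, 43.0, 30.0)
        recs = nearest_distances([cell], {"t": gt.mask()}, SPACING)
        half_diag = 0.5 * np.sqrt(1.3**2 + 1.3**2 + 2.5**2)
        assert recs[0].distances_um["t"] == pytest.approx(5.0, abs=half_diag)

    def test_translation_invariance(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[3:5, 3:5, 3:5] = True
        cells = [_spot(1, 10.0, 9.0, 11.0)]
        r0 = nearest_distances(cells, {"a": mask}, SPACING)
        shifted_mask = np.roll(mask, (2, 1, 3), axis=(0, 1, 2))
        shifted_cells = [_spot(1, 10.0 + 3 * 1.3, 9.0 + 1 * 1.3, 11.0 + 2 * 2.5)]
        r1 = nearest_distances(shifted_cells, {"a": shifted_mask}, SPACING)
        assert r1[0].distances_um["a"] == pytest.approx(r0[0].distances_um["a"], abs=1e-9)


class TestProximitySummaries:
    def _records(self, distances, phenotype="p"):
        from vesselniche.spatial import DistanceRecord

        return [
            DistanceRecord(cell_id=i, marker="Osterix", distances_um={phenotype: d})
            for i, d in enumerate(distances)
        ]

    def test_fraction_counts_inclusive_cutoff(self):
        recs = self._records([0.0, 3.0, 7.0, 12.0])
        assert proximity_fraction(recs, 5.0, "p") == 0.5
        recs_touch = self._records([0.0, 0.0, 0.0])
        assert proximity_fraction(recs_touch, 5.0, "p") == 1.0

    def test_empty_records_error_not_zero(self):
        with pytest.raises(ValueError):
            proximity_fraction([], 5.0, "p")

    @pytest.mark.parametrize("cutoffs", [(1.0, 2.0, 5.0, 10.0, 50.0)])
    def test_fraction_monotone_in_cutoff(self, cutoffs):
        rng = np.random.default_rng(2)
        recs = self._records(rng.exponential(5.0, size=200))
        fracs = [proximity_fraction(recs, c, "p") for c in cutoffs]
        assert fracs == sorted(fracs)

    def test_histogram_single_record(self):
        recs = self._records([2.0])
        h = distance_histogram(recs, "p", [0.0, 5.0, 10.0])
        np.testing.assert_array_equal(h.counts, [1, 0])
        assert h.n_cells == 1 and h.n_infinite == 0

    def test_histogram_conserves_counts_and_reports_infinite(self):
        recs = self._records([1.0, 4.0, 6.0, 25.0, np.inf])
        h = distance_histogram(recs, "p", [0.0, 5.0, 10.0])
        assert h.counts.sum() + h.n_overflow == h.n_cells == 4
        assert h.n_infinite == 1

    def test_histogram_uniform_distances_match_binomial_expectation(self):
        rng = np.random.default_rng(5)
        n = 10_000
        recs = self._records(rng.uniform(0, 20, size=n))
        edges = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        h = distance_histogram(recs, "p", edges)
        p = 0.25
        sigma = np.sqrt(n * p * (1 - p))
        for c in h.counts:
            assert abs(c - n * p) < 3 * sigma

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram(self._records([1.0]), "p", [0.0, 5.0, 4.0])

    def test_exponential_scale_mle_is_sample_mean(self):
        recs = self._records([2.0, 4.0, 6.0])
        assert fit_exponential_scale(recs, "p") == pytest.approx(4.0)


class TestVOI:
    def test_full_volume_voi_is_identity(self):
        cells = [_spot(i, 10.0 * i, 5.0, 5.0) for i in range(1, 5)]
        voi = VOI(shape="box", origin_um=(0, 0, 0), extent_um=(1000.0, 1000.0, 1000.0))
        assert apply_voi(cells, voi) == cells

    def test_box_faces_half_open(self):
        voi = VOI(shape="box", origin_um=(0, 0, 0), extent_um=(10.0, 10.0, 10.0))
        on_lower = _spot(1, 0.0, 5.0, 5.0)
        on_upper = _spot(2, 10.0, 5.0, 5.0)
        kept = apply_voi([on_lower, on_upper], voi)
        assert kept == [on_lower]

    def test_cylinder_keeps_area_fraction_of_uniform_field(self):
        # 1 mm cylinder on a uniform 2x2 mm field keeps ~ pi/16 of the cells
        rng = np.random.default_rng(9)
        n = 20_000
        pts = rng.uniform(0, 2000.0, size=(n, 2))
        cells = [_spot(i, x, y, 50.0) for i, (x, y) in enumerate(pts)]
        voi = VOI(shape="cylinder", center_um=(1000.0, 1000.0, 0.0), diameter_um=1000.0, axis="z")
        frac = len(apply_voi(cells, voi)) / n
        p = np.pi / 16
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_label_volume_clipping_recomputes_volumes(self):
        from vesselniche.image import LabelVolume

        labels = np.zeros((4, 4, 8), dtype=np.int32)
        labels[:, :, :] = 1
        lv = LabelVolume.from_labels(labels, (1.0, 1.0, 1.0))
        voi = VOI(shape="box", origin_um=(0, 0, 0), extent_um=(4.0, 4.0, 4.0))
        clipped = apply_voi(lv, voi)
        assert clipped.table["voxel_count"].iloc[0] == 4 * 4 * 4

    def test_invalid_voi_rejected(self):
        with pytest.raises(ValueError):
            VOI(shape="box", extent_um=(0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            VOI(shape="cylinder", center_um=(0, 0, 0), diameter_um=-1.0)
        with pytest.raises(ValueError):
            VOI(shape="cylinder", center_um=(0, 0, 0), diameter_um=5.0, axis="diagonal")
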