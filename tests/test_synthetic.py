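"""Phantom generator: determinism, planted laws, geometry, round-trips."""

import json

import numpy as np
import pytest

from vesselniche.synthetic import (
    CD31HI_EMCN_HI,
    CD31HI_EMCN_NEG,
    AffinityLaw,
    NoiseModel,
    SyntheticScene,
    VesselGT,
    make_vessel_scene,
    place_cells,
    point_to_polyline_distance,
    rasterize_scene,
    read_ground_truth,
    write_ground_truth,
)

from conftest import SPACING, sample_tube_surface

EXTENT = (300.0, 300.0, 150.0)


def _counts(n):
    return {"periosteum": n, "marrow": n, "dura": n, "transcortical": n}


class TestSceneConstruction:
    def test_empty_scene_is_valid(self):
        scene = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(0), rng_seed=0)
        assert scene.vessels == []
        vols, gt = rasterize_scene(scene, SPACING)
        assert gt.n_objects == 0 and not vols["CD31"].data.any()

    def test_same_seed_gives_byte_identical_serialization(self):
        a = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(2), rng_seed=42)
        b = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(2), rng_seed=42)
        assert a.to_json() == b.to_json()
        c = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(2), rng_seed=43)
        assert a.to_json() != c.to_json()

    def test_layers_carry_expected_phenotypes(self):
        scene = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(2), rng_seed=1)
        phenos = {v.phenotype for v in scene.vessels}
        assert phenos == {"CD31hi_EmcnNeg", "CD31hi_EmcnHi", "CD31lo_EmcnHi"}
        # arteriole-type tubes stay in the thin outer layers
        for v in scene.vessels:
            if v.phenotype == CD31HI_EMCN_NEG:
                z = v.centerline[:, 2]
                assert np.all(z <= 0.15 * EXTENT[2] + 1e-9) or np.all(z >= 0.85 * EXTENT[2] - 1e-9)

    def test_overlapping_layer_spec_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_vessel_scene(EXTENT, layer_spec={"dura": (0.0, 0.5), "marrow": (0.4, 0.8), "periosteum": (0.85, 1.0)})

    def test_tube_clearance_enforced(self):
        scene = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(3), rng_seed=7, min_clearance_um=4.0)
        for i, a in enumerate(scene.vessels):
            for b in scene.vessels[i + 1 :]:
                gap = min(point_to_polyline_distance(p, b.centerline) for p in a.centerline)
                assert gap > a.radius_um + b.radius_um  # surfaces strictly disjoint

    def test_cylinder_analytic_volume_closed_form(self, straight_tube_scene):
        v = straight_tube_scene.vessels[0]
        assert v.analytic_volume_um3 == pytest.approx(np.pi * 8.0**2 * 200.0, rel=1e-12)


class TestCellPlacement:
    def test_touching_law_gives_zero_distances(self, straight_tube_scene):
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="touching")
        scene = place_cells(straight_tube_scene, 50, "Osterix", aff, rng_seed=3)
        assert all(c.true_distance_um == 0.0 for c in scene.cells)

    def test_exponential_law_matches_closed_form_cdf(self):
        # fraction within one scale length of an Exp(5 μm) law is 1 - e^-1;
        # the scene leaves generous clearance so no draw is unplaceable
        tube = VesselGT(1, np.array([[20.0, 100.0, 100.0], [380.0, 100.0, 100.0]]),
                        8.0, CD31HI_EMCN_HI, 500.0, 500.0)
        base = SyntheticScene(rng_seed=0, extent_um=(400.0, 200.0, 200.0), vessels=[tube])
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="exponential", scale_um=5.0)
        scene = place_cells(base, 10_000, "Osterix", aff, rng_seed=4)
        d = np.array([c.true_distance_um for c in scene.cells])
        assert (d <= 5.0).mean() == pytest.approx(1 - np.exp(-1), abs=0.02)
        # empirical mean within 3 standard errors of the scale
        assert abs(d.mean() - 5.0) < 3 * 5.0 / np.sqrt(10_000)

    def test_background_only_cells_uniform_with_sentinel_distance(self):
        scene = SyntheticScene(rng_seed=0, extent_um=EXTENT)
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="uniform", fraction_background=1.0)
        scene = place_cells(scene, 200, "Gli1", aff, rng_seed=5)
        assert len(scene.cells) == 200
        assert all(np.isnan(c.true_distance_um) for c in scene.cells)
        centers = np.array([c.center for c in scene.cells])
        assert (centers >= 0).all() and (centers <= np.asarray(EXTENT)).all()

    def test_missing_target_phenotype_is_an_error(self):
        scene = SyntheticScene(rng_seed=0, extent_um=EXTENT)
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="exponential", scale_um=5.0)
        with pytest.raises(ValueError, match="no vessels of target phenotype"):
            place_cells(scene, 10, "Osterix", aff, rng_seed=0)

    def test_cells_do_not_perturb_vessel_stream(self):
        base = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(2), rng_seed=9)
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="exponential", scale_um=5.0)
        a = place_cells(base, 20, "Osterix", aff, rng_seed=1)
        b = place_cells(base, 20, "Osterix", aff, rng_seed=2)
        assert [v.centerline.tolist() for v in a.vessels] == [v.centerline.tolist() for v in b.vessels]
        assert a.cells[0].center.tolist() != b.cells[0].center.tolist()

    def test_analytic_distance_matches_brute_force_surface_sampling(self):
        scene = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(1), rng_seed=13)
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="uniform", max_um=15.0)
        scene = place_cells(scene, 5, "Osterix", aff, rng_seed=13)
        targets = scene.vessels_of(CD31HI_EMCN_HI)
        surface = np.vstack([sample_tube_surface(v) for v in targets])
        for c in scene.cells:
            brute = np.linalg.norm(surface - c.center, axis=1).min()
            inside = any(
                point_to_polyline_distance(c.center, v.centerline) < v.radius_um for v in targets
            )
            expected = 0.0 if inside else brute
            assert c.true_distance_um == pytest.approx(expected, abs=0.1)


class TestRasterization:
    def test_cylinder_voxel_volume_close_to_closed_form(self, straight_tube_scene):
        _, gt = rasterize_scene(straight_tube_scene, SPACING)
        voxvol = np.prod(SPACING)
        measured = gt.mask().sum() * voxvol
        assert measured == pytest.approx(np.pi * 8.0**2 * 200.0, rel=0.05)

    def test_zero_noise_render_is_deterministic(self, straight_tube_scene):
        v1, _ = rasterize_scene(straight_tube_scene, SPACING, noise=NoiseModel())
        v2, _ = rasterize_scene(straight_tube_scene, SPACING, noise=None)
        for ch in v1:
            np.testing.assert_array_equal(v1[ch].data, v2[ch].data)

    def test_noise_model_changes_but_reproduces_with_seed(self, straight_tube_scene):
        nm = NoiseModel(psf_sigma_um=(1.0, 1.0, 2.0), background_level=5.0, poisson_gain=1.0, rng_seed=8)
        a, _ = rasterize_scene(straight_tube_scene, SPACING, noise=nm)
        b, _ = rasterize_scene(straight_tube_scene, SPACING, noise=nm)
        clean, _ = rasterize_scene(straight_tube_scene, SPACING)
        np.testing.assert_array_equal(a["CD31"].data, b["CD31"].data)
        assert not np.array_equal(a["CD31"].data, clean["CD31"].data)

    def test_emcn_negative_tube_is_dark_in_emcn_channel(self):
        tube = VesselGT(1, np.array([[10.0, 30.0, 30.0], [190.0, 30.0, 30.0]]), 8.0, CD31HI_EMCN_NEG, 500.0, 0.0)
        scene = SyntheticScene(rng_seed=0, extent_um=(200.0, 60.0, 60.0), vessels=[tube])
        vols, gt = rasterize_scene(scene, SPACING)
        inside = gt.mask()
        assert vols["Emcn"].data[inside].max() == 0.0
        assert vols["CD31"].data[inside].min() == 500.0


class TestGroundTruthIO:
    def test_round_trip_is_lossless(self, tmp_path):
        scene = make_vessel_scene(EXTENT, n_vessels_per_layer=_counts(1), rng_seed=21)
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="exponential", scale_um=5.0)
        scene = place_cells(scene, 100, "Osterix", aff, rng_seed=21)
        write_ground_truth(scene, tmp_path)
        back = read_ground_truth(tmp_path)
        assert back.to_json() == scene.to_json()

    def test_table_cardinality(self, tmp_path):
        import pandas as pd

        scene = make_vessel_scene(
            EXTENT, n_vessels_per_layer={"periosteum": 1, "marrow": 1, "dura": 0, "transcortical": 1}, rng_seed=2
        )
        aff = AffinityLaw(target_phenotype=CD31HI_EMCN_HI, law="touching")
        scene = place_cells(scene, 100, "Gli1", aff, rng_seed=2)
        write_ground_truth(scene, tmp_path)
        assert len(pd.read_csv(tmp_path / "vessels.csv")) == 3
        assert len(pd.read_csv(tmp_path / "cells.csv")) == 100

    def test_empty_scene_writes_valid_files(self, tmp_path):
        scene = SyntheticScene(rng_seed=0, extent_um=EXTENT)
        write_ground_truth(scene, tmp_path)
        assert json.loads((tmp_path / "scene.json").read_text())["vessels"] == []
        assert read_ground_truth(tmp_path).vessels == []
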