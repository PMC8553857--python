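"""Shared fixtures and independent oracles.

Oracles here are deliberately naive re-implementations (brute force /
morphology) used only to check the package's fast paths; they never share
code with the implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.ndimage as ndi

from vesselniche.synthetic import CD31HI_EMCN_HI, HI_INTENSITY, SyntheticScene, VesselGT

SPACING = (1.3, 1.3, 2.5)  # published lateral / axial voxel spacing (μm)


@pytest.fixture
def straight_tube_scene() -> SyntheticScene:
    """One straight tube: radius 8 μm, length 200 μm along x."""
    tube = VesselGT(
        id=1,
        centerline=np.array([[10.0, 30.0, 30.0], [210.0, 30.0, 30.0]]),
        radius_um=8.0,
        phenotype=CD31HI_EMCN_HI,
        intensity_cd31=HI_INTENSITY,
        intensity_emcn=HI_INTENSITY,
    )
    return SyntheticScene(rng_seed=0, extent_um=(220.0, 60.0, 60.0), vessels=[tube])


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_edt(mask: np.ndarray, spacing_um) -> np.ndarray:
    """Min-over-mask-voxels Euclidean distance, via a KD-tree on scaled points."""
    from scipy.spatial import cKDTree

    spacing_zyx = np.asarray(spacing_um, dtype=float)[::-1]
    pts = np.argwhere(mask) * spacing_zyx
    tree = cKDTree(pts)
    grid = np.indices(mask.shape).reshape(3, -1).T * spacing_zyx
    d, _ = tree.query(grid, k=1)
    return d.reshape(mask.shape)


def rolling_ball_background(data: np.ndarray, radius_um: float, spacing_um) -> np.ndarray:
    """Morphological (flat-ellipsoid) rolling-ball background estimate."""
    spacing_zyx = np.asarray(spacing_um, dtype=float)[::-1]
    r = np.maximum(np.round(radius_um / spacing_zyx).astype(int), 1)
    zz, yy, xx = np.mgrid[-r[0] : r[0] + 1, -r[1] : r[1] + 1, -r[2] : r[2] + 1]
    footprint = (zz / r[0]) ** 2 + (yy / r[1]) ** 2 + (xx / r[2]) ** 2 <= 1.0
    return ndi.grey_opening(data, footprint=footprint, mode="nearest")


def sample_tube_surface(vessel: VesselGT, step_um: float = 0.05) -> np.ndarray:
    """Densely sampled points on a capsule surface (brute-force geometry oracle)."""
    pts = []
    cl = vessel.centerline
    r = vessel.radius_um
    n_circ = max(int(np.ceil(2 * np.pi * r / step_um)), 8)
    angles = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    for a, b in zip(cl[:-1], cl[1:]):
        axis = b - a
        length = np.linalg.norm(axis)
        axis = axis / length
        # orthonormal frame around the segment axis
        helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, helper)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        ts = np.arange(0, length + step_um, step_um)
        ring = r * (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))
        for t in ts:
            pts.append(a + t * axis + ring)
    # interior joint spheres and flat end disks (the tube model has no end caps)
    for c in cl[1:-1]:
        phi = np.linspace(0, np.pi, 64)
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        pp, tt = np.meshgrid(phi, theta)
        sphere = np.stack(
            [np.sin(pp) * np.cos(tt), np.sin(pp) * np.sin(tt), np.cos(pp)], axis=-1
        ).reshape(-1, 3)
        pts.append(c + r * sphere)
    for c, axis_pt in ((cl[0], cl[1]), (cl[-1], cl[-2])):
        axis = axis_pt - c
        axis = axis / np.linalg.norm(axis)
        helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, helper)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        for rho in np.arange(0, r + step_um, step_um):
            ring = rho * (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))
            pts.append(c + ring)
    return np.vstack(pts)


def digitized_sphere(radius_vox: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius_vox + pad) + 1
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
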