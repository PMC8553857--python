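"""Synthetic 3D phantoms of the calvarial microvascular niche.

The generator emulates the tissue architecture the analysis pipeline assumes:
tubular vessels of three intensity phenotypes arranged in three tissue layers
(periosteum-analog on top, marrow-analog in the middle, dura-analog at the
bottom), with arteriole-type CD31hi/Emcn-negative tubes in the thin outer
layers, Emcn-only sinusoid-type tubes in the marrow layer, and dual-positive
capillary tubes crossing all layers (the transcortical-canal analog).
Progenitor nuclei are placed with a configurable spatial affinity to a chosen
vessel phenotype, so every downstream stage can be validated against exact
ground truth without any acquired data.

Vessels are modelled as tube unions: piecewise-linear centrelines with a
constant radius per vessel, rendered as open-ended cylinders per segment with
spheres at interior joints (so a straight tube has volume exactly pi*r^2*L).
This makes the point-to-surface distance exact and cheap, which is what the
planted cell--vessel distances rely on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .image import ImageVolume, LabelVolume

__all__ = [
    "PHENOTYPES",
    "CD31HI_EMCN_NEG",
    "CD31HI_EMCN_HI",
    "CD31LO_EMCN_HI",
    "SPOT_SIZE_UM",
    "GLOBAL_THRESHOLD",
    "HI_INTENSITY",
    "LO_INTENSITY",
    "VesselGT",
    "CellGT",
    "AffinityLaw",
    "NoiseModel",
    "SyntheticScene",
    "make_vessel_scene",
    "place_cells",
    "rasterize_scene",
    "write_ground_truth",
    "read_ground_truth",
    "point_to_polyline_distance",
]

# Vessel phenotype identifiers (CD31 = pan-endothelial, Emcn = endomucin).
CD31HI_EMCN_NEG = "CD31hi_EmcnNeg"   # arteries / arterioles
CD31HI_EMCN_HI = "CD31hi_EmcnHi"     # dual-positive capillaries (type-H analog)
CD31LO_EMCN_HI = "CD31lo_EmcnHi"     # capillaries / sinusoids
PHENOTYPES = (CD31HI_EMCN_NEG, CD31HI_EMCN_HI, CD31LO_EMCN_HI)

# Pre-measured nuclear spot sizes (lateral, axial) in μm per marker.
SPOT_SIZE_UM = {"Gli1": (5.0, 15.0), "Osterix": (6.0, 18.0)}

# Intensity convention: "hi" channels render at >= 5x the default global
# threshold used downstream, "lo" at <= 0.5x, so phenotype ground truth is
# unambiguous under default thresholds.
GLOBAL_THRESHOLD = 100.0
HI_INTENSITY = 5.0 * GLOBAL_THRESHOLD
LO_INTENSITY = 0.5 * GLOBAL_THRESHOLD
CELL_AMPLITUDE = 1000.0

# Channel intensities (cd31, emcn) implied by each phenotype.
_PHENOTYPE_INTENSITY = {
    CD31HI_EMCN_NEG: (HI_INTENSITY, 0.0),
    CD31HI_EMCN_HI: (HI_INTENSITY, HI_INTENSITY),
    CD31LO_EMCN_HI: (LO_INTENSITY, HI_INTENSITY),
}

# Sub-step ids for the splittable RNG: adding cells never perturbs vessels.
_RNG_STREAMS = {"vessels": 0, "cells": 1, "noise": 2}


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_RNG_STREAMS[stream],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def point_to_polyline_distance(point_xyz, centerline) -> float:
    """Exact Euclidean distance from a point to a piecewise-linear centreline."""
    p = np.asarray(point_xyz, dtype=float)
    c = np.asarray(centerline, dtype=float)
    if c.shape[0] == 1:
        return float(np.linalg.norm(p - c[0]))
    a = c[:-1]
    b = c[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((p - proj) ** 2).sum(axis=1)).min())


def _grid_to_polyline_distance(points: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    """Min distance from each of N points (N,3) to the polyline (vectorised)."""
    c = np.asarray(centerline, dtype=float)
    dmin = np.full(points.shape[0], np.inf)
    for a, b in zip(c[:-1], c[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(points - proj, axis=1)
        np.minimum(dmin, d, out=dmin)
    if c.shape[0] == 1:
        dmin = np.linalg.norm(points - c[0], axis=1)
    return dmin


def _grid_to_tube_distance(points: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    """Distance to an *open-ended* tube axis: per-segment perpendicular bands
    plus spheres at interior joints (no spherical caps at the tube ends), so a
    straight tube rasterises to a true cylinder of volume pi*r^2*L."""
    c = np.asarray(centerline, dtype=float)
    dmin = np.full(points.shape[0], np.inf)
    for a, b in zip(c[:-1], c[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = (points - a) @ ab / denom
        band = (t >= 0.0) & (t <= 1.0)
        proj = a + np.clip(t, 0.0, 1.0)[:, None] * ab
        d = np.linalg.norm(points - proj, axis=1)
        np.minimum(dmin, np.where(band, d, np.inf), out=dmin)
    for joint in c[1:-1]:
        np.minimum(dmin, np.linalg.norm(points - joint, axis=1), out=dmin)
    return dmin


def _grid_to_tube_surface_distance(points: np.ndarray, centerline: np.ndarray, radius: float) -> np.ndarray:
    """Exact distance from points to the solid open-ended tube (0 inside).

    Handles points beyond a tube end correctly (distance to the flat end
    disk or its rim), which an axis-distance-minus-radius formula cannot.
    """
    c = np.asarray(centerline, dtype=float)
    dmin = np.full(points.shape[0], np.inf)
    for a, b in zip(c[:-1], c[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        length = np.sqrt(denom)
        t = (points - a) @ ab / denom
        proj = a + t[:, None] * ab
        rho = np.linalg.norm(points - proj, axis=1)
        overhang = np.maximum(np.maximum(-t, t - 1.0), 0.0) * length
        radial = np.maximum(rho - radius, 0.0)
        d = np.hypot(overhang, radial)
        np.minimum(dmin, d, out=dmin)
    for joint in c[1:-1]:
        d = np.maximum(np.linalg.norm(points - joint, axis=1) - radius, 0.0)
        np.minimum(dmin, d, out=dmin)
    return dmin


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class VesselGT:
    """Ground-truth vessel: capsule union around a piecewise-linear centreline."""

    id: int
    centerline: np.ndarray  # (N, 3) physical (x, y, z) μm, N >= 2
    radius_um: float
    phenotype: str
    intensity_cd31: float
    intensity_emcn: float

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3 or self.centerline.shape[0] < 2:
            raise ValueError("centerline must be an (N>=2, 3) array of μm points")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    @property
    def analytic_volume_um3(self) -> float:
        """Cylinder volume pi * r^2 * L along the centreline (caps ignored)."""
        return float(np.pi * self.radius_um**2 * self.length_um)

    def surface_distance(self, point_xyz) -> float:
        """Distance from a point to the tube surface, clamped at 0 inside.

        The tube is the union of open-ended cylinders around each centreline
        segment plus spheres at interior joints (no end caps), matching the
        rasterised geometry exactly.
        """
        p = np.atleast_2d(np.asarray(point_xyz, dtype=float))
        return float(_grid_to_tube_surface_distance(p, self.centerline, self.radius_um)[0])


@dataclass
class CellGT:
    """Ground-truth progenitor nucleus."""

    id: int
    center: np.ndarray  # (x, y, z) μm
    marker: str
    lateral_diam_um: float
    axial_diam_um: float
    # Distance from the cell centre to the analytic surface of the nearest
    # vessel of the affinity's target phenotype; NaN when no target exists.
    true_distance_um: float = float("nan")

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("cell center must be a 3-vector (x, y, z) μm")
        if self.lateral_diam_um <= 0 or self.axial_diam_um <= 0:
            raise ValueError("cell diameters must be positive")


@dataclass
class AffinityLaw:
    """Planted distance-to-vessel law for cell placement.

    ``law`` is one of ``"exponential"`` (parameter ``scale_um``), ``"uniform"``
    (parameter ``max_um``) or ``"touching"`` (all planted distances are 0).
    ``fraction_background`` of cells are instead placed uniformly at random in
    the volume irrespective of vessels.
    """

    target_phenotype: str
    law: str = "exponential"
    scale_um: float = 5.0
    max_um: float = 20.0
    fraction_background: float = 0.0

    def __post_init__(self) -> None:
        if self.law not in ("exponential", "uniform", "touching"):
            raise ValueError(f"unknown affinity law {self.law!r}")
        if self.law == "exponential" and self.scale_um <= 0:
            raise ValueError("scale_um must be positive")
        if self.law == "uniform" and self.max_um <= 0:
            raise ValueError("max_um must be positive")
        if not 0.0 <= self.fraction_background <= 1.0:
            raise ValueError("fraction_background must lie in [0, 1]")
        if self.target_phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.target_phenotype!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.law == "touching":
            return 0.0
        if self.law == "exponential":
            return float(rng.exponential(self.scale_um))
        return float(rng.uniform(0.0, self.max_um))


@dataclass
class NoiseModel:
    """Imaging degradation applied to the clean raster.

    All-zero parameters reproduce the clean raster exactly.  ``psf_sigma_um``
    is the Gaussian blur (x, y, z); ``poisson_gain`` converts intensity to
    expected photon counts (0 disables shot noise); ``gaussian_sigma`` is
    additive read noise.
    """

    psf_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_level: float = 0.0
    poisson_gain: float = 0.0
    gaussian_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.psf_sigma_um = tuple(float(s) for s in self.psf_sigma_um)  # type: ignore[assignment]
        if any(s < 0 for s in self.psf_sigma_um) or self.poisson_gain < 0 or self.gaussian_sigma < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def is_clean(self) -> bool:
        return (
            all(s == 0 for s in self.psf_sigma_um)
            and self.background_level == 0
            and self.poisson_gain == 0
            and self.gaussian_sigma == 0
        )


@dataclass
class SyntheticScene:
    """Full ground-truth description of a phantom."""

    rng_seed: int
    extent_um: tuple[float, float, float]
    vessels: list[VesselGT] = field(default_factory=list)
    cells: list[CellGT] = field(default_factory=list)
    affinity: AffinityLaw | None = None

    def __post_init__(self) -> None:
        self.extent_um = tuple(float(e) for e in self.extent_um)  # type: ignore[assignment]
        if any(e <= 0 for e in self.extent_um):
            raise ValueError("extent must be positive along all axes")
        ext = np.asarray(self.extent_um)
        for v in self.vessels:
            if (v.centerline < -1e-9).any() or (v.centerline > ext + 1e-9).any():
                raise ValueError(f"vessel {v.id} centreline leaves the scene extent")

    def vessels_of(self, phenotype: str) -> list[VesselGT]:
        return [v for v in self.vessels if v.phenotype == phenotype]

    def min_surface_distance(self, point_xyz, phenotype: str) -> float:
        """Analytic distance from a point to the nearest tube surface of a phenotype."""
        tubes = self.vessels_of(phenotype)
        if not tubes:
            return float("nan")
        return min(v.surface_distance(point_xyz) for v in tubes)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "rng_seed": self.rng_seed,
            "extent_um": list(self.extent_um),
            "vessels": [
                {**asdict(v), "centerline": v.centerline.tolist()} for v in self.vessels
            ],
            "cells": [{**asdict(c), "center": c.center.tolist()} for c in self.cells],
            "affinity": asdict(self.affinity) if self.affinity else None,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, allow_nan=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScene":
        return cls(
            rng_seed=d["rng_seed"],
            extent_um=tuple(d["extent_um"]),
            vessels=[VesselGT(**v) for v in d["vessels"]],
            cells=[CellGT(**c) for c in d["cells"]],
            affinity=AffinityLaw(**d["affinity"]) if d.get("affinity") else None,
        )


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

# Default layer layout: periosteum-analog / marrow-analog / dura-analog
# occupying 15 / 70 / 15 % of the z extent (dura at z=0).
DEFAULT_LAYER_SPEC = {
    "dura": (0.0, 0.15),
    "marrow": (0.15, 0.85),
    "periosteum": (0.85, 1.0),
}

# Which phenotype each layer's tubes carry; "transcortical" tubes span all
# layers and are the dual-positive capillary analog.
_LAYER_PHENOTYPE = {
    "periosteum": CD31HI_EMCN_NEG,
    "dura": CD31HI_EMCN_NEG,
    "marrow": CD31LO_EMCN_HI,
    "transcortical": CD31HI_EMCN_HI,
}

# Tube radius ranges (μm) by phenotype: arterioles widest, capillaries thinnest.
_RADIUS_RANGE = {
    CD31HI_EMCN_NEG: (6.0, 9.0),
    CD31LO_EMCN_HI: (5.0, 8.0),
    CD31HI_EMCN_HI: (4.0, 6.5),
}


def _validate_layer_spec(layer_spec: dict) -> None:
    intervals = []
    for name, (lo, hi) in layer_spec.items():
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"layer {name!r} fractions ({lo}, {hi}) must satisfy 0 <= lo < hi <= 1")
        intervals.append((lo, hi, name))
    intervals.sort()
    for (l0, h0, n0), (l1, h1, n1) in zip(intervals[:-1], intervals[1:]):
        if l1 < h0 - 1e-12:
            raise ValueError(f"layers {n0!r} and {n1!r} overlap")


def _wiggly_tube(
    rng: np.random.Generator,
    extent: np.ndarray,
    z_range: tuple[float, float],
    radius: float,
    n_segments: int = 8,
) -> np.ndarray:
    """An in-layer tube: mostly horizontal, randomly wiggled, kept in its layer."""
    zlo, zhi = z_range
    margin = min(radius, (zhi - zlo) / 2.0)
    lo = np.array([radius, radius, zlo + margin])
    hi = np.array([extent[0] - radius, extent[1] - radius, zhi - margin])
    start = rng.uniform(lo, np.maximum(lo, hi))
    theta = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    step = max(extent[:2].max() / n_segments, 4 * radius)
    pts = [start]
    for _ in range(n_segments):
        jitter = rng.normal(scale=[0.3, 0.3, 0.08])
        d = direction + jitter
        d /= np.linalg.norm(d)
        nxt = np.clip(pts[-1] + d * step, lo, np.maximum(lo, hi))
        pts.append(nxt)
        direction = 0.7 * direction + 0.3 * d
        direction /= np.linalg.norm(direction)
    return np.asarray(pts)


def _transcortical_tube(
    rng: np.random.Generator, extent: np.ndarray, radius: float, n_segments: int = 6
) -> np.ndarray:
    """A dual-positive tube crossing the layers along z (transcortical analog)."""
    x = rng.uniform(2 * radius, extent[0] - 2 * radius)
    y = rng.uniform(2 * radius, extent[1] - 2 * radius)
    z0 = 0.03 * extent[2]
    z1 = 0.97 * extent[2]
    zs = np.linspace(z0, z1, n_segments + 1)
    pts = []
    for z in zs:
        dx, dy = rng.normal(scale=0.04 * extent[:2])
        px = float(np.clip(x + dx, radius, extent[0] - radius))
        py = float(np.clip(y + dy, radius, extent[1] - radius))
        pts.append([px, py, float(z)])
    return np.asarray(pts)


def _min_surface_gap(vessels: list[VesselGT], centerline: np.ndarray, radius: float) -> float:
    """Smallest surface-to-surface gap between a candidate tube and existing tubes."""
    if not vessels:
        return np.inf
    # sample the candidate densely enough to bound the polyline-polyline distance
    seg = np.diff(centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    pts = [centerline[0]]
    for a, d, L in zip(centerline[:-1], seg, seg_len):
        n = max(int(np.ceil(L / 2.0)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + t * d)
    pts = np.asarray(pts)
    gap = np.inf
    for v in vessels:
        d = _grid_to_polyline_distance(pts, v.centerline).min()
        gap = min(gap, d - v.radius_um - radius)
    return float(gap)


def make_vessel_scene(
    extent_um,
    layer_spec: dict | None = None,
    n_vessels_per_layer: dict | None = None,
    rng_seed: int = 0,
    min_clearance_um: float = 4.0,
) -> SyntheticScene:
    """Generate a phantom vessel network with phenotype-labelled tubes.

    Parameters
    ----------
    extent_um : (x, y, z)
        Scene size in micrometres.
    layer_spec : dict, optional
        Mapping ``{"dura": (z0, z1), "marrow": ..., "periosteum": ...}`` of
        fractional, non-overlapping z intervals.  Default 15/70/15 %.
    n_vessels_per_layer : dict, optional
        Tube counts per layer; the extra key ``"transcortical"`` counts
        dual-positive tubes spanning all layers.  Default 4 each.
    rng_seed : int
        Single seed; vessel geometry uses its own RNG stream so later cell
        placement does not perturb it.
    min_clearance_um : float
        Minimum surface-to-surface gap enforced between distinct tubes
        (vessels do not interpenetrate in tissue); candidate tubes violating
        it are rejected and redrawn.  Set to a negative value to disable.
    """
    extent = np.asarray([float(e) for e in extent_um])
    if (extent <= 0).any():
        raise ValueError("extent must be positive")
    layer_spec = dict(DEFAULT_LAYER_SPEC if layer_spec is None else layer_spec)
    _validate_layer_spec(layer_spec)
    if n_vessels_per_layer is None:
        n_vessels_per_layer = {name: 4 for name in (*layer_spec, "transcortical")}
    if any(int(n) < 0 for n in n_vessels_per_layer.values()):
        raise ValueError("vessel counts must be >= 0")
    unknown = set(n_vessels_per_layer) - set(layer_spec) - {"transcortical"}
    if unknown:
        raise ValueError(f"counts given for unknown layers: {sorted(unknown)}")

    rng = _stream_rng(rng_seed, "vessels")
    vessels: list[VesselGT] = []
    vid = 1
    for layer in sorted(layer_spec):
        n = int(n_vessels_per_layer.get(layer, 0))
        phe = _LAYER_PHENOTYPE[layer]
        lo_f, hi_f = layer_spec[layer]
        z_range = (lo_f * extent[2], hi_f * extent[2])
        for _ in range(n):
            radius = float(rng.uniform(*_RADIUS_RANGE[phe]))
            for _try in range(200):
                cl = _wiggly_tube(rng, extent, z_range, radius)
                if _min_surface_gap(vessels, cl, radius) >= min_clearance_um:
                    break
            else:
                raise RuntimeError(
                    f"could not place a {phe} tube in layer {layer!r} with "
                    f"{min_clearance_um} μm clearance; reduce the vessel count"
                )
            icd31, iemcn = _PHENOTYPE_INTENSITY[phe]
            vessels.append(VesselGT(vid, cl, radius, phe, icd31, iemcn))
            vid += 1
    for _ in range(int(n_vessels_per_layer.get("transcortical", 0))):
        phe = _LAYER_PHENOTYPE["transcortical"]
        radius = float(rng.uniform(*_RADIUS_RANGE[phe]))
        for _try in range(200):
            cl = _transcortical_tube(rng, extent, radius)
            if _min_surface_gap(vessels, cl, radius) >= min_clearance_um:
                break
        else:
            raise RuntimeError(
                f"could not place a transcortical tube with {min_clearance_um} μm "
                "clearance; reduce the vessel count"
            )
        icd31, iemcn = _PHENOTYPE_INTENSITY[phe]
        vessels.append(VesselGT(vid, cl, radius, phe, icd31, iemcn))
        vid += 1

    return SyntheticScene(rng_seed=int(rng_seed), extent_um=tuple(extent), vessels=vessels)


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

_PLACEMENT_TOL_UM = 0.1
_MAX_TRIES = 500


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def place_cells(
    scene: SyntheticScene,
    n_cells: int,
    marker: str,
    affinity: AffinityLaw,
    rng_seed: int,
) -> SyntheticScene:
    """Plant ``n_cells`` nuclei whose surface distances follow the affinity law.

    Each affinity-placed cell draws a distance ``d`` from the law, is put at
    ``d`` from a random point on the surface of a random target-phenotype
    tube, and is accepted only if its exact analytic distance to the nearest
    target tube (capsule union) agrees with ``d`` within 0.1 μm and the cell
    lies inside the scene — so the recorded ``true_distance_um`` follows the
    law.  Background cells are uniform in the extent.
    """
    if marker not in SPOT_SIZE_UM:
        raise ValueError(f"unknown marker {marker!r}; known: {sorted(SPOT_SIZE_UM)}")
    targets = scene.vessels_of(affinity.target_phenotype)
    if not targets and affinity.fraction_background < 1.0:
        raise ValueError(
            f"no vessels of target phenotype {affinity.target_phenotype!r} in the scene; "
            "cannot place affinity cells"
        )
    rng = _stream_rng(rng_seed, "cells")
    extent = np.asarray(scene.extent_um)
    lat, ax = SPOT_SIZE_UM[marker]
    lengths = np.array([v.length_um for v in targets]) if targets else None
    weights = lengths / lengths.sum() if targets else None

    cells = list(scene.cells)
    next_id = max((c.id for c in cells), default=0) + 1
    for _ in range(int(n_cells)):
        if rng.uniform() < affinity.fraction_background:
            pos = rng.uniform(np.zeros(3), extent)
            d_true = scene.min_surface_distance(pos, affinity.target_phenotype)
        else:
            d = affinity.sample(rng)
            pos = None
            for _try in range(_MAX_TRIES):
                v = targets[int(rng.choice(len(targets), p=weights))]
                # random point on the tube axis, weighted by segment length
                seg = np.diff(v.centerline, axis=0)
                seg_len = np.linalg.norm(seg, axis=1)
                si = int(rng.choice(len(seg_len), p=seg_len / seg_len.sum()))
                t = rng.uniform()
                c = v.centerline[si] + t * seg[si]
                u = _random_unit_vector(rng)
                cand = c + u * (v.radius_um + d)
                if (cand < 0).any() or (cand > extent).any():
                    continue
                d_actual = scene.min_surface_distance(cand, affinity.target_phenotype)
                if abs(d_actual - d) <= _PLACEMENT_TOL_UM:
                    pos = cand
                    d_true = d_actual if affinity.law != "touching" else 0.0
                    break
            if pos is None:
                raise RuntimeError(
                    f"could not place a cell at distance {d:.2f} μm after {_MAX_TRIES} tries; "
                    "scene too crowded for the requested affinity law"
                )
        cells.append(
            CellGT(
                id=next_id,
                center=np.clip(pos, 0.0, extent),
                marker=marker,
                lateral_diam_um=lat,
                axial_diam_um=ax,
                true_distance_um=float(d_true),
            )
        )
        next_id += 1
    return replace(scene, cells=cells, affinity=affinity)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _tube_mask_in_bbox(
    vessel: VesselGT, shape_zyx, spacing_xyz: np.ndarray
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Voxel-centre-inside-capsule mask restricted to the tube bounding box."""
    r = vessel.radius_um
    lo = vessel.centerline.min(axis=0) - r
    hi = vessel.centerline.max(axis=0) + r
    # voxel index range whose centres could fall inside (centre of i = (i+.5)s)
    i_lo = np.maximum(np.floor(lo / spacing_xyz - 0.5).astype(int), 0)
    i_hi = np.minimum(np.ceil(hi / spacing_xyz - 0.5).astype(int) + 1, np.asarray(shape_zyx)[::-1])
    if (i_lo >= i_hi).any():
        return (slice(0, 0), slice(0, 0), slice(0, 0)), np.zeros((0, 0, 0), bool)
    sl = tuple(slice(int(i_lo[a]), int(i_hi[a])) for a in (2, 1, 0))
    zz, yy, xx = np.meshgrid(
        (np.arange(i_lo[2], i_hi[2]) + 0.5) * spacing_xyz[2],
        (np.arange(i_lo[1], i_hi[1]) + 0.5) * spacing_xyz[1],
        (np.arange(i_lo[0], i_hi[0]) + 0.5) * spacing_xyz[0],
        indexing="ij",
    )
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    d = _grid_to_tube_distance(pts, vessel.centerline)
    mask = (d <= r).reshape(zz.shape)
    return sl, mask


def rasterize_scene(
    scene: SyntheticScene,
    spacing_um=(1.3, 1.3, 2.5),
    noise: NoiseModel | None = None,
) -> tuple[dict[str, ImageVolume], LabelVolume]:
    """Render the scene to CD31 / Emcn / cell channels plus ground-truth labels.

    A voxel belongs to a tube when its centre lies inside the capsule union.
    Overlapping tubes keep the intensity maximum per channel; the label volume
    assigns each voxel to the first (lowest-id) tube containing it.  Cells are
    rendered as anisotropic Gaussian blobs with sigma = diameter / 4.
    """
    spacing = np.asarray([float(s) for s in spacing_um])
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    extent = np.asarray(scene.extent_um)
    shape_xyz = np.ceil(extent / spacing - 1e-9).astype(int)
    if (shape_xyz < 1).any():
        raise ValueError("extent/spacing must yield at least one voxel per axis")
    shape_zyx = tuple(int(n) for n in shape_xyz[::-1])

    cd31 = np.zeros(shape_zyx, dtype=np.float64)
    emcn = np.zeros(shape_zyx, dtype=np.float64)
    labels = np.zeros(shape_zyx, dtype=np.int32)
    phenotype_of: dict[int, str] = {}
    for v in scene.vessels:
        sl, mask = _tube_mask_in_bbox(v, shape_zyx, spacing)
        if mask.size == 0 or not mask.any():
            phenotype_of[v.id] = v.phenotype
            continue
        np.maximum(cd31[sl], np.where(mask, v.intensity_cd31, 0.0), out=cd31[sl])
        np.maximum(emcn[sl], np.where(mask, v.intensity_emcn, 0.0), out=emcn[sl])
        sub = labels[sl]
        sub[mask & (sub == 0)] = v.id
        phenotype_of[v.id] = v.phenotype

    cellch = np.zeros(shape_zyx, dtype=np.float64)
    for c in scene.cells:
        sig = np.array([c.lateral_diam_um, c.lateral_diam_um, c.axial_diam_um]) / 4.0  # xyz μm
        lo = np.maximum(np.floor((c.center - 4 * sig) / spacing - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((c.center + 4 * sig) / spacing - 0.5).astype(int) + 1, shape_xyz)
        if (lo >= hi).any():
            continue
        sl = tuple(slice(int(lo[a]), int(hi[a])) for a in (2, 1, 0))
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[2], hi[2]) + 0.5) * spacing[2],
            (np.arange(lo[1], hi[1]) + 0.5) * spacing[1],
            (np.arange(lo[0], hi[0]) + 0.5) * spacing[0],
            indexing="ij",
        )
        q = ((xx - c.center[0]) / sig[0]) ** 2 + ((yy - c.center[1]) / sig[1]) ** 2 + (
            (zz - c.center[2]) / sig[2]
        ) ** 2
        cellch[sl] += CELL_AMPLITUDE * np.exp(-0.5 * q)

    markers = {c.marker for c in scene.cells}
    cell_channel_name = markers.pop() if len(markers) == 1 else "cells"

    if noise is not None and not noise.is_clean:
        nrng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(noise.rng_seed), spawn_key=(_RNG_STREAMS["noise"],))
        )
        processed = []
        for img in (cd31, emcn, cellch):
            out = img
            if any(s > 0 for s in noise.psf_sigma_um):
                sigma_vox = np.asarray(noise.psf_sigma_um)[::-1] / spacing[::-1]
                out = ndi.gaussian_filter(out, sigma=sigma_vox, mode="nearest")
            out = out + noise.background_level
            if noise.poisson_gain > 0:
                out = nrng.poisson(np.maximum(out, 0.0) / noise.poisson_gain) * noise.poisson_gain
                out = out.astype(np.float64)
            if noise.gaussian_sigma > 0:
                out = out + nrng.normal(scale=noise.gaussian_sigma, size=out.shape)
            processed.append(np.maximum(out, 0.0))
        cd31, emcn, cellch = processed

    sp = tuple(spacing)
    volumes = {
        "CD31": ImageVolume(cd31, sp, channel="CD31"),
        "Emcn": ImageVolume(emcn, sp, channel="Emcn"),
        cell_channel_name: ImageVolume(cellch, sp, channel=cell_channel_name),
    }
    gt = LabelVolume.from_labels(labels, sp, extra_columns={"phenotype": phenotype_of})
    # objects fully outside the grid still appear in the scene, not the raster
    return volumes, gt


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------

def write_ground_truth(scene: SyntheticScene, path) -> None:
    """Write the scene descriptor (JSON) plus vessel and cell CSV tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "scene.json").write_text(scene.to_json())
    pd.DataFrame(
        [
            {
                "id": v.id,
                "phenotype": v.phenotype,
                "radius_um": v.radius_um,
                "analytic_volume_um3": v.analytic_volume_um3,
            }
            for v in scene.vessels
        ],
        columns=["id", "phenotype", "radius_um", "analytic_volume_um3"],
    ).to_csv(path / "vessels.csv", index=False)
    pd.DataFrame(
        [
            {
                "id": c.id,
                "x": c.center[0],
                "y": c.center[1],
                "z": c.center[2],
                "marker": c.marker,
                "true_distance_um": c.true_distance_um,
            }
            for c in scene.cells
        ],
        columns=["id", "x", "y", "z", "marker", "true_distance_um"],
    ).to_csv(path / "cells.csv", index=False)


def read_ground_truth(path) -> SyntheticScene:
    """Read a scene written by :func:`write_ground_truth` (lossless)."""
    path = Path(path)
    return SyntheticScene.from_dict(json.loads((path / "scene.json").read_text()))
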