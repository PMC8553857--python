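"""Ground-truth validation helpers.

Runs the analysis chain in memory on a synthetic scene and scores recovery
against the scene's exact ground truth: per-object phenotype classification
accuracy, phenotype volume fractions, and planted cell--vessel distance
statistics.  This is the harness behind the package's self-validation; it
uses only public pipeline operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import LabelVolume
from .phenotype import (
    VesselSegment,
    classify_vessel_phenotypes,
    fullres_phenotype_masks,
    summarize_phenotype_volumes,
)
from .segmentation import PipelineConfig, downsample, segment_vessels, split_objects, subtract_background
from .spatial import nearest_distances
from .synthetic import GLOBAL_THRESHOLD, PHENOTYPES, SyntheticScene, rasterize_scene

__all__ = [
    "SceneAnalysis",
    "analyze_scene",
    "classification_accuracy",
    "ground_truth_volume_fractions",
    "recovered_volume_fractions",
]


@dataclass
class SceneAnalysis:
    """Everything the analysis chain produced for one scene."""

    spacing_um: tuple
    labels: dict                       # full-res LabelVolume per channel
    split: dict                        # down-sampled, split LabelVolume per channel
    segments: list                     # classified VesselSegment list
    gt_ds: LabelVolume                 # ground-truth labels on the analysis grid
    full_masks: dict = field(default_factory=dict)   # full-res mask per phenotype
    records: list = field(default_factory=list)      # DistanceRecord per scene cell


def analyze_scene(
    scene: SyntheticScene,
    spacing_um=(1.3, 1.3, 2.5),
    config: PipelineConfig | None = None,
    channel_threshold: float = GLOBAL_THRESHOLD,
    noise=None,
    compute_distances: bool = True,
) -> SceneAnalysis:
    """Render a scene and run segment → down-sample → split → classify →
    (optionally) per-cell distances, against the scene's planted cells.

    ``channel_threshold`` defaults to the generator's global intensity
    threshold (renders place "hi" tubes at 5x it and "lo" tubes at 0.5x).
    Distances are measured to per-phenotype masks projected back to full
    resolution, the same convention the file pipeline uses.
    """
    cfg = config or PipelineConfig()
    channels, gt = rasterize_scene(scene, spacing_um=spacing_um, noise=noise)

    labels = {}
    for name in ("CD31", "Emcn"):
        bgsub = subtract_background(channels[name], cfg.bg_radius_um)
        labels[name] = segment_vessels(bgsub, channel_threshold, cfg.min_vessel_volume_um3)

    factor = cfg.downsample_factor
    split = {
        name: split_objects(downsample(lv, factor), cfg.split_seed_diameter_um)
        for name, lv in labels.items()
    }
    segments = classify_vessel_phenotypes(split["CD31"], split["Emcn"], cfg.colocalization_fraction)
    gt_ds = downsample(gt, factor)

    analysis = SceneAnalysis(
        spacing_um=tuple(spacing_um), labels=labels, split=split, segments=segments, gt_ds=gt_ds
    )
    if compute_distances and scene.cells:
        analysis.full_masks = fullres_phenotype_masks(labels, split, segments)
        analysis.records = nearest_distances(scene.cells, analysis.full_masks, spacing_um)
    return analysis


def classification_accuracy(
    segments: list[VesselSegment], gt_ds: LabelVolume, scene: SyntheticScene
) -> float:
    """Object-level phenotype accuracy against the planted tube phenotypes.

    Each classified object is matched to the ground-truth vessel covering
    the majority of its voxels; the object is correct when its phenotype
    equals that vessel's planted phenotype.  Emcn-side objects dropped as
    the face of a dual-positive vessel are correct exactly when their
    ground-truth vessel is dual-positive (the counting rule counts that
    vessel from the CD31 side).  Objects matching no ground-truth vessel
    count as wrong.
    """
    phenotype_of = {v.id: v.phenotype for v in scene.vessels}
    gt_labels = gt_ds.labels
    n_correct = 0
    n_total = 0
    for seg in segments:
        n_total += 1
        ids = gt_labels[seg.voxels_zyx]
        ids = ids[ids > 0]
        if ids.size == 0:
            continue
        gt_phe = phenotype_of.get(int(np.bincount(ids).argmax()))
        if seg.phenotype == "dropped":
            ok = gt_phe == PHENOTYPES[1]  # CD31hi_EmcnHi counted from the CD31 side
        else:
            ok = seg.phenotype == gt_phe
        n_correct += int(ok)
    if n_total == 0:
        raise ValueError("no segments to score")
    return n_correct / n_total


def ground_truth_volume_fractions(scene: SyntheticScene) -> dict:
    """Analytic per-phenotype volume fractions of the planted tubes."""
    vols = {p: 0.0 for p in PHENOTYPES}
    for v in scene.vessels:
        vols[v.phenotype] += v.analytic_volume_um3
    total = sum(vols.values())
    return {p: (v / total if total else float("nan")) for p, v in vols.items()}


def recovered_volume_fractions(segments: list[VesselSegment]) -> dict:
    summary = summarize_phenotype_volumes(segments)
    return summary.fractional_volume
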