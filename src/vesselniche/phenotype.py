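"""Vessel phenotype classification by mask co-localization.

The three phenotypes are assigned by the published two-pass rule:

* CD31-sourced objects are split on the presence of masked Emcn signal:
  absent => CD31hi/Emcn-negative (arteries/arterioles), present =>
  CD31hi/Emcnhi (dual-positive capillaries).
* Emcn-sourced objects co-localized with masked CD31 signal are dropped
  (they are the Emcn face of a dual-positive vessel already counted from the
  CD31 side); the remainder are CD31lo/Emcnhi capillaries and sinusoids.

"Presence" is a voxel-overlap fraction threshold (default 0.05): an object
is co-localized when the fraction of its voxels inside the other channel's
mask is at least ``colocalization_fraction`` *and* strictly positive, so a
fraction of 0 reproduces strict any-voxel overlap.  Dim CD31lo/Emcnlo
sinusoids are excluded implicitly: objects only exist where a channel
segments at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import LabelVolume
from .synthetic import CD31HI_EMCN_HI, CD31HI_EMCN_NEG, CD31LO_EMCN_HI, PHENOTYPES

__all__ = ["VesselSegment", "PhenotypeSummary", "classify_vessel_phenotypes", "summarize_phenotype_volumes", "phenotype_masks"]


@dataclass
class VesselSegment:
    """One classified vessel object with its voxel set."""

    id: int
    source_channel: str  # "CD31" or "Emcn"
    phenotype: str       # one of PHENOTYPES or "dropped"
    volume_um3: float
    voxel_count: int
    overlap_fraction_other_channel: float
    voxels_zyx: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.source_channel == "CD31" and self.phenotype == CD31LO_EMCN_HI:
            raise ValueError("a CD31-sourced object cannot be CD31lo_EmcnHi")
        if self.source_channel == "Emcn" and self.phenotype in (CD31HI_EMCN_NEG, CD31HI_EMCN_HI):
            raise ValueError("an Emcn-sourced object cannot be CD31hi")

    def to_row(self) -> dict:
        return {
            "id": self.id,
            "source_channel": self.source_channel,
            "phenotype": self.phenotype,
            "volume_um3": self.volume_um3,
            "voxel_count": self.voxel_count,
            "overlap_fraction_other_channel": self.overlap_fraction_other_channel,
        }


@dataclass
class PhenotypeSummary:
    """Per-phenotype absolute and fractional vessel volumes inside a VOI."""

    volume_um3: dict
    total_vessel_volume_um3: float
    fractional_volume: dict  # NaN fractions when the total is zero

    def to_row(self) -> dict:
        row = {"total_vessel_volume_um3": self.total_vessel_volume_um3}
        for p in PHENOTYPES:
            row[f"volume_um3_{p}"] = self.volume_um3.get(p, 0.0)
            row[f"fraction_{p}"] = self.fractional_volume.get(p, float("nan"))
        return row


def _overlap_fractions(labels: np.ndarray, other_mask: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """fraction of each object's voxels lying inside ``other_mask``."""
    total = np.bincount(labels.ravel(), minlength=int(ids.max(initial=0)) + 1)
    inside = np.bincount(labels[other_mask].ravel(), minlength=int(ids.max(initial=0)) + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = inside / total
    return frac[ids]


def _colocalized(frac: np.ndarray, colocalization_fraction: float) -> np.ndarray:
    # fraction 0 degenerates to strict any-voxel overlap
    return (frac >= colocalization_fraction) & (frac > 0)


def classify_vessel_phenotypes(
    cd31_labels: LabelVolume,
    emcn_labels: LabelVolume,
    colocalization_fraction: float = 0.05,
) -> list[VesselSegment]:
    """Classify CD31- and Emcn-sourced objects into the three phenotypes.

    Both label volumes must share shape and spacing (i.e. be from the same
    down-sampled grid).  Dual-positive vessels are counted once, from the
    CD31 side; the co-localized Emcn objects are returned with phenotype
    ``"dropped"`` so totals remain auditable.
    """
    if cd31_labels.labels.shape != emcn_labels.labels.shape:
        raise ValueError("label volumes must share shape")
    if tuple(cd31_labels.spacing_um) != tuple(emcn_labels.spacing_um):
        raise ValueError("label volumes must share spacing")
    if not 0.0 <= colocalization_fraction < 1.0:
        raise ValueError("colocalization_fraction must lie in [0, 1)")

    voxvol = cd31_labels.voxel_volume_um3
    segments: list[VesselSegment] = []
    emcn_mask = emcn_labels.mask()
    cd31_mask = cd31_labels.mask()

    cd31_ids = cd31_labels.ids
    if len(cd31_ids):
        fracs = _overlap_fractions(cd31_labels.labels, emcn_mask, cd31_ids)
        coloc = _colocalized(fracs, colocalization_fraction)
        for oid, f, c in zip(cd31_ids, fracs, coloc):
            vox = np.nonzero(cd31_labels.labels == oid)
            segments.append(
                VesselSegment(
                    id=int(oid),
                    source_channel="CD31",
                    phenotype=CD31HI_EMCN_HI if c else CD31HI_EMCN_NEG,
                    volume_um3=float(len(vox[0]) * voxvol),
                    voxel_count=int(len(vox[0])),
                    overlap_fraction_other_channel=float(f),
                    voxels_zyx=vox,
                    spacing_um=cd31_labels.spacing_um,
                )
            )
    emcn_ids = emcn_labels.ids
    if len(emcn_ids):
        fracs = _overlap_fractions(emcn_labels.labels, cd31_mask, emcn_ids)
        coloc = _colocalized(fracs, colocalization_fraction)
        for oid, f, c in zip(emcn_ids, fracs, coloc):
            vox = np.nonzero(emcn_labels.labels == oid)
            segments.append(
                VesselSegment(
                    id=int(oid),
                    source_channel="Emcn",
                    phenotype="dropped" if c else CD31LO_EMCN_HI,
                    volume_um3=float(len(vox[0]) * voxvol),
                    voxel_count=int(len(vox[0])),
                    overlap_fraction_other_channel=float(f),
                    voxels_zyx=vox,
                    spacing_um=emcn_labels.spacing_um,
                )
            )
    return segments


def phenotype_masks(segments: list[VesselSegment], shape_zyx) -> dict[str, np.ndarray]:
    """Binary mask per phenotype from the classified objects' voxel sets."""
    masks = {p: np.zeros(shape_zyx, dtype=bool) for p in PHENOTYPES}
    for seg in segments:
        if seg.phenotype in masks and seg.voxels_zyx is not None:
            masks[seg.phenotype][seg.voxels_zyx] = True
    return masks


def fullres_phenotype_masks(
    full_labels: dict[str, LabelVolume],
    split_labels: dict[str, LabelVolume],
    segments: list[VesselSegment],
) -> dict[str, np.ndarray]:
    """Project object phenotypes back onto the full-resolution channel masks.

    Classification runs on the down-sampled, split masks, but nearest-vessel
    distances are sub-voxel quantities, so the distance maps are built at
    acquisition resolution: each full-resolution object (ids survive the
    block-mode down-sampling) receives the volume-weighted majority phenotype
    of its split pieces, and each phenotype mask is the union of the
    full-resolution objects so labelled.  Emcn-side pieces dropped as the
    face of a dual-positive vessel cast no vote — that vessel is carried by
    the CD31 mask.
    """
    votes: dict[tuple[str, int], dict[str, float]] = {}
    for ch in ("CD31", "Emcn"):
        parent = dict(zip(split_labels[ch].table["id"], split_labels[ch].table["parent_id"]))
        for seg in segments:
            if seg.source_channel != ch or seg.phenotype not in PHENOTYPES:
                continue
            key = (ch, int(parent[seg.id]))
            votes.setdefault(key, {}).setdefault(seg.phenotype, 0.0)
            votes[key][seg.phenotype] += seg.volume_um3
    masks = {p: np.zeros(full_labels["CD31"].labels.shape, dtype=bool) for p in PHENOTYPES}
    for ch in ("CD31", "Emcn"):
        by_phe: dict[str, list[int]] = {}
        for (vch, oid), v in votes.items():
            if vch == ch:
                winner = max(sorted(v), key=v.get)
                by_phe.setdefault(winner, []).append(oid)
        for p, ids in by_phe.items():
            masks[p] |= np.isin(full_labels[ch].labels, ids)
    return masks


def summarize_phenotype_volumes(segments: list[VesselSegment], voi=None) -> PhenotypeSummary:
    """Per-phenotype volumes (optionally VOI-restricted) and fractions.

    Dropped Emcn-face objects are excluded (their volume is carried by the
    CD31-side object).  An empty VOI intersection yields a zero-volume
    summary with NaN fractions.
    """
    volumes = {p: 0.0 for p in PHENOTYPES}
    for seg in segments:
        if seg.phenotype not in volumes:
            continue
        if voi is None or seg.voxels_zyx is None:
            volumes[seg.phenotype] += seg.volume_um3
            continue
        zz, yy, xx = seg.voxels_zyx
        s = np.asarray(seg.spacing_um)
        centers = np.stack([(xx + 0.5) * s[0], (yy + 0.5) * s[1], (zz + 0.5) * s[2]], axis=1)
        n_in = int(voi.contains(centers).sum())
        volumes[seg.phenotype] += n_in * float(np.prod(s))
    total = float(sum(volumes.values()))
    if total > 0:
        fractions = {p: v / total for p, v in volumes.items()}
    else:
        fractions = {p: float("nan") for p in PHENOTYPES}
    return PhenotypeSummary(volume_um3=volumes, total_vessel_volume_um3=total, fractional_volume=fractions)
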