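"""Volume and table I/O plus tile fusion.

Images travel as OME-TIFF with the voxel spacing recorded in metadata
(``PhysicalSizeX/Y/Z``); plain TIFF stacks without metadata are accepted when
a fallback spacing is supplied.  Tables are plain CSV.

Tile fusion replaces the original manual x–y alignment with automatic,
translation-only refinement: each tile's nominal stage offset is corrected by
phase correlation against the already-fused neighbours, bounded to ±10 % of
the tile size, and overlapping voxels are linearly feathered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.registration import phase_cross_correlation

from .image import ImageVolume

__all__ = ["read_volume", "write_volume", "TileLayout", "fuse_tiles", "export_stats_table", "save_mip"]

logger = logging.getLogger(__name__)


def write_volume(vol: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as OME-TIFF with spacing metadata.

    Integer data round-trips bit-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sx, sy, sz = vol.spacing_um
    tifffile.imwrite(
        path,
        vol.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": sx,
            "PhysicalSizeY": sy,
            "PhysicalSizeZ": sz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": [vol.channel or "unnamed"]},
        },
    )


def read_volume(path, spacing_um=None, channel: str | None = None) -> ImageVolume:
    """Read a TIFF / OME-TIFF stack into an :class:`ImageVolume`.

    Spacing is taken from OME metadata when present, else from ``spacing_um``
    (the config fallback).  A file that is neither 3D nor carries spacing
    from either source is an error; intensities are never rescaled.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_spacing = None
        meta_channel = None
        if tf.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                if px is not None and px.get("PhysicalSizeX"):
                    meta_spacing = (
                        float(px.get("PhysicalSizeX")),
                        float(px.get("PhysicalSizeY", px.get("PhysicalSizeX"))),
                        float(px.get("PhysicalSizeZ", px.get("PhysicalSizeX"))),
                    )
                ch = root.find(".//ome:Channel", ns)
                if ch is not None:
                    meta_channel = ch.get("Name")
            except Exception:  # pragma: no cover - malformed metadata
                logger.warning("could not parse OME metadata in %s", path)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    spacing = meta_spacing or spacing_um
    if spacing is None:
        raise ValueError(f"{path}: no spacing metadata and no fallback spacing_um given")
    return ImageVolume(
        data=data,
        spacing_um=tuple(spacing),
        channel=channel or meta_channel or path.stem,
    )


# ---------------------------------------------------------------------------
# tile fusion
# ---------------------------------------------------------------------------

@dataclass
class TileLayout:
    """Tiles with nominal stage offsets (physical μm, (x, y, z)).

    ``overlap_fraction`` is the declared overlap between adjacent tiles
    (acquisitions here used 15 %).
    """

    tiles: list[tuple[ImageVolume, tuple[float, float, float]]]
    overlap_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ValueError("TileLayout needs at least one tile")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1)")


def _feather_weight(shape_zyx) -> np.ndarray:
    """Separable linear ramp from each face; positive everywhere."""
    w = np.ones(shape_zyx, dtype=np.float64)
    for ax, n in enumerate(shape_zyx):
        ramp = np.minimum(np.arange(n) + 1, n - np.arange(n)).astype(np.float64)
        shape = [1, 1, 1]
        shape[ax] = n
        w = w * ramp.reshape(shape)
    return w


def _refine_offset(
    canvas: np.ndarray,
    canvas_w: np.ndarray,
    tile: np.ndarray,
    nominal_vox: np.ndarray,
    max_shift_vox: np.ndarray,
) -> np.ndarray:
    """Phase-correlate the tile against the current canvas near its nominal slot."""
    lo = np.maximum(nominal_vox, 0)
    hi = np.minimum(nominal_vox + tile.shape, canvas.shape)
    if (hi - lo <= 1).any():
        return nominal_vox
    ref = canvas[tuple(slice(a, b) for a, b in zip(lo, hi))]
    ref_w = canvas_w[tuple(slice(a, b) for a, b in zip(lo, hi))]
    # the canvas holds feather-weighted sums; normalize before correlating
    ref = np.divide(ref, ref_w, out=np.zeros_like(ref), where=ref_w > 0)
    mov = tile[tuple(slice(a - n, b - n) for a, b, n in zip(lo, hi, nominal_vox))]
    overlap = ref_w > 0
    if overlap.mean() < 0.01 or np.ptp(ref[overlap]) == 0 or np.ptp(mov) == 0:
        return nominal_vox
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = phase_cross_correlation(
                ref, mov, reference_mask=ref_w > 0, moving_mask=np.ones(mov.shape, dtype=bool)
            )
        shift = result[0] if isinstance(result, tuple) else result
    except Exception:
        logger.warning("phase correlation failed; keeping nominal offset")
        return nominal_vox
    shift = np.round(shift).astype(int)
    if (np.abs(shift) > max_shift_vox).any():
        logger.warning("refined shift %s exceeds bound %s; keeping nominal offset", shift, max_shift_vox)
        return nominal_vox
    return nominal_vox + shift


def fuse_tiles(layout: TileLayout, refine: bool = True) -> ImageVolume:
    """Fuse tiles into one volume with feathered blending.

    Offsets are refined tile-by-tile by translation-only phase correlation
    seeded at the nominal positions (search bounded to ±10 % of the tile
    size); failures fall back to the nominal offset with a logged warning.
    A single tile is returned unchanged (up to float cast).
    """
    first = layout.tiles[0][0]
    spacing = np.asarray(first.spacing_um)
    spacing_zyx = spacing[::-1]
    for vol, _ in layout.tiles:
        if tuple(vol.spacing_um) != tuple(first.spacing_um):
            raise ValueError("all tiles must share voxel spacing")

    offsets_vox = []
    for vol, off in layout.tiles:
        off_zyx = np.asarray(off, dtype=float)[::-1] / spacing_zyx
        offsets_vox.append(np.round(off_zyx).astype(int))
    offsets_vox = [o - np.min(offsets_vox, axis=0) for o in offsets_vox]

    shapes = np.array([t[0].data.shape for t in layout.tiles])
    canvas_shape = tuple((np.array(offsets_vox) + shapes).max(axis=0))
    pad = np.ceil(0.1 * shapes.max(axis=0)).astype(int)
    canvas_shape = tuple(np.array(canvas_shape) + pad)

    canvas = np.zeros(canvas_shape, dtype=np.float64)
    weight = np.zeros(canvas_shape, dtype=np.float64)
    final_offsets = []
    for i, ((vol, _), nominal) in enumerate(zip(layout.tiles, offsets_vox)):
        tile = vol.data.astype(np.float64)
        if refine and i > 0:
            max_shift = np.maximum(np.ceil(0.1 * np.array(tile.shape)).astype(int), 1)
            nominal = _refine_offset(canvas, weight, tile, nominal, max_shift)
        nominal = np.clip(nominal, 0, np.array(canvas_shape) - tile.shape)
        sl = tuple(slice(o, o + s) for o, s in zip(nominal, tile.shape))
        w = _feather_weight(tile.shape)
        canvas[sl] += tile * w
        weight[sl] += w
        final_offsets.append(nominal)

    covered = weight > 0
    fused = np.zeros_like(canvas)
    fused[covered] = canvas[covered] / weight[covered]
    # crop to the covered bounding box
    idx = np.nonzero(covered)
    bbox = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    fused = fused[bbox]
    origin_zyx = np.array([s.start for s in bbox]) * spacing_zyx
    return ImageVolume(
        data=fused,
        spacing_um=tuple(spacing),
        channel=first.channel,
        origin_um=tuple(origin_zyx[::-1]),
    )


# ---------------------------------------------------------------------------
# tables and QC
# ---------------------------------------------------------------------------

def export_stats_table(records, path, allow_empty: bool = False, columns=None) -> pd.DataFrame:
    """Write per-object records (dataclasses, dicts, or a DataFrame) to CSV."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "to_row"):
                rows.append(r.to_row())
            elif isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows, columns=columns)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def save_mip(vol: ImageVolume, path, axis: str = "z") -> None:
    """Maximum-intensity-projection PNG for quick QC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax_idx = {"z": 0, "y": 1, "x": 2}[axis]
    mip = vol.data.max(axis=ax_idx)
    plt.imsave(Path(path), mip, cmap="magma")
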