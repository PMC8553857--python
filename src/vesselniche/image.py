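"""Core volumetric containers.

Conventions used across the package:

* Arrays are stored in ``(z, y, x)`` axis order (the order TIFF stacks are
  read in), while every *public* physical coordinate, spacing or extent is an
  ``(x, y, z)`` triple in micrometres.
* Voxel ``(k, j, i)`` has its centre at ``origin + (i + 0.5) * sx`` (and
  likewise for y, z): the volume occupies the half-open physical box
  ``[origin, origin + shape * spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ImageVolume", "LabelVolume"]


def _as_xyz(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a 3-vector, got {v!r}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    spacing_um : (sx, sy, sz)
        Voxel spacing in micrometres, strictly positive.
    channel : str
        Channel label, e.g. ``"CD31"``, ``"Emcn"``, ``"Osterix"``.
    origin_um : (x, y, z)
        Physical position of the volume's lower corner.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel: str = ""
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing_um = _as_xyz(self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_um}")
        self.origin_um = _as_xyz(self.origin_um)

    # -- geometry ---------------------------------------------------------
    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return self.spacing_um[::-1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) of the voxel grid in micrometres."""
        nz, ny, nx = self.data.shape
        sx, sy, sz = self.spacing_um
        return (nx * sx, ny * sy, nz * sz)

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing_um
        return sx * sy * sz

    def phys_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) μm points to fractional (z, y, x) indices."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        s = np.asarray(self.spacing_um)
        o = np.asarray(self.origin_um)
        idx_xyz = (p - o) / s - 0.5
        return idx_xyz[:, ::-1]

    def index_to_phys(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map (z, y, x) voxel indices to physical voxel-centre (x, y, z) μm."""
        i = np.atleast_2d(np.asarray(idx_zyx, dtype=float))[:, ::-1]
        s = np.asarray(self.spacing_um)
        o = np.asarray(self.origin_um)
        return (i + 0.5) * s + o

    def copy(self, **changes) -> "ImageVolume":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


@dataclass
class LabelVolume:
    """Integer instance segmentation with a per-object table.

    ``0`` is background; object ids are dense positive integers.  ``table``
    has one row per object with at least ``id``, ``voxel_count`` and
    ``volume_um3`` columns.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["id", "voxel_count", "volume_um3"]))
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label data must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing_um = _as_xyz(self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_um}")
        self.origin_um = _as_xyz(self.origin_um)

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return self.spacing_um[::-1]

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing_um
        return sx * sy * sz

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy() if len(self.table) else np.array([], dtype=int)

    @property
    def n_objects(self) -> int:
        return len(self.table)

    def mask(self) -> np.ndarray:
        return self.labels > 0

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        spacing_um,
        origin_um=(0.0, 0.0, 0.0),
        extra_columns: dict | None = None,
    ) -> "LabelVolume":
        """Build the object table from a raw label array (ids need not be dense)."""
        labels = np.asarray(labels)
        counts = np.bincount(labels.ravel())
        ids = np.nonzero(counts)[0]
        ids = ids[ids > 0]
        sx, sy, sz = _as_xyz(spacing_um)
        voxvol = sx * sy * sz
        table = pd.DataFrame(
            {
                "id": ids.astype(int),
                "voxel_count": counts[ids].astype(int),
                "volume_um3": counts[ids] * voxvol,
            }
        )
        if extra_columns:
            for k, v in extra_columns.items():
                table[k] = [v[i] for i in ids]
        return cls(labels=labels, spacing_um=(sx, sy, sz), table=table, origin_um=origin_um)
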