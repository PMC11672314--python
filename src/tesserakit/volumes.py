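"""Voxel-grid containers shared across the pipeline.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]``;
* voxel indices are 0-based and the world coordinate of a voxel centre is
  ``(index + 0.5) * voxel_size`` in micrometres;
* label 0 is background (including the unmineralized intertesseral gap);
  tile ids start at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class GrayscaleVolume:
    """Reconstructed tomographic intensity volume.

    Parameters
    ----------
    data : ndarray, 3-D float or integer
        Intensity grid, indexed ``[x, y, z]``.
    voxel_size : float
        Isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


@dataclass
class BinaryVolume:
    """Boolean foreground mask (mineralized tissue vs. background)."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)


@dataclass
class DistanceVolume:
    """Euclidean distance field in micrometres.

    ``signed`` distinguishes the unsigned foreground-to-background transform
    (zero on background) from the signed map that is negative inside the
    mineralized tissue and positive outside.
    """

    data: np.ndarray
    voxel_size: float
    signed: bool = False


@dataclass
class LabelVolume:
    """Instance segmentation: one positive integer id per tessera.

    ``log`` records scriptable proofreading edits (merge/split/remove) so a
    segmentation's provenance is reconstructable.
    """

    data: np.ndarray
    voxel_size: float
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    def ids(self) -> np.ndarray:
        """Sorted array of positive label ids present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.voxel_size, list(self.log))


def voxel_centers_world(indices: np.ndarray, voxel_size: float) -> np.ndarray:
    """World coordinates (µm) of voxel centres for an (N, 3) index array."""
    return (np.asarray(indices, dtype=float) + 0.5) * voxel_size


def write_tiff(path, volume) -> None:
    """Write a volume as a multi-page TIFF stack (pages along the last axis)."""
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    # tifffile pages are the leading axis; store z-first for stack viewers
    tifffile.imwrite(str(path), np.ascontiguousarray(np.moveaxis(data, 2, 0)))


def read_tiff(path, voxel_size: float, kind: str = "gray"):
    """Read a multi-page TIFF stack written by :func:`write_tiff`.

    ``kind`` selects the container: ``"gray"``, ``"labels"`` or ``"binary"``.
    """
    data = np.moveaxis(tifffile.imread(str(path)), 0, 2)
    if kind == "labels":
        return LabelVolume(data.astype(np.int32), voxel_size)
    if kind == "binary":
        return BinaryVolume(data.astype(bool), voxel_size)
    return GrayscaleVolume(data.astype(np.float32), voxel_size)
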