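"""Channel binarisation and 3D ROI bookkeeping.

Each fluorescence channel is thresholded globally over the full 3D volume
(default: Otsu's method; fixed and quantile thresholds are available for
sensitivity analyses) and connected components are labelled on the
anisotropic voxel grid with 6- or 26-connectivity.  The threshold actually
applied is always recorded on the resulting mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imgio import VoxelSize

__all__ = ["BinaryMask3D", "ROI3D", "binarize", "label_components", "mask_volume_um3"]


@dataclass
class BinaryMask3D:
    """A boolean voxel grid with its physical voxel size and provenance."""

    grid: np.ndarray
    voxel: VoxelSize
    source_channel: str = ""
    threshold: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x); got ndim={self.grid.ndim}")
        if self.grid.dtype != bool:
            self.grid = self.grid.astype(bool)

    @property
    def volume_um3(self) -> float:
        return mask_volume_um3(self)


@dataclass(frozen=True)
class ROI3D:
    """One labelled connected component."""

    label: int
    voxel_count: int
    volume_um3: float
    bbox: tuple[tuple[int, int], ...]  # ((z0, z1), (y0, y1), (x0, x1)), half-open
    centroid: tuple[float, float, float]  # (z, y, x), voxel units


def binarize(
    image: np.ndarray,
    voxel: VoxelSize,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    quantile: float = 0.99,
    source_channel: str = "",
) -> BinaryMask3D:
    """Threshold a single-channel 3D image into a :class:`BinaryMask3D`.

    ``mask = image > threshold`` with the threshold computed globally over
    the volume (``otsu``/``quantile``) or supplied (``fixed``).  A constant
    image cannot be Otsu-thresholded: its histogram is degenerate and an
    error is raised rather than returning a silent all-true/all-false mask.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected single-channel 3D image, got ndim={image.ndim}")
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if image.max() == image.min():
            raise ValueError(
                "Otsu threshold undefined: constant image yields a degenerate "
                "single-bin histogram"
            )
        thr = float(threshold_otsu(image))
    elif method == "quantile":
        if not 0 < quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        thr = float(np.quantile(image, quantile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask3D(
        grid=image > thr,
        voxel=voxel,
        source_channel=source_channel,
        threshold=thr,
        method=method,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(
    mask: BinaryMask3D, connectivity: int = 26, min_voxels: int = 10
) -> list[ROI3D]:
    """Label connected components of a mask into ROI records.

    Components smaller than ``min_voxels`` are discarded.  ROIs are ordered
    by descending voxel count, ties broken by lexicographic centroid order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.grid, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(int)
    keep = counts >= min_voxels
    if not np.any(keep):
        return []
    centroids = ndimage.center_of_mass(mask.grid, labels, idx[keep])
    slices = ndimage.find_objects(labels)
    vvol = mask.voxel.volume_um3
    rois = []
    for lab, cnt, cen in zip(idx[keep], counts[keep], centroids):
        sl = slices[lab - 1]
        rois.append(
            ROI3D(
                label=int(lab),
                voxel_count=int(cnt),
                volume_um3=float(cnt) * vvol,
                bbox=tuple((s.start, s.stop) for s in sl),
                centroid=tuple(float(c) for c in cen),
            )
        )
    rois.sort(key=lambda r: (-r.voxel_count, r.centroid))
    return rois


def mask_volume_um3(mask: BinaryMask3D) -> float:
    """Physical volume of the true voxels: count x dx*dy*dz."""
    return float(np.count_nonzero(mask.grid)) * mask.voxel.volume_um3
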