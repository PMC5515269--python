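"""3-D segmentation of confocal z-stacks into biofilm clusters.

A cluster is a maximal connected component of voxels at or above an
absolute intensity threshold (default 10 on the 8-bit scale), under a
configurable 3-D neighbourhood (6/18/26), with components smaller than a
minimum voxel count (default 3) discarded.  Biovolume is voxel count times
the voxel volume (0.42 x 0.42 x 0.78 um = 0.137592 um^3 by default);
thresholding on fluorescence intensity alone is what excludes the
extracellular matrix from the biovolume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

DEFAULT_VOXEL_DIMS = (0.42, 0.42, 0.78)  # (x, y, z) um

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold, size filter and connectivity for cluster segmentation."""

    intensity_threshold: float = 10.0
    min_voxels: int = 3
    connectivity: int = 26
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS  # (x, y, z) um

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity threshold must be >= 0")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        vx, vy, vz = self.voxel_dims
        return vx * vy * vz


@dataclass(frozen=True)
class Cluster:
    """One segmented connected component."""

    id: int
    voxel_count: int
    biovolume: float  # um^3
    centroid: tuple[float, float, float]  # (x, y, z) um, window coordinates
    bbox: tuple[int, int, int, int, int, int]  # (z0, z1, y0, y1, x0, x1), voxel indices


def segment_stack(stack: np.ndarray, params: SegmentationParams | None = None) -> list[Cluster]:
    """Segment a 3-D stack (z, y, x) into clusters.

    Voxels with intensity >= threshold are foreground; connected components
    under ``params.connectivity`` smaller than ``min_voxels`` are dropped.
    Centroids are voxel-centre means converted to um.
    """
    if params is None:
        params = SegmentationParams()
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError(f"expected a non-empty 3-D stack, got shape {stack.shape}")

    fg = stack >= params.intensity_threshold
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labels, n_labels = ndimage.label(fg, structure=structure)
    if n_labels == 0:
        return []

    counts = np.bincount(labels.ravel())[1:]  # per-label voxel counts
    keep = np.nonzero(counts >= params.min_voxels)[0] + 1
    if keep.size == 0:
        return []

    vx, vy, vz = params.voxel_dims
    vol = params.voxel_volume
    centroids = ndimage.center_of_mass(fg, labels, keep)  # (z, y, x) voxel coords
    slices = ndimage.find_objects(labels)

    clusters: list[Cluster] = []
    for new_id, lab in enumerate(keep, start=1):
        cz, cy, cx = centroids[new_id - 1]
        sl = slices[lab - 1]
        clusters.append(
            Cluster(
                id=new_id,
                voxel_count=int(counts[lab - 1]),
                biovolume=float(counts[lab - 1] * vol),
                centroid=((cx + 0.5) * vx, (cy + 0.5) * vy, (cz + 0.5) * vz),
                bbox=(
                    sl[0].start, sl[0].stop,
                    sl[1].start, sl[1].stop,
                    sl[2].start, sl[2].stop,
                ),
            )
        )
    return clusters


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF z-stack as a (z, y, x) array plus metadata."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt / non-TIFF input
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    meta = {"shape": arr.shape, "dtype": str(arr.dtype), "path": str(path)}
    return arr, meta


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (z, y, x) array as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(stack))
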