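"""Cel-shading, greyscale bracketing and 3D blob isolation.

Segmentation proceeds in three steps.  *Cel-shading* quantises greyscale
values into bins of width ``C`` via ``X_new = X - (X mod C)``, collapsing
near-identical materials (air, mount plastic, bone) onto single histogram
levels so a bracket is easy to choose and scanner noise is suppressed.
*Bracket thresholding* keeps voxels with ``t_lower <= X <= t_upper`` as
foreground.  *Blobbing* splits the foreground into 3D connected components
and discards components smaller than a minimum voxel count, which removes
residual fragments of the mount that survive the bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "SegmentationParams",
    "Blob",
    "cel_shade",
    "grey_level_count",
    "bracket_threshold",
    "label_blobs",
    "connectivity_structure",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationParams:
    """User-facing segmentation settings.

    ``cel_base`` of 0 disables cel-shading (it must be >= 2 when enabled).
    ``min_blob_size`` is counted in working-resolution voxels — the same
    resolution at which per-slice pixel counts are compared during plate
    detection.
    """

    t_lower: int
    t_upper: int
    cel_base: int = 0
    min_blob_size: int = 1
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.t_lower > self.t_upper:
            raise ValueError(f"t_lower {self.t_lower} > t_upper {self.t_upper}")
        if self.cel_base and self.cel_base < 2:
            raise ValueError("cel_base must be >= 2 when enabled (0 disables)")
        if self.min_blob_size < 1:
            raise ValueError("min_blob_size must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")


@dataclass
class Blob:
    """One connected foreground component at working resolution.

    ``bbox`` is half-open per axis: ``((z0, z1), (y0, y1), (x0, x1))``.
    ``centroid`` is the arithmetic mean of member voxel coordinates,
    ``(z, y, x)`` in working-resolution voxel units.
    """

    id: int
    voxel_count: int
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    centroid: tuple[float, float, float]


def cel_shade(vol: Volume, base: int) -> Volume:
    """Quantise greyscale values: every voxel becomes ``X - (X mod base)``.

    Output values are multiples of ``base``, never exceed the input, and the
    operation is idempotent.  ``base`` must be >= 2.
    """
    if base < 2:
        raise ValueError(f"cel-shading base must be >= 2, got {base}")
    data = vol.data - (vol.data % base)
    return Volume(data=data, meta=vol.meta, source_path=vol.source_path,
                  source_kind=vol.source_kind)


def grey_level_count(base: int, levels: int = 255, convention: str = "floor") -> int:
    """Number of grey values after cel-shading an image of ``levels`` levels.

    Two conventions coexist: ``"floor"`` returns ``levels // base`` (the
    count conventionally quoted for 8-bit data, e.g. base 10 on 255 levels
    gives 25); ``"enumerate"`` counts the distinct outputs of the quantiser
    over ``0..levels`` inclusive (base 10 gives 26: {0, 10, ..., 250}).
    """
    if base < 2:
        raise ValueError("base must be >= 2")
    if convention == "floor":
        return levels // base
    if convention == "enumerate":
        return len({x - (x % base) for x in range(levels + 1)})
    raise ValueError(f"unknown convention {convention!r}")


def bracket_threshold(vol: Volume, t_lower: int, t_upper: int) -> np.ndarray:
    """Binary mask of voxels inside the greyscale bracket.

    A voxel is foreground iff ``t_lower <= X <= t_upper``; the lower and
    upper cuts are applied together so material both darker and brighter
    than the bracket (air below, dense inclusions above) is excluded.
    Returns a boolean array with the volume's shape.
    """
    if t_lower > t_upper:
        raise ValueError(f"t_lower {t_lower} > t_upper {t_upper}")
    return (vol.data >= t_lower) & (vol.data <= t_upper)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def label_blobs(mask: np.ndarray, connectivity: int = 26, min_blob_size: int = 1) -> list[Blob]:
    """Isolate connected components of a binary mask as :class:`Blob` objects.

    Components with fewer than ``min_blob_size`` voxels are discarded.  Ids
    are assigned 1..n in raster order of each component's first voxel, so
    repeated runs (and hence export filenames) are reproducible.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    structure = connectivity_structure(connectivity)
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []

    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    objects = ndimage.find_objects(labeled)
    centroids = ndimage.center_of_mass(mask, labeled, index=range(1, n + 1))
    # raster order of first voxel per label
    flat = labeled.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    lab_ids, first_occurrence = np.unique(flat, return_index=True)
    first_idx[lab_ids] = first_occurrence

    order = sorted(
        (lab for lab in range(1, n + 1) if counts[lab] >= min_blob_size),
        key=lambda lab: first_idx[lab],
    )
    blobs = []
    for new_id, lab in enumerate(order, start=1):
        sl = objects[lab - 1]
        bbox = tuple((s.start, s.stop) for s in sl)
        blobs.append(
            Blob(
                id=new_id,
                voxel_count=int(counts[lab]),
                bbox=bbox,
                centroid=tuple(float(c) for c in centroids[lab - 1]),
            )
        )
    return blobs
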