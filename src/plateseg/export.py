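"""Per-specimen full-resolution TIFF stack export.

Segmentation runs on a downsampled working template, but exports go back to
the original data: each blob's working-resolution bounding box is scaled up
by the downsample factor (plus a small margin so blurred halos survive the
crop) and the full-resolution volume is re-cropped there.  Three export
modes exist per specimen: ``raw`` (the cropped original, 8-bit), ``mask``
(the blob's binary mask as a {0, 255} stack) and ``processed`` (original
voxels inside the mask, zero outside).  Output folders and filenames are
rooted at the specimen's assigned label, so external IDs survive export.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .plate_layout import Assignment
from .segmentation import Blob
from .volume import Volume, to_8bit

__all__ = ["ExportJob", "MODES", "scale_bbox_to_full", "upscale_mask",
           "blob_mask", "export_specimen", "sanitise_label", "write_manifest"]

MODES = ("raw", "mask", "processed")

BBox = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class ExportJob:
    """One specimen's export request: its assignment, full-res bbox and modes.

    ``rethreshold`` optionally re-applies the greyscale bracket to the
    full-resolution crop within the blob's upscaled support, sharpening mask
    edges at the cost of re-reading intensities.
    """

    assignment: Assignment
    blob: Blob
    bbox_full: BBox
    modes: tuple[str, ...] = MODES
    out_dir: Path = Path(".")
    rethreshold: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown export modes: {sorted(bad)}")


def scale_bbox_to_full(blob: Blob, downsample_factor: int, margin: int,
                       full_dims: tuple[int, int, int]) -> BBox:
    """Scale a working-resolution blob bbox to full resolution.

    Each half-open bound is multiplied by the downsample factor; the lower
    bounds are then pushed out by ``margin`` full-resolution voxels and the
    upper by the same, and the result is clamped to the full volume.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    out = []
    for (lo, hi), dim in zip(blob.bbox, full_dims):
        lo_f = max(0, lo * downsample_factor - margin)
        hi_f = min(dim, hi * downsample_factor + margin)
        out.append((lo_f, hi_f))
    return tuple(out)


def upscale_mask(mask: np.ndarray, factor: int, full_dims: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour (block replication) upscale of a working mask.

    Each working voxel becomes a ``factor**3`` block; the result is padded
    with background (or cropped) to exactly ``full_dims``, since stride
    downsampling floors the working dims.
    """
    up = mask.astype(bool)
    for axis in range(3):
        up = np.repeat(up, factor, axis=axis)
    out = np.zeros(full_dims, dtype=bool)
    sz = tuple(min(a, b) for a, b in zip(up.shape, full_dims))
    out[: sz[0], : sz[1], : sz[2]] = up[: sz[0], : sz[1], : sz[2]]
    return out


def blob_mask(mask: np.ndarray, blob: Blob, connectivity: int = 26) -> np.ndarray:
    """Extract the single-blob mask (same dims as ``mask``, this blob only)."""
    from scipy import ndimage

    from .segmentation import connectivity_structure

    out = np.zeros(mask.shape, dtype=bool)
    sl = tuple(slice(lo, hi) for lo, hi in blob.bbox)
    sub = np.asarray(mask)[sl].astype(bool)
    labeled, _ = ndimage.label(sub, structure=connectivity_structure(connectivity))
    zc, yc, xc = (int(round(c - lo)) for c, (lo, _) in zip(blob.centroid, blob.bbox))
    zc = min(max(zc, 0), sub.shape[0] - 1)
    yc = min(max(yc, 0), sub.shape[1] - 1)
    xc = min(max(xc, 0), sub.shape[2] - 1)
    target = labeled[zc, yc, xc]
    if target == 0:
        # centroid off-body (e.g. a C-shaped blob): fall back to the
        # component nearest the centroid inside the bbox
        fg = np.argwhere(labeled > 0)
        d = ((fg - np.array([zc, yc, xc])) ** 2).sum(axis=1)
        target = labeled[tuple(fg[int(np.argmin(d))])]
    out[sl] = labeled == target
    return out


_SANITISE_RE = re.compile(r"[^A-Za-z0-9._-]")


def sanitise_label(label: str) -> str:
    """ASCII-sanitised filesystem name: anything outside [A-Za-z0-9._-] -> '_'."""
    return _SANITISE_RE.sub("_", label)


def export_specimen(original: Volume, mask_full: np.ndarray, job: ExportJob) -> dict[str, list[Path]]:
    """Write one specimen's TIFF stacks.

    ``original`` is the full-resolution volume; ``mask_full`` the blob's
    full-resolution binary mask (same dims).  Layout:
    ``out_dir/<label>/<mode>/<label>_<mode>_<slice####>.tif``.  The raw mode
    crops the original (converted to 8-bit), mask mode writes {0, 255}, and
    processed writes original voxels where the mask is set, zero elsewhere.
    """
    label = sanitise_label(job.assignment.label)
    spec_dir = Path(job.out_dir) / label
    if spec_dir.exists():
        raise FileExistsError(
            f"output directory {spec_dir} already exists — labels must be unique"
        )
    sl = tuple(slice(lo, hi) for lo, hi in job.bbox_full)
    raw_crop = to_8bit(original).data[sl]
    mask_crop = np.asarray(mask_full)[sl].astype(bool)
    if job.rethreshold is not None:
        lo, hi = job.rethreshold
        mask_crop = mask_crop & (raw_crop >= lo) & (raw_crop <= hi)

    written: dict[str, list[Path]] = {}
    n = raw_crop.shape[0]
    width = max(4, len(str(n - 1)))
    for mode in job.modes:
        if mode == "raw":
            stack = raw_crop
        elif mode == "mask":
            stack = np.where(mask_crop, 255, 0).astype(np.uint8)
        else:  # processed
            stack = np.where(mask_crop, raw_crop, 0).astype(np.uint8)
        mode_dir = spec_dir / mode
        mode_dir.mkdir(parents=True)
        paths = []
        for z in range(n):
            p = mode_dir / f"{label}_{mode}_{z:0{width}d}.tif"
            tifffile.imwrite(p, stack[z])
            paths.append(p)
        written[mode] = paths
    return written


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write the per-specimen traceability manifest CSV."""
    path = Path(path)
    fields = ["label", "plate_index", "cell_row", "cell_col", "blob_id",
              "voxel_count", "distance", "bbox_full", "voxel_size_um", "modes",
              "status"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in fields})
    return path
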