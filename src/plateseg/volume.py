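"""Volume input/output for stacked-plate microCT data.

A scan arrives either as a single headerless ``.raw`` file or as a folder of
single-slice grayscale TIFFs, together with a plain-text ``.info`` sidecar
carrying the physical voxel size (microns) and, optionally, the volume
dimensions, bit depth and explicit slice ordering.  Volumes are indexed
``(z, y, x)`` with ``z`` the stacking (plate) axis, 0-based throughout.

Scans are typically far too large to process at full resolution, so a volume
is downsampled on import by an integer stride factor and used as a working
template; the original path is retained on the volume so specimens can later
be re-cropped from the full-resolution data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "MetadataAbsentError",
    "VolumeMeta",
    "Volume",
    "parse_info_file",
    "write_info_file",
    "read_volume",
    "write_tiff_stack",
    "write_raw",
    "downsample",
    "to_8bit",
    "natural_sort_key",
]

_BIT_DEPTH_DTYPES = {8: np.uint8, 16: np.uint16, 32: np.uint32}


class MetadataAbsentError(Exception):
    """Raised when the mandatory voxel size is missing from a ``.info`` file.

    Recoverable: the caller may prompt for / supply a voxel size and call
    :func:`write_info_file` to regenerate the sidecar.
    """


@dataclass
class VolumeMeta:
    """Scan metadata held in (or destined for) a ``.info`` sidecar file.

    Parameters
    ----------
    voxel_size_um : float
        Physical edge length of one full-resolution voxel, in microns.
    dims : tuple of int, optional
        ``(n_slices, n_rows, n_cols)``.  Mandatory for headerless raw input;
        may be absent until a volume is actually read.
    bit_depth : int
        One of 8, 16, 32.
    slice_order : list of str or "raw"
        Source slice filenames in stacking order, or ``"raw"`` for raw input.
    downsample_factor : int
        Stride applied on import; 1 means full resolution.
    """

    voxel_size_um: float
    dims: tuple[int, int, int] | None = None
    bit_depth: int = 8
    slice_order: list[str] | str = "raw"
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.dims is not None:
            self.dims = tuple(int(d) for d in self.dims)
            if len(self.dims) != 3 or any(d < 1 for d in self.dims):
                raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.bit_depth not in _BIT_DEPTH_DTYPES:
            raise ValueError(f"bit_depth must be one of {sorted(_BIT_DEPTH_DTYPES)}, got {self.bit_depth}")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(_BIT_DEPTH_DTYPES[self.bit_depth])


@dataclass
class Volume:
    """A 3D grid of non-negative integer intensities plus its metadata.

    ``data`` is indexed ``(z, y, x)``.  ``source_path`` points back at the
    original (full-resolution) input so exports can re-crop it.
    """

    data: np.ndarray
    meta: VolumeMeta
    source_path: Path | None = None
    source_kind: str | None = None  # "raw" | "tiff_folder"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if self.meta.dims is None:
            self.meta = replace(self.meta, dims=self.data.shape)
        elif tuple(self.meta.dims) != self.data.shape:
            raise ValueError(f"meta.dims {self.meta.dims} != data shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def natural_sort_key(name: str) -> tuple:
    """Numeric-aware sort key: ``slice2.tif`` sorts before ``slice10.tif``."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


# --------------------------------------------------------------------------
# .info sidecar
# --------------------------------------------------------------------------

def parse_info_file(text: str) -> VolumeMeta:
    """Parse a ``.info`` sidecar (UTF-8 ``key=value`` lines) into metadata.

    Mandatory key: ``voxel_size_um``.  Optional: ``dims`` (``z,y,x``),
    ``bit_depth`` (default 8), ``slice_order`` (comma-separated filenames or
    ``raw``; default ``raw``), ``downsample_factor`` (default 1).  Unknown
    keys are tolerated so vendor-generated files can be pointed at directly.

    Raises
    ------
    MetadataAbsentError
        If ``voxel_size_um`` is missing — the caller can supply it and
        regenerate the file with :func:`write_info_file`.
    """
    kv: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f".info line {lineno} is not key=value: {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    if "voxel_size_um" not in kv:
        raise MetadataAbsentError(
            "mandatory key 'voxel_size_um' missing from .info text; "
            "supply a voxel size and regenerate with write_info_file()"
        )

    dims = None
    if "dims" in kv and kv["dims"]:
        dims = tuple(int(v) for v in kv["dims"].split(","))
    slice_order: list[str] | str = "raw"
    if "slice_order" in kv and kv["slice_order"] and kv["slice_order"] != "raw":
        slice_order = [s.strip() for s in kv["slice_order"].split(",")]
    return VolumeMeta(
        voxel_size_um=float(kv["voxel_size_um"]),
        dims=dims,
        bit_depth=int(kv.get("bit_depth", 8)),
        slice_order=slice_order,
        downsample_factor=int(kv.get("downsample_factor", 1)),
    )


def write_info_file(meta: VolumeMeta) -> str:
    """Serialise metadata to ``.info`` text; inverse of :func:`parse_info_file`."""
    lines = [f"voxel_size_um={meta.voxel_size_um:g}"]
    if meta.dims is not None:
        lines.append("dims=" + ",".join(str(d) for d in meta.dims))
    lines.append(f"bit_depth={meta.bit_depth}")
    if meta.slice_order == "raw":
        lines.append("slice_order=raw")
    else:
        lines.append("slice_order=" + ",".join(meta.slice_order))
    lines.append(f"downsample_factor={meta.downsample_factor}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# volume readers / writers
# --------------------------------------------------------------------------

def _read_raw(path: Path, meta: VolumeMeta) -> np.ndarray:
    if meta.dims is None:
        raise ValueError("raw input is headerless: meta.dims must be supplied")
    dtype = meta.dtype
    expected = int(np.prod(meta.dims)) * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"raw file {path} is {actual} bytes but dims {meta.dims} at "
            f"{meta.bit_depth}-bit require {expected} bytes"
        )
    data = np.fromfile(path, dtype=dtype)
    return data.reshape(meta.dims)


def _read_tiff_folder(path: Path, meta: VolumeMeta) -> tuple[np.ndarray, list[str]]:
    if isinstance(meta.slice_order, list):
        names = list(meta.slice_order)
    else:
        names = sorted(
            (p.name for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=natural_sort_key,
        )
    if not names:
        raise ValueError(f"no TIFF slices found in {path}")
    slices = []
    shape = None
    for name in names:
        img = tifffile.imread(path / name)
        if img.ndim != 2:
            raise ValueError(f"slice {name} is not a single-page 2D image (shape {img.shape})")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"slice dimension mismatch: {name} is {img.shape}, expected {shape}"
            )
        slices.append(img)
    return np.stack(slices, axis=0), names


def read_volume(
    path: str | Path,
    kind: str,
    meta: VolumeMeta,
    downsample_factor: int = 1,
) -> Volume:
    """Read a volume from disk, downsampling by an integer stride on import.

    Parameters
    ----------
    path : path
        The ``.raw`` file or the TIFF folder.
    kind : {"raw", "tiff_folder"}
    meta : VolumeMeta
        For raw input, ``dims`` and ``bit_depth`` are mandatory (the file is
        headerless).  For TIFF folders, slices are read in numeric-aware
        filename order unless ``meta.slice_order`` lists them explicitly.
    downsample_factor : int
        Stride; the returned volume has ``floor(dim / factor)`` voxels per
        axis.  The original path is retained for full-resolution re-cropping.
    """
    path = Path(path)
    if kind == "raw":
        data = _read_raw(path, meta)
        order: list[str] | str = "raw"
    elif kind == "tiff_folder":
        data, order = _read_tiff_folder(path, meta)
    else:
        raise ValueError(f"kind must be 'raw' or 'tiff_folder', got {kind!r}")

    full_meta = VolumeMeta(
        voxel_size_um=meta.voxel_size_um,
        dims=data.shape,
        bit_depth=meta.bit_depth,
        slice_order=order,
        downsample_factor=1,
    )
    vol = Volume(data=data, meta=full_meta, source_path=path, source_kind=kind)
    if downsample_factor > 1:
        vol = downsample(vol, downsample_factor)
    return vol


def write_tiff_stack(vol: Volume, out_dir: str | Path, prefix: str = "slice") -> list[Path]:
    """Write a volume as one 8-bit grayscale TIFF per slice.

    Filenames are ``<prefix>_<zero-padded index>.tif``; returns the paths in
    stacking order.  Non-8-bit volumes must be converted with
    :func:`to_8bit` first.
    """
    if vol.data.dtype != np.uint8:
        raise ValueError("write_tiff_stack expects an 8-bit volume; use to_8bit() first")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(vol.data.shape[0] - 1)))
    paths = []
    for z in range(vol.data.shape[0]):
        p = out_dir / f"{prefix}_{z:0{width}d}.tif"
        tifffile.imwrite(p, vol.data[z])
        paths.append(p)
    return paths


def write_raw(vol: Volume, path: str | Path) -> Path:
    """Write a volume as a headerless raw file (voxel-major, x fastest)."""
    path = Path(path)
    vol.data.astype(vol.meta.dtype).tofile(path)
    return path


# --------------------------------------------------------------------------
# resampling / bit depth
# --------------------------------------------------------------------------

def downsample(vol: Volume, factor: int, method: str = "stride") -> Volume:
    """Downsample by an integer factor.

    ``method="stride"`` (default) picks every ``factor``-th voxel, so output
    voxel ``(i, j, k)`` equals input voxel ``(i*f, j*f, k*f)`` and each axis
    shrinks to ``floor(dim / f)``.  ``method="mean"`` block-averages instead
    (same output dims); the template is only a guide, so stride is the
    default for speed.
    """
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return vol
    if any(factor > d for d in vol.data.shape):
        raise ValueError(f"factor {factor} exceeds volume dims {vol.data.shape}")
    nz, ny, nx = (d // factor for d in vol.data.shape)
    if method == "stride":
        data = vol.data[: nz * factor : factor, : ny * factor : factor, : nx * factor : factor]
        data = np.ascontiguousarray(data)
    elif method == "mean":
        trimmed = vol.data[: nz * factor, : ny * factor, : nx * factor]
        blocks = trimmed.reshape(nz, factor, ny, factor, nx, factor)
        data = blocks.mean(axis=(1, 3, 5)).round().astype(vol.data.dtype)
    else:
        raise ValueError(f"unknown downsample method {method!r}")
    meta = replace(
        vol.meta,
        dims=data.shape,
        downsample_factor=vol.meta.downsample_factor * factor,
    )
    return Volume(data=data, meta=meta, source_path=vol.source_path, source_kind=vol.source_kind)


def to_8bit(vol: Volume) -> Volume:
    """Linearly rescale intensities to the 8-bit range [0, 255].

    8-bit input passes through unchanged; constant input maps to 0; otherwise
    each voxel maps to ``round(255 * (x - min) / (max - min))``.  Monotone.
    """
    if vol.data.dtype == np.uint8:
        return vol
    x = vol.data.astype(np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        data = np.zeros(vol.data.shape, dtype=np.uint8)
    else:
        data = np.round(255.0 * (x - lo) / (hi - lo)).astype(np.uint8)
    meta = replace(vol.meta, bit_depth=8)
    return Volume(data=data, meta=meta, source_path=vol.source_path, source_kind=vol.source_kind)
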