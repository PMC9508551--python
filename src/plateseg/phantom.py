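"""Synthetic stacked-plate microCT phantoms with ground truth.

The phantom emulates the structure of a bulk scan of microtiter plates:
plates are slabs of mounting material at an intermediate grey level, stacked
along z and separated by empty air gaps; each plate carries a regular grid
of cylindrical wells, and occupied wells hold an ellipsoidal "specimen" at a
higher grey level.  Air sits near 0.  A Gaussian blur reproduces the
partial-volume halo at object margins and additive clipped Gaussian noise
emulates scanner noise, so the grey-level histogram shows the characteristic
three peaks (air, mount, specimen — by default 0, 31 and 114).

Every placement is recorded in a :class:`PhantomTruth`, together with the
per-plate CSV label grids and the true plate z-spans, so each downstream
stage (segmentation, plate detection, label assignment, export, meshing) can
be tested against known answers without any real scan.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .plate_layout import PlateSpan
from .volume import Volume, VolumeMeta, write_info_file, write_tiff_stack

__all__ = ["PhantomConfig", "SpecimenTruth", "PhantomTruth", "generate_phantom", "write_phantom"]


@dataclass
class PhantomConfig:
    """Geometry, greyscale and noise settings of a synthetic scan.

    Defaults model two stacked 24-well plates (4 x 6 wells) with the
    air/mount/specimen grey levels at 0/31/114, a sub-voxel partial-volume
    blur and mild additive noise.  ``jitter`` displaces specimens off their
    well centres (in voxels); it is 0 by default, i.e. specimens centred in
    wells.  ``doubled_well`` places two specimens in the first occupied well
    and empties the last one, exercising the doubled/empty labelling paths.
    """

    n_plates: int = 2
    grid_rows: int = 4
    grid_cols: int = 6
    well_pitch: int = 16
    specimen_radius_range: tuple[float, float] = (3.0, 5.0)
    greyscale_air: int = 0
    greyscale_mount: int = 31
    greyscale_specimen: int = 114
    blur_sigma: float = 0.7
    noise_sigma: float = 2.0
    gap_slices: int = 8
    plate_slices: int = 14
    occupancy: float = 1.0
    jitter: float = 0.0
    doubled_well: bool = False
    voxel_size_um: float = 48.0
    border: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.greyscale_air < self.greyscale_mount < self.greyscale_specimen <= 255):
            raise ValueError("grey levels must satisfy 0 <= air < mount < specimen <= 255")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.specimen_radius_range[0] > self.specimen_radius_range[1]:
            raise ValueError("specimen_radius_range must be (min, max)")
        r_max = self.specimen_radius_range[1]
        if r_max > self.well_radius:
            raise ValueError(
                f"max specimen radius {r_max} does not fit the well radius "
                f"{self.well_radius:.1f} (pitch {self.well_pitch})"
            )
        if 2 * r_max + 4 > self.plate_slices:
            raise ValueError(
                f"max specimen diameter {2 * r_max} does not fit plate thickness "
                f"{self.plate_slices} (needs a 2-slice mount floor and headroom)"
            )

    @property
    def well_radius(self) -> float:
        return 0.35 * self.well_pitch

    @property
    def dims(self) -> tuple[int, int, int]:
        nz = self.gap_slices + self.n_plates * (self.plate_slices + self.gap_slices)
        ny = self.grid_rows * self.well_pitch + 2 * self.border
        nx = self.grid_cols * self.well_pitch + 2 * self.border
        return (nz, ny, nx)


@dataclass
class SpecimenTruth:
    """Ground truth for one placed specimen."""

    plate_index: int
    row: int
    col: int
    centroid: tuple[float, float, float]  # (z, y, x) voxels
    voxel_count: int
    label: str


@dataclass
class PhantomTruth:
    """Everything known about a generated phantom: placements, grids, spans."""

    specimens: list[SpecimenTruth]
    csv_texts: list[str]
    spans: list[PlateSpan]
    config: PhantomConfig

    def labels(self) -> list[str]:
        return [s.label for s in self.specimens]


def _well_label(plate: int, row: int, col: int) -> str:
    return f"P{plate + 1}-{chr(ord('A') + row)}{col + 1:02d}"


def _paint_ellipsoid(canvas: np.ndarray, centre: tuple[float, float, float],
                     radii: tuple[float, float, float], value: int) -> int:
    """Set voxels inside the ellipsoid; returns the voxel count painted."""
    cz, cy, cx = centre
    rz, ry, rx = radii
    z0, z1 = int(np.floor(cz - rz)), int(np.ceil(cz + rz)) + 1
    y0, y1 = int(np.floor(cy - ry)), int(np.ceil(cy + ry)) + 1
    x0, x1 = int(np.floor(cx - rx)), int(np.ceil(cx + rx)) + 1
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0
    region = canvas[z0:z1, y0:y1, x0:x1]
    region[inside] = value
    return int(inside.sum())


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, PhantomTruth]:
    """Render a stacked-plate phantom and its ground truth.

    Deterministic for a fixed ``cfg.seed``.  Plates are mount-grey slabs with
    air-filled cylindrical well cavities; each occupied well holds one
    ellipsoidal specimen (random axis ratios in [0.5, 1]) at the specimen
    grey level.  The volume is then Gaussian-blurred (the partial-volume
    halo) and additive Gaussian noise is applied, clipped to [0, 255].
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.dims
    canvas = np.full((nz, ny, nx), cfg.greyscale_air, dtype=np.float32)

    occupied = rng.random((cfg.n_plates, cfg.grid_rows, cfg.grid_cols)) < cfg.occupancy

    doubled_cell: tuple[int, int, int] | None = None
    emptied_cell: tuple[int, int, int] | None = None
    if cfg.doubled_well:
        occ_list = [tuple(idx) for idx in np.argwhere(occupied)]
        if len(occ_list) < 2:
            raise ValueError("doubled_well mode needs at least two occupied wells")
        doubled_cell = occ_list[0]
        emptied_cell = occ_list[-1]
        occupied[emptied_cell] = False

    specimens: list[SpecimenTruth] = []
    spans: list[PlateSpan] = []
    r_lo, r_hi = cfg.specimen_radius_range

    for p in range(cfg.n_plates):
        z0 = cfg.gap_slices + p * (cfg.plate_slices + cfg.gap_slices)
        z1 = z0 + cfg.plate_slices - 1  # inclusive
        spans.append(PlateSpan(p, z0, z1))
        canvas[z0 : z1 + 1, cfg.border : ny - cfg.border, cfg.border : nx - cfg.border] = cfg.greyscale_mount

        # drill well cavities (2-slice mount floor at the bottom of the slab)
        yy, xx = np.ogrid[0:ny, 0:nx]
        for r in range(cfg.grid_rows):
            for c in range(cfg.grid_cols):
                wy = cfg.border + (r + 0.5) * cfg.well_pitch
                wx = cfg.border + (c + 0.5) * cfg.well_pitch
                hole = (yy - wy) ** 2 + (xx - wx) ** 2 <= cfg.well_radius**2
                canvas[z0 + 2 : z1 + 1, hole] = cfg.greyscale_air

        # place specimens
        zc = z0 + 2 + (cfg.plate_slices - 2) / 2  # centre of the cavity depth
        for r in range(cfg.grid_rows):
            for c in range(cfg.grid_cols):
                if not occupied[p, r, c]:
                    continue
                wy = cfg.border + (r + 0.5) * cfg.well_pitch
                wx = cfg.border + (c + 0.5) * cfg.well_pitch
                is_doubled = doubled_cell == (p, r, c)
                if is_doubled:
                    # two small specimens, pushed apart so the partial-volume
                    # halo cannot bridge them at the working threshold
                    base = min(r_lo, 1.8)
                    off_x = cfg.well_radius - base - 0.2
                    offsets = [(-off_x, 0.0), (off_x, 0.0)]
                    placements = [(base, off) for off in offsets]
                else:
                    placements = [(rng.uniform(r_lo, r_hi), None)]
                for radius, off in placements:
                    if is_doubled:
                        # fixed spheres: large enough to survive the blur,
                        # small enough to stay clearly separated
                        radii = (radius, radius, radius)
                    else:
                        ratios = rng.uniform(0.5, 1.0, size=3)
                        radii = tuple(max(1.0, radius * q) for q in ratios)
                    if off is None:
                        jy = rng.uniform(-cfg.jitter, cfg.jitter) if cfg.jitter else 0.0
                        jx = rng.uniform(-cfg.jitter, cfg.jitter) if cfg.jitter else 0.0
                        centre = (zc, wy + jy, wx + jx)
                    else:
                        centre = (zc, wy + off[1], wx + off[0])
                    count = _paint_ellipsoid(canvas, centre, radii, cfg.greyscale_specimen)
                    specimens.append(
                        SpecimenTruth(p, r, c, centre, count, _well_label(p, r, c))
                    )

    if cfg.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma=cfg.blur_sigma)
    if cfg.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, cfg.noise_sigma, size=canvas.shape)
    data = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    csv_texts = []
    for p in range(cfg.n_plates):
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        for r in range(cfg.grid_rows):
            writer.writerow(
                [_well_label(p, r, c) if occupied[p, r, c] else ""
                 for c in range(cfg.grid_cols)]
            )
        csv_texts.append(buf.getvalue())

    meta = VolumeMeta(voxel_size_um=cfg.voxel_size_um, dims=data.shape, bit_depth=8,
                      slice_order="raw")
    vol = Volume(data=data, meta=meta)
    truth = PhantomTruth(specimens=specimens, csv_texts=csv_texts, spans=spans, config=cfg)
    return vol, truth


def write_phantom(cfg: PhantomConfig, out_dir: str | Path) -> Path:
    """Write a phantom as a TIFF folder + .info + per-plate CSVs + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol, truth = generate_phantom(cfg)
    slice_dir = out_dir / "slices"
    paths = write_tiff_stack(vol, slice_dir)
    meta = VolumeMeta(
        voxel_size_um=cfg.voxel_size_um,
        dims=vol.data.shape,
        bit_depth=8,
        slice_order=[p.name for p in paths],
    )
    (slice_dir / "volume.info").write_text(write_info_file(meta))
    for p, text in enumerate(truth.csv_texts):
        (out_dir / f"plate_{p + 1}.csv").write_text(text)
    truth_json = {
        "config": asdict(cfg),
        "spans": [[s.plate_index, s.start_slice, s.end_slice] for s in truth.spans],
        "specimens": [asdict(s) for s in truth.specimens],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    return out_dir
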