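"""End-to-end orchestration: import, segment, label, export, mesh.

A single :class:`RunConfig` (usually loaded from YAML) drives the whole
pipeline: the scan is read and downsampled into a working template,
segmented by (optional) cel-shading plus bracket thresholding, split into
blobs, plates are detected along z, labels are assigned from the per-plate
CSV grids, and every specimen is re-cropped from the full-resolution data
and written out as TIFF stacks and a PLY surface mesh.  A manifest CSV and a
run log record every parameter, plate span, corner label and assignment
distance so a run is fully reconstructible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import export as export_mod
from . import meshing
from .plate_layout import (Assignment, GridTransform, LabelGrid, assign_labels,
                           cell_centres, corner_labels, detect_plates, load_label_grid)
from .segmentation import SegmentationParams, bracket_threshold, cel_shade, label_blobs
from .volume import (MetadataAbsentError, Volume, VolumeMeta, parse_info_file,
                     read_volume, to_8bit, write_info_file, write_tiff_stack)

__all__ = ["PlateConfig", "RunConfig", "load_config", "run_pipeline", "split_plates"]

log = logging.getLogger("plateseg")


@dataclass
class PlateConfig:
    """One plate's label CSV path and grid placement transform."""

    csv: Path | None = None
    transform: GridTransform = field(default_factory=GridTransform)


@dataclass
class RunConfig:
    """All user choices for one pipeline run."""

    input: Path
    kind: str  # "raw" | "tiff_folder"
    out_dir: Path
    info: Path | None = None
    downsample_factor: int = 1
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(t_lower=52, t_upper=255)
    )
    plates: list[PlateConfig] | None = None
    export_modes: tuple[str, ...] = export_mod.MODES
    export_margin: int = 2
    mesh_enabled: bool = True
    mesh_ascii: bool = False
    pointcloud: str = "none"  # "none" | "filled" | "hollow"
    max_match_distance: float | None = None

    def validate(self) -> None:
        """Check referenced files exist before any I/O is performed."""
        if self.kind not in ("raw", "tiff_folder"):
            raise ValueError(f"kind must be 'raw' or 'tiff_folder', got {self.kind!r}")
        if not Path(self.input).exists():
            raise FileNotFoundError(f"input path does not exist: {self.input}")
        if self.info is not None and not Path(self.info).exists():
            raise FileNotFoundError(f".info file does not exist: {self.info}")
        if self.plates:
            for p in self.plates:
                if p.csv is not None and not Path(p.csv).exists():
                    raise FileNotFoundError(f"label CSV does not exist: {p.csv}")
        if self.pointcloud not in ("none", "filled", "hollow"):
            raise ValueError(f"pointcloud must be none/filled/hollow, got {self.pointcloud!r}")


def _transform_from_dict(d: dict) -> GridTransform:
    return GridTransform(
        translate=tuple(d.get("translate", (0.0, 0.0))),
        rotate_deg=float(d.get("rotate_deg", 0.0)),
        flip_h=bool(d.get("flip_h", False)),
        flip_v=bool(d.get("flip_v", False)),
        pitch=tuple(d.get("pitch", (1.0, 1.0))),
    )


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, applying flat key overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    seg = raw.get("segmentation", {})
    plates = None
    if raw.get("plates") is not None:
        plates = [
            PlateConfig(
                csv=Path(p["csv"]) if p.get("csv") else None,
                transform=_transform_from_dict(p.get("transform", {})),
            )
            for p in raw["plates"]
        ]
    exp = raw.get("export", {})
    mesh = raw.get("mesh", {})
    return RunConfig(
        input=Path(raw["input"]),
        kind=raw.get("kind", "tiff_folder"),
        out_dir=Path(raw["out_dir"]),
        info=Path(raw["info"]) if raw.get("info") else None,
        downsample_factor=int(raw.get("downsample_factor", 1)),
        segmentation=SegmentationParams(
            t_lower=int(seg.get("t_lower", 52)),
            t_upper=int(seg.get("t_upper", 255)),
            cel_base=int(seg.get("cel_base", 0)),
            min_blob_size=int(seg.get("min_blob_size", 1)),
            connectivity=int(seg.get("connectivity", 26)),
        ),
        plates=plates,
        export_modes=tuple(exp.get("modes", list(export_mod.MODES))),
        export_margin=int(exp.get("margin", 2)),
        mesh_enabled=bool(mesh.get("enabled", True)),
        mesh_ascii=bool(mesh.get("ascii", False)),
        pointcloud=str(mesh.get("pointcloud", "none")),
        max_match_distance=raw.get("max_match_distance"),
    )


def _load_meta(cfg: RunConfig) -> VolumeMeta:
    if cfg.info is not None:
        return parse_info_file(Path(cfg.info).read_text())
    default = Path(cfg.input) / "volume.info" if cfg.kind == "tiff_folder" else None
    if default is not None and default.exists():
        return parse_info_file(default.read_text())
    raise MetadataAbsentError(
        "no .info file found: supply one with the 'info' config key "
        "(mandatory key voxel_size_um)"
    )


def run_pipeline(cfg: RunConfig) -> list[dict]:
    """Execute the full pipeline; returns the manifest rows.

    Deterministic: re-running the same configuration into a clean output
    directory yields bit-identical stacks, meshes and manifest.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out_dir: Path) -> list[dict]:
    meta = _load_meta(cfg)
    log.info("config: input=%s kind=%s downsample=%d seg=%s margin=%d modes=%s",
             cfg.input, cfg.kind, cfg.downsample_factor, cfg.segmentation,
             cfg.export_margin, cfg.export_modes)

    working = read_volume(cfg.input, cfg.kind, meta, cfg.downsample_factor)
    working = to_8bit(working)
    log.info("working volume: dims=%s (factor %d)", working.shape, cfg.downsample_factor)

    seg = cfg.segmentation
    vol = cel_shade(working, seg.cel_base) if seg.cel_base else working
    mask = bracket_threshold(vol, seg.t_lower, seg.t_upper)
    blobs = label_blobs(mask, seg.connectivity, seg.min_blob_size)
    spans = detect_plates(mask, seg.min_blob_size)
    log.info("segmentation: %d blobs, %d plate spans", len(blobs), len(spans))
    for s in spans:
        log.info("plate %d: slices %d..%d, centre %.1f",
                 s.plate_index, s.start_slice, s.end_slice, s.centre_slice)
    if not blobs:
        log.warning("no blobs found — nothing to export")
        export_mod.write_manifest([], out_dir / "manifest.csv")
        return []

    grids: list[LabelGrid | None] | None = None
    if cfg.plates is not None:
        if len(cfg.plates) != len(spans):
            raise ValueError(
                f"{len(cfg.plates)} plate configs supplied but {len(spans)} plates detected"
            )
        grids = []
        for i, pc in enumerate(cfg.plates):
            if pc.csv is None:
                grids.append(None)
                continue
            grid = load_label_grid(Path(pc.csv).read_text(), plate_index=i,
                                   transform=pc.transform)
            grids.append(grid)
            log.info("plate %d corner labels (after flips): %s", i, corner_labels(grid))

    assignments = assign_labels(blobs, grids, spans, cfg.max_match_distance)
    for a in assignments:
        log.info("blob %d -> %s (plate %d, cell %s, distance %.2f)",
                 a.blob_id, a.label, a.plate_index, a.cell, a.distance)

    # full-resolution pass
    if cfg.downsample_factor > 1:
        original = read_volume(cfg.input, cfg.kind, meta, 1)
    else:
        original = working
    original8 = to_8bit(original)

    blob_by_id = {b.id: b for b in blobs}
    manifest: list[dict] = []
    for a in assignments:
        blob = blob_by_id[a.blob_id]
        status = "ok"
        bbox_full = export_mod.scale_bbox_to_full(
            blob, cfg.downsample_factor, cfg.export_margin, original.shape
        )
        wmask = export_mod.blob_mask(mask, blob, seg.connectivity)
        fmask = export_mod.upscale_mask(wmask, cfg.downsample_factor, original.shape)
        job = export_mod.ExportJob(assignment=a, blob=blob, bbox_full=bbox_full,
                                   modes=cfg.export_modes, out_dir=out_dir)
        try:
            export_mod.export_specimen(original8, fmask, job)
            label_dir = out_dir / export_mod.sanitise_label(a.label)
            sl = tuple(slice(lo, hi) for lo, hi in bbox_full)
            mask_crop = fmask[sl]
            if cfg.mesh_enabled:
                mesh = meshing.marching_cubes(mask_crop)
                mesh = meshing.recentre_and_scale(mesh, meta.voxel_size_um)
                mesh.comments = [f"label {a.label}",
                                 f"voxel_size_um {meta.voxel_size_um:g}"]
                meshing.write_ply(mesh, label_dir / f"{export_mod.sanitise_label(a.label)}.ply",
                                  ascii=cfg.mesh_ascii)
            if cfg.pointcloud != "none":
                cloud = meshing.mask_to_pointcloud(mask_crop,
                                                   hollow=cfg.pointcloud == "hollow")
                np.savetxt(label_dir / f"{export_mod.sanitise_label(a.label)}_points.xyz",
                           cloud.points, fmt="%d")
        except meshing.EmptyMaskError:
            status = "empty-mask"
            log.warning("specimen %s: nothing to mesh", a.label)
        manifest.append({
            "label": a.label,
            "plate_index": a.plate_index,
            "cell_row": a.cell[0] if a.cell else "",
            "cell_col": a.cell[1] if a.cell else "",
            "blob_id": a.blob_id,
            "voxel_count": blob.voxel_count,
            "distance": f"{a.distance:.3f}",
            "bbox_full": ";".join(f"{lo}:{hi}" for lo, hi in bbox_full),
            "voxel_size_um": meta.voxel_size_um,
            "modes": "|".join(cfg.export_modes),
            "status": status,
        })

    export_mod.write_manifest(manifest, out_dir / "manifest.csv")
    log.info("exported %d specimens", len(manifest))
    return manifest


def split_plates(cfg: RunConfig) -> list[Path]:
    """Write each detected plate as its own full-resolution TIFF stack + .info.

    For memory-constrained machines: detection runs on the downsampled
    template, the z-ranges are scaled back up, and the original slices of
    each plate are written under ``out_dir/plate_<n>/``.
    """
    cfg.validate()
    meta = _load_meta(cfg)
    working = to_8bit(read_volume(cfg.input, cfg.kind, meta, cfg.downsample_factor))
    seg = cfg.segmentation
    vol = cel_shade(working, seg.cel_base) if seg.cel_base else working
    mask = bracket_threshold(vol, seg.t_lower, seg.t_upper)
    spans = detect_plates(mask, seg.min_blob_size)

    original = (read_volume(cfg.input, cfg.kind, meta, 1)
                if cfg.downsample_factor > 1 else working)
    original = to_8bit(original)
    d = cfg.downsample_factor
    out_paths = []
    for s in spans:
        z0 = s.start_slice * d
        z1 = min(original.shape[0], (s.end_slice + 1) * d)
        sub = Volume(data=original.data[z0:z1].copy(),
                     meta=VolumeMeta(voxel_size_um=meta.voxel_size_um,
                                     dims=(z1 - z0, *original.shape[1:]),
                                     bit_depth=8))
        plate_dir = Path(cfg.out_dir) / f"plate_{s.plate_index + 1}"
        paths = write_tiff_stack(sub, plate_dir)
        sub_meta = VolumeMeta(voxel_size_um=meta.voxel_size_um, dims=sub.shape,
                              bit_depth=8, slice_order=[p.name for p in paths])
        (plate_dir / "volume.info").write_text(write_info_file(sub_meta))
        out_paths.append(plate_dir)
    return out_paths
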