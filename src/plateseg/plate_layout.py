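"""Plate detection, CSV label grids and specimen-ID assignment.

Microtiter plates are stacked along z with empty gaps between them, so a
plate is a maximal run of z-slices whose foreground pixel count reaches the
minimum blob size; its centre is the median slice of the run.  Specimen IDs
come from one CSV per plate whose grid of cells mirrors the physical well
layout.  The grid is placed in volume x-y coordinates by a user transform
(flip, rotate about the grid centre, translate, per-axis pitch), and each
blob is matched to the nearest non-empty cell centre by Euclidean distance.
A cell claimed by several blobs (a doubled well) yields suffixed labels;
blobs too far from any cell — or every blob when no CSV is supplied — fall
back to sequential numeric labels so data is never silently dropped.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import Blob

__all__ = [
    "EMPTY",
    "PlateSpan",
    "GridTransform",
    "LabelGrid",
    "Assignment",
    "detect_plates",
    "slice_foreground_counts",
    "load_label_grid",
    "cell_centres",
    "corner_labels",
    "assign_labels",
]

#: Sentinel stored in a grid cell whose well holds no specimen.
EMPTY = None


@dataclass
class PlateSpan:
    """One detected plate: inclusive start/end slice and centre along z."""

    plate_index: int
    start_slice: int
    end_slice: int

    @property
    def centre_slice(self) -> float:
        # half-integer for even-length spans; used only for plate/grid
        # pairing, never as an array index
        return (self.start_slice + self.end_slice) / 2

    def contains(self, z: float) -> bool:
        return self.start_slice <= z <= self.end_slice


@dataclass
class GridTransform:
    """Places well-grid cell centres in volume x-y coordinates.

    Applied in the fixed order: flips (about the grid centre), rotation
    (about the grid centre), translation.  ``pitch`` is the cell spacing in
    working-resolution voxels per axis.
    """

    translate: tuple[float, float] = (0.0, 0.0)
    rotate_deg: float = 0.0
    flip_h: bool = False
    flip_v: bool = False
    pitch: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.pitch[0] <= 0 or self.pitch[1] <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")


@dataclass
class LabelGrid:
    """rows x cols of specimen-ID strings (or EMPTY) plus a placement transform."""

    cells: list[list[str | None]]
    transform: GridTransform = field(default_factory=GridTransform)
    plate_index: int = 0

    @property
    def rows(self) -> int:
        return len(self.cells)

    @property
    def cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0


@dataclass
class Assignment:
    """The label given to one blob: its plate, grid cell (or None) and distance."""

    blob_id: int
    plate_index: int
    cell: tuple[int, int] | None
    label: str
    distance: float


# --------------------------------------------------------------------------
# plate detection
# --------------------------------------------------------------------------

def slice_foreground_counts(mask: np.ndarray) -> np.ndarray:
    """Foreground pixel count of every z-slice."""
    return np.asarray(mask).astype(bool).sum(axis=(1, 2))


def detect_plates(mask: np.ndarray, min_blob_size: int) -> list[PlateSpan]:
    """Find stacked plates as maximal runs of occupied z-slices.

    A slice is occupied iff its foreground pixel count is at least
    ``min_blob_size``; consistent empty gaps between runs separate plates.
    Returns spans in z order; empty list if nothing is occupied.
    """
    counts = slice_foreground_counts(mask)
    return spans_from_counts(counts, min_blob_size)


def spans_from_counts(counts: np.ndarray | list[int], min_blob_size: int) -> list[PlateSpan]:
    """Run-length grouping of the per-slice count sequence (1D core of
    :func:`detect_plates`, exposed for direct use on precomputed counts)."""
    occupied = np.asarray(counts) >= min_blob_size
    spans: list[PlateSpan] = []
    start = None
    for z, occ in enumerate(occupied):
        if occ and start is None:
            start = z
        elif not occ and start is not None:
            spans.append(PlateSpan(len(spans), start, z - 1))
            start = None
    if start is not None:
        spans.append(PlateSpan(len(spans), start, len(occupied) - 1))
    return spans


# --------------------------------------------------------------------------
# label grids
# --------------------------------------------------------------------------

def load_label_grid(csv_text: str, plate_index: int = 0,
                    transform: GridTransform | None = None) -> LabelGrid:
    """Parse one plate's CSV grid of specimen IDs.

    The CSV has no header: every row is a plate row, every column a plate
    column.  Blank / whitespace-only cells become EMPTY wells.  The CSV must
    be rectangular and its non-empty labels unique (they become filenames).
    """
    rows = list(csv.reader(io.StringIO(csv_text)))
    if not rows:
        raise ValueError("label CSV is empty")
    width = len(rows[0])
    cells: list[list[str | None]] = []
    seen: set[str] = set()
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"ragged label CSV: row {r} has {len(row)} cells, expected {width}")
        out_row: list[str | None] = []
        for value in row:
            value = value.strip()
            if not value:
                out_row.append(EMPTY)
                continue
            if value in seen:
                raise ValueError(f"duplicate specimen ID {value!r} in label CSV")
            seen.add(value)
            out_row.append(value)
        cells.append(out_row)
    return LabelGrid(cells=cells, transform=transform or GridTransform(),
                     plate_index=plate_index)


def _flipped_cells(grid: LabelGrid) -> list[list[str | None]]:
    cells = grid.cells
    if grid.transform.flip_v:
        cells = cells[::-1]
    if grid.transform.flip_h:
        cells = [row[::-1] for row in cells]
    return cells


def cell_centres(grid: LabelGrid) -> np.ndarray:
    """(rows, cols, 2) array of transformed cell-centre (x, y) coordinates.

    Cell (r, c) starts at ``((c + 0.5) * pitch_x, (r + 0.5) * pitch_y)``;
    then flips about the grid centre, rotation about the grid centre, and
    translation are applied, in that order.
    """
    t = grid.transform
    R, C = grid.rows, grid.cols
    px, py = t.pitch
    cx, cy = C * px / 2, R * py / 2  # grid centre
    cols = (np.arange(C) + 0.5) * px
    rows = (np.arange(R) + 0.5) * py
    x = np.broadcast_to(cols[None, :], (R, C)).copy()
    y = np.broadcast_to(rows[:, None], (R, C)).copy()
    if t.flip_h:
        x = 2 * cx - x
    if t.flip_v:
        y = 2 * cy - y
    if t.rotate_deg:
        a = math.radians(t.rotate_deg)
        dx, dy = x - cx, y - cy
        x = cx + dx * math.cos(a) - dy * math.sin(a)
        y = cy + dx * math.sin(a) + dy * math.cos(a)
    return np.stack([x + t.translate[0], y + t.translate[1]], axis=-1)


def corner_labels(grid: LabelGrid) -> tuple[str | None, str | None, str | None, str | None]:
    """The four corner IDs after flips, for mirror-check display/logging.

    Order: top-left, top-right, bottom-left, bottom-right of the grid as it
    will be overlaid on the scan.  A human comparing these against the
    physical plate catches a mirrored scan before labels are committed.
    """
    cells = _flipped_cells(grid)
    return (cells[0][0], cells[0][-1], cells[-1][0], cells[-1][-1])


# --------------------------------------------------------------------------
# assignment
# --------------------------------------------------------------------------

def _numeric_label(counter: int) -> str:
    return f"specimen_{counter:04d}"


def _span_for_blob(blob: Blob, spans: list[PlateSpan]) -> PlateSpan:
    z = blob.centroid[0]
    for span in spans:
        if span.contains(z):
            return span
    # centroid in a gap: nearest span by centre distance
    return min(spans, key=lambda s: abs(s.centre_slice - z))


def assign_labels(
    blobs: list[Blob],
    grids: list[LabelGrid | None] | None,
    spans: list[PlateSpan],
    max_match_distance: float | None = None,
    matching: str = "nearest_cell",
) -> list[Assignment]:
    """Assign a unique output label to every blob.

    Each blob belongs to the plate span containing its centroid z (nearest
    span if it sits in a gap).  Within a plate it is matched to the nearest
    non-empty cell centre in x-y Euclidean distance — so specimens need not
    lie entirely inside the grid.  A cell claimed by k > 1 blobs yields
    ``label_1 .. label_k`` ordered by ascending distance (the doubled-well
    case); empty cells never receive a blob.  Blobs farther than
    ``max_match_distance`` from every cell, and all blobs of a plate whose
    grid is None, get sequential ``specimen_NNNN`` labels.

    ``max_match_distance`` defaults to ``0.75 * min(pitch)`` per plate.
    Ties between equidistant cells break row-major-first.

    ``matching="greedy_mutual"`` instead pairs blobs and cells greedily by
    ascending distance with each cell used at most once; surplus blobs (e.g.
    the second occupant of a doubled well) then degrade to numeric labels.
    """
    if matching not in ("nearest_cell", "greedy_mutual"):
        raise ValueError(f"unknown matching mode {matching!r}")
    if not spans:
        raise ValueError("no plate spans supplied")
    if grids is not None and len(grids) != len(spans):
        raise ValueError(f"{len(grids)} grids supplied for {len(spans)} plate spans")

    per_plate: dict[int, list[Blob]] = {s.plate_index: [] for s in spans}
    for blob in blobs:
        per_plate[_span_for_blob(blob, spans).plate_index].append(blob)

    assignments: list[Assignment] = []
    numeric_counter = 1
    used_labels: set[str] = set()

    def unique(label: str) -> str:
        # labels are unique by construction; guard against collisions across
        # plates' CSVs by suffixing
        out, k = label, 2
        while out in used_labels:
            out = f"{label}.{k}"
            k += 1
        used_labels.add(out)
        return out

    for span in spans:
        plate_blobs = per_plate[span.plate_index]
        grid = grids[span.plate_index] if grids is not None else None
        if grid is None:
            for blob in plate_blobs:
                assignments.append(Assignment(blob.id, span.plate_index, None,
                                              unique(_numeric_label(numeric_counter)),
                                              float("nan")))
                numeric_counter += 1
            continue

        centres = cell_centres(grid)  # (R, C, 2) of (x, y)
        flat_cells = [
            (r, c)
            for r in range(grid.rows)
            for c in range(grid.cols)
            if grid.cells[r][c] is not EMPTY
        ]
        limit = max_match_distance
        if limit is None:
            limit = 0.75 * min(grid.transform.pitch)

        if not flat_cells:
            matches: dict[tuple[int, int], list[tuple[float, Blob]]] = {}
            unmatched = list(plate_blobs)
        elif matching == "nearest_cell":
            centre_xy = np.array([centres[r, c] for (r, c) in flat_cells])
            matches = {}
            unmatched = []
            for blob in plate_blobs:
                bx, by = blob.centroid[2], blob.centroid[1]
                d = np.hypot(centre_xy[:, 0] - bx, centre_xy[:, 1] - by)
                best = int(np.argmin(d))  # argmin takes the first minimum:
                # flat_cells is row-major, so equidistant ties break
                # row-major-first
                if d[best] > limit:
                    unmatched.append(blob)
                else:
                    matches.setdefault(flat_cells[best], []).append((float(d[best]), blob))
        else:  # greedy mutual-nearest: every cell used at most once
            centre_xy = np.array([centres[r, c] for (r, c) in flat_cells])
            pairs = []
            for blob in plate_blobs:
                bx, by = blob.centroid[2], blob.centroid[1]
                d = np.hypot(centre_xy[:, 0] - bx, centre_xy[:, 1] - by)
                for ci, dist in enumerate(d):
                    if dist <= limit:
                        pairs.append((float(dist), blob.id, ci, blob))
            matches = {}
            used_blobs: set[int] = set()
            used_cells: set[int] = set()
            for dist, _, ci, blob in sorted(pairs, key=lambda t: (t[0], t[1], t[2])):
                if blob.id in used_blobs or ci in used_cells:
                    continue
                used_blobs.add(blob.id)
                used_cells.add(ci)
                matches[flat_cells[ci]] = [(dist, blob)]
            unmatched = [b for b in plate_blobs if b.id not in used_blobs]

        for (r, c) in sorted(matches):
            claimed = sorted(matches[(r, c)], key=lambda t: (t[0], t[1].id))
            base = grid.cells[r][c]
            if len(claimed) == 1:
                dist, blob = claimed[0]
                assignments.append(Assignment(blob.id, span.plate_index, (r, c),
                                              unique(base), dist))
            else:
                for k, (dist, blob) in enumerate(claimed, start=1):
                    assignments.append(Assignment(blob.id, span.plate_index, (r, c),
                                                  unique(f"{base}_{k}"), dist))
        for blob in unmatched:
            assignments.append(Assignment(blob.id, span.plate_index, None,
                                          unique(_numeric_label(numeric_counter)),
                                          float("nan")))
            numeric_counter += 1

    assignments.sort(key=lambda a: a.blob_id)
    return assignments
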