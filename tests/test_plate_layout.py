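"""Plate detection, label grids, grid transforms and label assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plateseg import (EMPTY, GridTransform, LabelGrid, PhantomConfig, assign_labels,
                      bracket_threshold, cell_centres, corner_labels, detect_plates,
                      generate_phantom, label_blobs, load_label_grid, spans_from_counts)
from conftest import runs_oracle


def segment_phantom(cfg, min_blob_size=2):
    vol, truth = generate_phantom(cfg)
    mask = bracket_threshold(vol, 52, 255)
    blobs = label_blobs(mask, 26, min_blob_size)
    spans = detect_plates(mask, min_blob_size)
    return vol, truth, mask, blobs, spans


def identity_grids(truth, transform_extra=None):
    """Grids from the phantom's CSVs, placed exactly over the wells."""
    from plateseg import load_label_grid

    cfg = truth.config
    grids = []
    for p, text in enumerate(truth.csv_texts):
        t = transform_extra or GridTransform()
        t = GridTransform(
            translate=(cfg.border + t.translate[0], cfg.border + t.translate[1]),
            rotate_deg=t.rotate_deg, flip_h=t.flip_h, flip_v=t.flip_v,
            pitch=(cfg.well_pitch, cfg.well_pitch),
        )
        grids.append(load_label_grid(text, plate_index=p, transform=t))
    return grids


class TestDetectPlates:
    def test_stated_rule_on_count_sequence(self):
        spans = spans_from_counts([0, 0, 5, 9, 8, 0, 0, 7, 7, 0], 3)
        assert [(s.start_slice, s.end_slice, s.centre_slice) for s in spans] == \
            [(2, 4, 3.0), (7, 8, 7.5)]

    def test_all_occupied_is_one_span(self):
        mask = np.ones((6, 4, 4), dtype=bool)
        spans = detect_plates(mask, 1)
        assert len(spans) == 1
        assert (spans[0].start_slice, spans[0].end_slice) == (0, 5)

    def test_nothing_occupied_is_empty(self):
        assert detect_plates(np.zeros((5, 4, 4), dtype=bool), 1) == []

    def test_three_plate_phantom_yields_three_spans_inside_truth(self):
        cfg = PhantomConfig(seed=9, n_plates=3, gap_slices=8)
        _, truth, _, _, spans = segment_phantom(cfg)
        assert len(spans) == 3
        for got, want in zip(spans, truth.spans):
            assert want.start_slice <= got.start_slice <= got.end_slice <= want.end_slice

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=60), st.integers(1, 10))
    @settings(max_examples=200, deadline=None)
    def test_matches_run_length_oracle(self, counts, min_size):
        spans = spans_from_counts(counts, min_size)
        assert [(s.start_slice, s.end_slice) for s in spans] == runs_oracle(counts, min_size)
        assert [s.plate_index for s in spans] == list(range(len(spans)))


class TestLabelGrid:
    def test_rectangular_csv(self):
        grid = load_label_grid("A1,A2,A3\nB1,B2,B3")
        assert (grid.rows, grid.cols) == (2, 3)
        assert all(cell is not EMPTY for row in grid.cells for cell in row)

    def test_blank_cell_becomes_empty(self):
        grid = load_label_grid("A1,,A3\nB1,B2,B3")
        assert grid.cells[0][1] is EMPTY

    def test_ragged_csv_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            load_label_grid("A1,A2\nB1")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            load_label_grid("A1,A1")


class TestCellCentres:
    def test_identity_transform_closed_form(self):
        grid = LabelGrid(cells=[["A"]], transform=GridTransform(pitch=(10, 10)))
        np.testing.assert_allclose(cell_centres(grid)[0, 0], (5.0, 5.0))

    def test_rotate_180_maps_onto_opposite_cell(self):
        cells = [["A1", "A2", "A3"], ["B1", "B2", "B3"]]
        base = LabelGrid(cells=cells, transform=GridTransform(pitch=(7, 9)))
        rot = LabelGrid(cells=cells, transform=GridTransform(pitch=(7, 9), rotate_deg=180))
        np.testing.assert_allclose(cell_centres(rot)[0, 0], cell_centres(base)[1, 2],
                                   atol=1e-12)

    def test_flip_h_swaps_row_end_centres(self):
        cells = [["A1", "A2", "A3"]]
        base = LabelGrid(cells=cells, transform=GridTransform(pitch=(4, 4)))
        flip = LabelGrid(cells=cells, transform=GridTransform(pitch=(4, 4), flip_h=True))
        c0, c1 = cell_centres(base), cell_centres(flip)
        assert c1[0, 0, 0] == c0[0, 2, 0]
        assert c1[0, 2, 0] == c0[0, 0, 0]

    def test_translation_shifts_all_centres(self):
        cells = [["A", "B"], ["C", "D"]]
        base = LabelGrid(cells=cells, transform=GridTransform(pitch=(3, 3)))
        moved = LabelGrid(cells=cells, transform=GridTransform(pitch=(3, 3),
                                                               translate=(2.5, -1)))
        np.testing.assert_allclose(cell_centres(moved),
                                   cell_centres(base) + np.array([2.5, -1]))


class TestCornerLabels:
    def test_identity(self):
        grid = load_label_grid("A1,A2,A3\nB1,B2,B3")
        assert corner_labels(grid) == ("A1", "A3", "B1", "B3")

    def test_flip_h(self):
        grid = load_label_grid("A1,A2,A3\nB1,B2,B3",
                               transform=GridTransform(flip_h=True))
        assert corner_labels(grid) == ("A3", "A1", "B3", "B1")

    def test_degenerate_1x1(self):
        grid = load_label_grid("X")
        assert corner_labels(grid) == ("X", "X", "X", "X")


class TestAssignLabels:
    def test_identity_grids_recover_all_truth_labels(self):
        _, truth, _, blobs, spans = segment_phantom(PhantomConfig(seed=7))
        assignments = assign_labels(blobs, identity_grids(truth), spans)
        assert sorted(a.label for a in assignments) == sorted(truth.labels())
        assert len(assignments) == len(blobs)

    def test_translated_grid_up_to_point4_pitch_still_exact(self):
        cfg = PhantomConfig(seed=8)
        _, truth, _, blobs, spans = segment_phantom(cfg)
        shift = 0.4 * cfg.well_pitch
        grids = identity_grids(truth, GridTransform(translate=(shift, -shift)))
        assignments = assign_labels(blobs, grids, spans)
        assert sorted(a.label for a in assignments) == sorted(truth.labels())

    def test_empty_well_cell_receives_no_blob(self):
        cfg = PhantomConfig(seed=13, occupancy=0.85)
        _, truth, _, blobs, spans = segment_phantom(cfg)
        n_wells = cfg.n_plates * cfg.grid_rows * cfg.grid_cols
        assert len(truth.specimens) < n_wells  # some wells actually empty
        assignments = assign_labels(blobs, identity_grids(truth), spans)
        assert sorted(a.label for a in assignments) == sorted(truth.labels())
        assigned_cells = {(a.plate_index, *a.cell) for a in assignments}
        occupied = {(s.plate_index, s.row, s.col) for s in truth.specimens}
        assert assigned_cells == occupied

    def test_doubled_well_yields_suffixed_labels(self):
        cfg = PhantomConfig(seed=5, doubled_well=True)
        _, truth, _, blobs, spans = segment_phantom(cfg)
        assignments = assign_labels(blobs, identity_grids(truth), spans)
        from collections import Counter

        cell_truth = Counter((s.plate_index, s.row, s.col) for s in truth.specimens)
        (doubled_cell, _), = [kv for kv in cell_truth.items() if kv[1] == 2]
        doubled = [a for a in assignments
                   if a.cell is not None and (a.plate_index, *a.cell) == doubled_cell]
        assert sorted(a.label[-2:] for a in doubled) == ["_1", "_2"]
        assert doubled[0].label[:-2] == doubled[1].label[:-2]

    def test_no_grid_falls_back_to_sequential_numbering(self):
        _, truth, _, blobs, spans = segment_phantom(PhantomConfig(seed=7))
        assignments = assign_labels(blobs, None, spans)
        labels = [a.label for a in assignments]
        assert all(l.startswith("specimen_") for l in labels)
        assert len(set(labels)) == len(labels)

    def test_far_blob_degrades_to_numeric_label(self):
        """A blob beyond max_match_distance keeps its data under a numeric label."""
        from plateseg import Blob, PlateSpan

        near = Blob(id=1, voxel_count=8, bbox=((0, 2), (4, 6), (4, 6)),
                    centroid=(1.0, 5.0, 5.0))
        far = Blob(id=2, voxel_count=8, bbox=((0, 2), (4, 6), (40, 42)),
                   centroid=(1.0, 5.0, 41.0))
        grid = load_label_grid("A1", transform=GridTransform(pitch=(10, 10)))
        spans = [PlateSpan(0, 0, 3)]
        assignments = assign_labels([near, far], [grid], spans)
        by_id = {a.blob_id: a for a in assignments}
        assert by_id[1].label == "A1" and by_id[1].cell == (0, 0)
        assert by_id[2].label.startswith("specimen_") and by_id[2].cell is None

    def test_assignment_is_a_function_with_unique_labels(self):
        cfg = PhantomConfig(seed=5, doubled_well=True)
        _, truth, _, blobs, spans = segment_phantom(cfg)
        assignments = assign_labels(blobs, identity_grids(truth), spans)
        ids = [a.blob_id for a in assignments]
        assert sorted(ids) == sorted(b.id for b in blobs)
        labels = [a.label for a in assignments]
        assert len(set(labels)) == len(labels)

    def test_invariant_under_common_rigid_translation(self):
        """Translating grid and blob centroids together leaves labels unchanged."""
        from dataclasses import replace

        _, truth, _, blobs, spans = segment_phantom(PhantomConfig(seed=7))
        grids = identity_grids(truth)
        base = assign_labels(blobs, grids, spans)
        dx, dy = 3.7, -2.2
        moved_blobs = [replace(b, centroid=(b.centroid[0], b.centroid[1] + dy,
                                            b.centroid[2] + dx)) for b in blobs]
        moved_grids = []
        for g in grids:
            t = g.transform
            moved_grids.append(LabelGrid(cells=g.cells, plate_index=g.plate_index,
                                         transform=GridTransform(
                                             translate=(t.translate[0] + dx,
                                                        t.translate[1] + dy),
                                             pitch=t.pitch)))
        moved = assign_labels(moved_blobs, moved_grids, spans)
        assert [(a.blob_id, a.label) for a in base] == [(a.blob_id, a.label) for a in moved]

    def test_greedy_mutual_matching_uses_each_cell_once(self):
        """Under mutual matching the second occupant of a doubled well
        degrades to a numeric label instead of a suffix."""
        cfg = PhantomConfig(seed=5, doubled_well=True)
        _, truth, _, blobs, spans = segment_phantom(cfg)
        assignments = assign_labels(blobs, identity_grids(truth), spans,
                                    matching="greedy_mutual")
        labels = [a.label for a in assignments]
        assert not any(l[-2:] in ("_1", "_2") for l in labels)
        assert sum(l.startswith("specimen_") for l in labels) == 1
        cells = [(a.plate_index, *a.cell) for a in assignments if a.cell is not None]
        assert len(cells) == len(set(cells))

    def test_grid_count_mismatch_is_hard_error(self):
        _, truth, _, blobs, spans = segment_phantom(PhantomConfig(seed=7))
        with pytest.raises(ValueError, match="grids"):
            assign_labels(blobs, identity_grids(truth)[:1], spans)
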