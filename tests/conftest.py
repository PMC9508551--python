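"""Shared fixtures and brute-force oracles.

The oracles here are deliberately naive (BFS flood fill, run-length scans,
per-voxel neighbour checks) and independent of the library code paths they
verify.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from plateseg import PhantomConfig, generate_phantom

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    """All 3D neighbour offsets of the given connectivity class."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                nz = abs(dz) + abs(dy) + abs(dx)
                if nz == 0:
                    continue
                if connectivity == 6 and nz > 1:
                    continue
                if connectivity == 18 and nz > 2:
                    continue
                offsets.append((dz, dy, dx))
    return offsets


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Exhaustive BFS flood fill; returns components as sets of (z, y, x)."""
    mask = np.asarray(mask).astype(bool)
    offsets = neighbour_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                        and 0 <= p[2] < mask.shape[2] and mask[p] and not seen[p]):
                    seen[p] = True
                    queue.append(p)
        comps.append(comp)
    return comps


def component_stats(comp: set) -> tuple:
    """(voxel_count, bbox, centroid) of a voxel set, for partition comparison."""
    arr = np.array(sorted(comp))
    bbox = tuple((int(arr[:, a].min()), int(arr[:, a].max()) + 1) for a in range(3))
    centroid = tuple(np.round(arr.mean(axis=0), 9))
    return (len(comp), bbox, centroid)


def runs_oracle(counts, min_size: int) -> list[tuple[int, int]]:
    """Run-length oracle: maximal runs of counts >= min_size as (start, end)."""
    runs = []
    start = None
    for z, c in enumerate(counts):
        if c >= min_size and start is None:
            start = z
        elif c < min_size and start is not None:
            runs.append((start, z - 1))
            start = None
    if start is not None:
        runs.append((start, len(counts) - 1))
    return runs


def surface_voxels_oracle(mask: np.ndarray) -> set:
    """A voxel is surface iff any face/edge/corner neighbour is background
    (out-of-bounds counts as background)."""
    mask = np.asarray(mask).astype(bool)
    offsets = neighbour_offsets(26)
    surface = set()
    for z, y, x in map(tuple, np.argwhere(mask)):
        for dz, dy, dx in offsets:
            p = (z + dz, y + dy, x + dx)
            outside = not (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                           and 0 <= p[2] < mask.shape[2])
            if outside or not mask[p]:
                surface.add((z, y, x))
                break
    return surface


def digital_ellipsoid(shape, centre, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (((zz - centre[0]) / radii[0]) ** 2 + ((yy - centre[1]) / radii[1]) ** 2
            + ((xx - centre[2]) / radii[2]) ** 2) <= 1.0


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_phantom():
    """Default 2-plate, 4x6, fully occupied phantom with its truth."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """The default phantom written to disk (TIFF folder + .info + CSVs + truth)."""
    from plateseg import write_phantom

    out = tmp_path_factory.mktemp("phantom")
    write_phantom(PhantomConfig(seed=7), out)
    return out
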