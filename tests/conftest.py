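"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
import trimesh

from scaffoldnet.geometry import CUBE_EDGE_MM

L = CUBE_EDGE_MM


def box_mesh(bounds):
    """Axis-aligned box mesh from ((ax, ay, az), (bx, by, bz)) in mm."""
    (ax, ay, az), (bx, by, bz) = bounds
    b = trimesh.creation.box(extents=(bx - ax, by - ay, bz - az))
    b.apply_translation([(ax + bx) / 2, (ay + by) / 2, (az + bz) / 2])
    return b


def box_union_mesh(boxes):
    """Triangle soup of several (possibly overlapping) boxes.

    Even-odd parity of the soup equals the parity of the number of
    boxes containing a point, which is what the brute-force oracle
    evaluates.
    """
    return trimesh.util.concatenate([box_mesh(b) for b in boxes])


def box_union_oracle(boxes, n_slices, spacing, resolution):
    """Brute-force point-in-solid parity at every pixel center."""
    p = L / resolution
    xc = (np.arange(resolution) + 0.5) * p
    yc = (np.arange(resolution) + 0.5) * p
    out = np.zeros((n_slices, resolution, resolution), dtype=np.uint8)
    for k in range(n_slices):
        zk = (k + 0.5) * spacing
        count = np.zeros((resolution, resolution), dtype=int)
        for (a, b) in boxes:
            if not (a[2] < zk < b[2]):
                continue
            inx = (xc >= a[0]) & (xc < b[0])
            iny = (yc >= a[1]) & (yc < b[1])
            count += np.outer(iny, inx).astype(int)  # rows = y
        out[k] = (count % 2).astype(np.uint8)
    return out


def random_boxes(rng, resolution, n_slices=20, spacing=0.25, max_boxes=4):
    """Random boxes with edges snapped to the pixel/slice grid.

    Snapping guarantees no box face contains a pixel center or slice
    plane, so the rasterizer and the oracle agree exactly.
    """
    p = L / resolution
    boxes = []
    for _ in range(rng.integers(1, max_boxes + 1)):
        ix = np.sort(rng.choice(resolution + 1, size=2, replace=False))
        iy = np.sort(rng.choice(resolution + 1, size=2, replace=False))
        iz = np.sort(rng.choice(n_slices + 1, size=2, replace=False))
        boxes.append(((ix[0] * p, iy[0] * p, iz[0] * spacing),
                      (ix[1] * p, iy[1] * p, iz[1] * spacing)))
    return boxes


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    return box_mesh(((0, 0, 0), (L, L, L)))
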