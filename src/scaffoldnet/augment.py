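"""Volumetric data augmentation for voxelized scaffold geometries.

Six cumulative strategies expand a base library of labelled occupancy
tensors; for a base of ``n`` lattices the record counts are exactly
``n, 6n, 12n, 18n, 24n, 34n`` (20 -> 20/120/240/360/480/680):

1. the untransformed base;
2. plus in-plane rotations about z at 15°, 30°, 45°, 60°, 75°;
3. plus a zoom-in of every record of strategy 2;
4. plus vertical flips of the 6n non-zoomed records;
5. plus horizontal flips of the 6n non-zoomed records;
6. plus 3D rotations of the base about the x and y axes at the same
   five angles.

Labels are copied unchanged from the source lattice — the working
assumption being that the transforms describe the same geometry seen
differently.  (For zoom this is an approximation: elastic moduli are
not scale-free once strut slenderness changes; the caveat is
documented, the convention kept.)

All transforms map binary grids to binary grids of identical shape;
interpolating transforms re-binarize at 0.5 with ties counted as
material, the same rule the slicer's downscaler uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .elasticity import PropertyVector
from .errors import ShapeError
from .geometry import CUBE_EDGE_MM

STRATEGY_ANGLES = (15.0, 30.0, 45.0, 60.0, 75.0)
DEFAULT_ZOOM = 1.25

#: record-count multiplier per strategy, for any base size
STRATEGY_MULTIPLIERS = {1: 1, 2: 6, 3: 12, 4: 18, 5: 24, 6: 34}


@dataclass(frozen=True)
class Record:
    grid: np.ndarray
    label: PropertyVector
    provenance: str


@dataclass
class AugmentedDataset:
    """Labelled voxel grids produced by one augmentation strategy."""

    records: List[Record]
    strategy_id: int
    seed: int
    base_count: int = 0

    def __len__(self):
        return len(self.records)

    def grids(self) -> np.ndarray:
        return np.stack([r.grid for r in self.records])

    def labels(self) -> np.ndarray:
        return np.stack([r.label.as_array() for r in self.records])

    def provenances(self) -> List[str]:
        return [r.provenance for r in self.records]


def _binarize(a: np.ndarray) -> np.ndarray:
    return (a >= 0.5).astype(np.uint8)


def _check_binary(grid):
    g = np.asarray(grid)
    if g.ndim != 3 or not np.isin(g, (0, 1)).all():
        raise ShapeError("expected a 3D binary occupancy grid")
    return g


def rotate_z(grid: np.ndarray, angle: float) -> np.ndarray:
    """Rotate each slice about the image center within a fixed footprint.

    Bilinear rotation re-binarized at 0.5; material rotated past the
    frame is lost and exposed regions fill with void.  Exact for
    quarter turns, and material-fraction preserving (to resampling
    tolerance) for geometry with enough clearance from the frame, e.g.
    a centered cylinder.
    """
    g = _check_binary(grid)
    if angle % 360 == 0:
        return g.copy()
    out = np.empty_like(g)
    for k in range(g.shape[2]):
        sl = g[:, :, k].astype(float)
        rot = ndimage.rotate(sl, angle, reshape=False, order=1, cval=0.0)
        out[:, :, k] = _binarize(rot)
    return out


def zoom_in(grid: np.ndarray, factor: float = DEFAULT_ZOOM) -> np.ndarray:
    """Central crop of side ``round(n/factor)`` resampled back to n."""
    if factor <= 1:
        raise ValueError(f"zoom factor must exceed 1, got {factor}")
    g = _check_binary(grid)
    nx, ny, nz = g.shape
    cx, cy = int(round(nx / factor)), int(round(ny / factor))
    ox, oy = (nx - cx) // 2, (ny - cy) // 2
    crop = g[ox:ox + cx, oy:oy + cy, :].astype(float)
    out = np.empty_like(g)
    for k in range(nz):
        out[:, :, k] = _binarize(
            _sk_resize(crop[:, :, k], (nx, ny), order=1, anti_aliasing=False,
                       preserve_range=True))
    return out


def flip(grid: np.ndarray, axis: str) -> np.ndarray:
    """Mirror slice rows (``vertical``) or columns (``horizontal``).

    Flips act in-plane on every slice, never along the z stack; they
    are involutions and preserve the material fraction exactly.
    """
    g = _check_binary(grid)
    if axis == "vertical":      # mirror rows = the y image axis
        return np.flip(g, axis=1).copy()
    if axis == "horizontal":    # mirror columns = the x image axis
        return np.flip(g, axis=0).copy()
    raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")


def rotate_about_xy(grid: np.ndarray, axis: str, angle: float,
                    cube_edge: float = CUBE_EDGE_MM,
                    slice_spacing: float = None) -> np.ndarray:
    """Rigid 3D rotation of the occupancy tensor about the cell center.

    The rotation happens in physical coordinates, so the anisotropic
    voxel size (lateral ``L/n`` vs axial slice spacing) is honoured.
    Nearest-neighbour sampling keeps the grid binary; material rotated
    out of the frame is lost, exposed frame corners fill with void.
    """
    g = _check_binary(grid)
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if angle % 360 == 0:
        return g.copy()
    nx, ny, nz = g.shape
    if slice_spacing is None:
        slice_spacing = cube_edge / nz
    voxel = np.array([cube_edge / nx, cube_edge / ny, slice_spacing])
    # index of the cell center: voxel i sits at physical (i + 0.5) * h
    center = (np.array([nx, ny, nz]) - 1) / 2.0
    th = np.deg2rad(angle)
    c, s = np.cos(th), np.sin(th)
    if axis == "x":
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    else:
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    # output index -> physical offset -> inverse-rotate -> input index
    S = np.diag(voxel)
    Sinv = np.diag(1.0 / voxel)
    A = Sinv @ R.T @ S
    offset = center - A @ center
    idx = np.stack(np.meshgrid(*(np.arange(n) for n in g.shape),
                               indexing="ij"), axis=-1).astype(float)
    src = np.rint(idx @ A.T + offset).astype(int)
    valid = ((src >= 0) & (src < np.array(g.shape))).all(axis=-1)
    out = np.zeros_like(g)
    sv = src[valid]
    out[valid] = g[sv[:, 0], sv[:, 1], sv[:, 2]]
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# strategy assembly


def build_strategy(base: Sequence[Tuple[np.ndarray, PropertyVector, str]],
                   strategy_id: int, seed: int = 0,
                   zoom: float = DEFAULT_ZOOM) -> AugmentedDataset:
    """Expand a labelled base library with one of the six strategies.

    ``base`` holds ``(grid, label, name)`` triples.  Labels of every
    augmented record equal their source's label; provenance tags record
    the source name and the transform chain.
    """
    if strategy_id not in STRATEGY_MULTIPLIERS:
        raise ValueError(f"strategy_id must be 1..6, got {strategy_id}")
    base_records = [Record(np.asarray(g, dtype=np.uint8), lab, name)
                    for g, lab, name in base]
    records = list(base_records)

    if strategy_id >= 2:
        rotated = [Record(rotate_z(r.grid, a), r.label, f"{r.provenance}|rotz{a:g}")
                   for r in base_records for a in STRATEGY_ANGLES]
        records += rotated
    if strategy_id >= 3:
        non_zoomed = list(records)  # base + z-rotations: 6n records
        records += [Record(zoom_in(r.grid, zoom), r.label,
                           f"{r.provenance}|zoom{zoom:g}")
                    for r in non_zoomed]
    if strategy_id >= 4:
        records += [Record(flip(r.grid, "vertical"), r.label,
                           f"{r.provenance}|vflip")
                    for r in non_zoomed]
    if strategy_id >= 5:
        records += [Record(flip(r.grid, "horizontal"), r.label,
                           f"{r.provenance}|hflip")
                    for r in non_zoomed]
    if strategy_id >= 6:
        records += [Record(rotate_about_xy(r.grid, ax, a), r.label,
                           f"{r.provenance}|rot{ax}{a:g}")
                    for r in base_records for ax in ("x", "y")
                    for a in STRATEGY_ANGLES]

    expected = STRATEGY_MULTIPLIERS[strategy_id] * len(base_records)
    assert len(records) == expected, (len(records), expected)
    return AugmentedDataset(records, strategy_id, seed,
                            base_count=len(base_records))
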