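"""Procedural generation of unit-cell scaffold geometries.

A scaffold unit cell is a porous solid inscribed in a cube of edge
``CUBE_EDGE_MM`` = 5 mm.  Four parametric families provide geometric
diversity comparable to a hand-designed CAD collection:

``strut_grid``
    Union of axis-aligned square-section struts on a periodic grid.
``truss``
    Irregular interconnections of cylindrical struts between seeded
    nodes, always including the four vertical cube edges so a
    compressive load path exists.
``implicit_surface``
    Solid network of a gyroid-like triply periodic implicit field.
``inverse``
    Voxelwise complement of another family member (a porous solid
    obtained by subtracting a scaffold from the bulk cube).

Every family is defined by an analytic indicator field (solid/void at a
point).  Triangle meshes are produced by polygonizing that field with
marching cubes on a fine sample grid, which guarantees watertight
surfaces; boolean operations (the ``inverse`` family) act on the field,
not on meshes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from .errors import InvalidSpecError, STLFormatError, TopologyError

#: Edge length of the working cube, mm.
CUBE_EDGE_MM = 5.0

#: Default sample resolution for polygonization; 5 mm / 100 = 0.05 mm,
#: the mesh precision used when exporting scaffold CAD models for slicing.
DEFAULT_MESH_RESOLUTION = 100

_FAMILIES = ("strut_grid", "truss", "implicit_surface", "inverse")


@dataclass(frozen=True)
class LatticeSpec:
    """Parametric description of one unit-cell scaffold.

    Parameters
    ----------
    family : str
        One of ``strut_grid``, ``truss``, ``implicit_surface``,
        ``inverse``.
    params : dict
        Family-specific parameters (periods and widths in mm,
        dimensionless iso-levels, or a ``source`` spec for ``inverse``).
    seed : int
        Seed for stochastic families (``truss``); ignored otherwise.
    name : str
        Identifier used in provenance records.
    """

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise InvalidSpecError(f"unknown lattice family {self.family!r}")


# ---------------------------------------------------------------------------
# indicator fields


def _near_grid(t: np.ndarray, period: float, half_width: float) -> np.ndarray:
    r = np.remainder(t, period)
    return np.minimum(r, period - r) <= half_width + 1e-12


def _strut_grid_field(pts, period, strut_width):
    gx = _near_grid(pts[..., 0], period, strut_width / 2)
    gy = _near_grid(pts[..., 1], period, strut_width / 2)
    gz = _near_grid(pts[..., 2], period, strut_width / 2)
    return (gy & gz) | (gx & gz) | (gx & gy)


def strut_grid_solid_fraction(period: float, strut_width: float,
                              cube_edge: float = CUBE_EDGE_MM) -> float:
    """Closed-form solid fraction of a strut grid by inclusion-exclusion.

    With grid planes at multiples of ``period`` (half-struts on the cube
    boundary), the 1D measure fraction covered by strut cross-sections is
    ``a = m*w/L`` with ``m = L/period`` lines.  The union of the three
    orthogonal strut sets then occupies ``3 a^2 - 2 a^3`` of the cube.
    """
    m = cube_edge / period
    a = min(m * strut_width / cube_edge, 1.0)
    return 3 * a**2 - 2 * a**3


def _gyroid_field(pts, level, periods, cube_edge=CUBE_EDGE_MM):
    w = 2.0 * np.pi * periods / cube_edge
    x, y, z = pts[..., 0] * w, pts[..., 1] * w, pts[..., 2] * w
    g = np.sin(x) * np.cos(y) + np.sin(y) * np.cos(z) + np.sin(z) * np.cos(x)
    return g <= level


def _truss_segments(seed, n_struts, cube_edge=CUBE_EDGE_MM):
    rng = np.random.default_rng(seed)
    L = cube_edge
    corners = np.array([[x, y, z] for x in (0, L) for y in (0, L) for z in (0, L)],
                       dtype=float)
    # the four vertical cube edges guarantee a load path bottom -> top
    segs = [(corners[i], corners[i + 1]) for i in (0, 2, 4, 6)]
    nodes = np.vstack([corners, rng.uniform(0, L, size=(max(n_struts, 4), 3))])
    for _ in range(max(n_struts - 4, 0)):
        i, j = rng.choice(len(nodes), size=2, replace=False)
        segs.append((nodes[i], nodes[j]))
    return segs


def _truss_field(pts, seed, n_struts, radius):
    segs = _truss_segments(seed, n_struts)
    flat = pts.reshape(-1, 3)
    dmin = np.full(len(flat), np.inf)
    for a, b in segs:
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-12:
            continue
        t = np.clip((flat - a) @ ab / denom, 0.0, 1.0)
        d = np.linalg.norm(flat - (a + t[:, None] * ab), axis=1)
        np.minimum(dmin, d, out=dmin)
    return (dmin <= radius).reshape(pts.shape[:-1])


def evaluate_field(spec: LatticeSpec, pts: np.ndarray) -> np.ndarray:
    """Evaluate the solid indicator of ``spec`` at points (..., 3) in mm."""
    p = spec.params
    if spec.family == "strut_grid":
        _validate_strut_params(p["period"], p["strut_width"])
        return _strut_grid_field(pts, p["period"], p["strut_width"])
    if spec.family == "implicit_surface":
        _validate_level(p["level"])
        return _gyroid_field(pts, p["level"], p.get("periods", 1))
    if spec.family == "truss":
        return _truss_field(pts, spec.seed, p.get("n_struts", 12), p["radius"])
    if spec.family == "inverse":
        return ~evaluate_field(p["source"], pts)
    raise InvalidSpecError(f"unknown family {spec.family!r}")


def _validate_strut_params(period, strut_width):
    if not (0 < period <= CUBE_EDGE_MM + 1e-9):
        raise InvalidSpecError(f"period must be in (0, {CUBE_EDGE_MM}] mm, got {period}")
    if strut_width <= 0:
        raise InvalidSpecError(f"strut_width must be positive, got {strut_width}")
    if strut_width > period:
        raise InvalidSpecError(
            f"strut_width {strut_width} mm exceeds period {period} mm")


def _validate_level(level):
    # the gyroid field ranges over [-1.5, 1.5]; outside, one phase vanishes
    if abs(level) >= 1.5:
        raise InvalidSpecError(
            f"iso-level {level} leaves the whole field on one side (|level| >= 1.5)")


# ---------------------------------------------------------------------------
# voxel sampling and polygonization


def sample_field(spec: LatticeSpec, shape=(32, 32, 20),
                 cube_edge: float = CUBE_EDGE_MM) -> np.ndarray:
    """Sample the solid indicator at voxel centers of a ``shape`` grid.

    Returns a binary occupancy array (1 = material).  Voxel centers lie
    at ``(i + 0.5) * L / n`` along each axis.
    """
    axes = [(np.arange(n) + 0.5) * (cube_edge / n) for n in shape]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return evaluate_field(spec, pts).astype(np.uint8)


def mesh_from_spec(spec: LatticeSpec,
                   resolution: int = DEFAULT_MESH_RESOLUTION,
                   cube_edge: float = CUBE_EDGE_MM) -> trimesh.Trimesh:
    """Polygonize the indicator field of ``spec`` into a watertight mesh.

    The field is sampled on a ``resolution``^3 grid, padded with a void
    ring so marching cubes closes the surface at the cube faces, and
    vertices are clipped back to the working cube ``[0, L]^3``.
    """
    occ = sample_field(spec, (resolution,) * 3, cube_edge).astype(np.float32)
    if occ.max() == 0:
        raise InvalidSpecError(f"spec {spec.name or spec.family!r} produced empty geometry")
    h = cube_edge / resolution
    vol = np.pad(occ, 1, constant_values=0.0)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=(h, h, h))
    verts = np.clip(verts - 0.5 * h, 0.0, cube_edge)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    if not mesh.is_watertight:
        raise TopologyError(
            f"polygonization of {spec.name or spec.family!r} is not watertight")
    return mesh


def make_strut_grid(period: float, strut_width: float,
                    resolution: int = DEFAULT_MESH_RESOLUTION) -> trimesh.Trimesh:
    """Mesh the union of axis-aligned square-section struts.

    Struts of width ``strut_width`` run along x, y and z on grid planes
    spaced ``period`` apart.  ``strut_width == period`` degenerates to
    the full calibration cube; ``strut_width > period`` is invalid.
    """
    spec = LatticeSpec("strut_grid",
                       {"period": period, "strut_width": strut_width})
    _validate_strut_params(period, strut_width)
    return mesh_from_spec(spec, resolution)


def make_implicit_cell(level: float, periods: int = 1,
                       resolution: int = DEFAULT_MESH_RESOLUTION) -> trimesh.Trimesh:
    """Mesh the solid network ``g(x) <= level`` of a gyroid-like field."""
    _validate_level(level)
    spec = LatticeSpec("implicit_surface", {"level": level, "periods": periods})
    return mesh_from_spec(spec, resolution)


def make_truss(seed: int = 0, n_struts: int = 12, radius: float = 0.4,
               resolution: int = DEFAULT_MESH_RESOLUTION) -> trimesh.Trimesh:
    """Mesh an irregular truss of cylindrical struts (seeded, reproducible)."""
    spec = LatticeSpec("truss", {"n_struts": n_struts, "radius": radius}, seed=seed)
    return mesh_from_spec(spec, resolution)


def invert_lattice(grid: np.ndarray) -> np.ndarray:
    """Voxelwise complement of a binary occupancy grid.

    Porosity of the output is exactly ``100 - porosity(input)``.
    """
    g = np.asarray(grid)
    if not np.isin(g, (0, 1)).all():
        raise InvalidSpecError("invert_lattice expects a binary grid")
    return (1 - g).astype(g.dtype)


# ---------------------------------------------------------------------------
# default library

def _sg(name, period, width):
    return LatticeSpec("strut_grid", {"period": period, "strut_width": width}, name=name)


def _gy(name, level, periods):
    return LatticeSpec("implicit_surface", {"level": level, "periods": periods}, name=name)


def _tr(name, seed, radius, n_struts):
    return LatticeSpec("truss", {"radius": radius, "n_struts": n_struts},
                       seed=seed, name=name)


def _inv(name, source):
    return LatticeSpec("inverse", {"source": source}, name=name)


def default_library():
    """Curated default library: 20 training specs + 8 disjoint test specs.

    Specs are chosen once so voxelized porosities span at least
    [10%, 90%] with complementary (inverse) pairs included.
    """
    train = [
        _sg("sg_thick", 2.5, 2.1),
        _sg("sg_heavy", 2.5, 1.6),
        _sg("sg_mid", 2.5, 1.1),
        _sg("sg_light", 2.5, 0.8),
        _sg("sg_fine", 2.5, 0.4),
        _sg("sg_dense_fine", 1.25, 0.7),
        _sg("sg_dense_thin", 1.25, 0.45),
        _sg("sg_frame", 5.0, 2.2),
        _gy("gy_lo", -1.0, 1),
        _gy("gy_open", -0.5, 1),
        _gy("gy_mid", 0.0, 1),
        _gy("gy_closed", 0.5, 2),
        _gy("gy_hi", 1.0, 2),
        _gy("gy_fine", 0.25, 3),
        _tr("truss_a", 11, 0.35, 14),
        _tr("truss_b", 22, 0.5, 10),
        _tr("truss_c", 33, 0.25, 20),
        _inv("inv_sg_heavy", _sg("sg_heavy", 2.5, 1.6)),
        _inv("inv_gy_closed", _gy("gy_closed", 0.5, 2)),
        _inv("inv_truss_a", _tr("truss_a", 11, 0.35, 14)),
    ]
    test = [
        _sg("t_sg_a", 2.5, 0.65),
        _sg("t_sg_b", 1.25, 0.55),
        _sg("t_sg_c", 2.5, 1.8),
        _gy("t_gy_a", -0.75, 1),
        _gy("t_gy_b", 0.75, 2),
        _gy("t_gy_c", -0.25, 3),
        _tr("t_truss", 77, 0.4, 12),
        _inv("t_inv", _sg("t_sg_d", 2.5, 0.9)),
    ]
    return train, test


# ---------------------------------------------------------------------------
# STL I/O


def write_stl(mesh: trimesh.Trimesh, path) -> None:
    """Write a watertight mesh as binary STL."""
    if len(mesh.faces) and not mesh.is_watertight:
        raise TopologyError("refusing to write a non-watertight mesh")
    mesh.export(str(path), file_type="stl")


def read_stl(path) -> trimesh.Trimesh:
    """Read an STL file (binary, or ASCII via dialect detection).

    Binary files are validated against the declared triangle count; a
    truncated or malformed file raises :class:`STLFormatError` naming
    the byte offset at which the data ends.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    head = data[:512].lstrip()
    if head.startswith(b"solid") and b"facet" in data[:2048]:
        mesh = trimesh.load(str(path), file_type="stl", process=True)
    else:
        if len(data) < 84:
            raise STLFormatError(
                f"binary STL truncated at byte offset {len(data)}: "
                "80-byte header plus uint32 count requires 84 bytes")
        (n_tri,) = struct.unpack_from("<I", data, 80)
        expected = 84 + 50 * n_tri
        if len(data) != expected:
            raise STLFormatError(
                f"binary STL declares {n_tri} triangles ({expected} bytes) "
                f"but data ends at byte offset {len(data)}")
        mesh = trimesh.load(str(path), file_type="stl", process=True)
    if not isinstance(mesh, trimesh.Trimesh):
        raise STLFormatError(f"{path} did not contain a single triangle mesh")
    return mesh
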