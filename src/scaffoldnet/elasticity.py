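"""Voxel finite-element homogenization of scaffold elastic properties.

Each unit cell is characterized by three geometry-only labels:

* **porosity** — percentage of void voxels in the 5 x 5 x 5 mm^3
  working volume;
* **relative compression modulus** ``e_rel`` — apparent modulus of the
  lattice under uniaxial compression divided by the bulk modulus of the
  raw material, in %;
* **relative shear modulus** ``g_rel`` — apparent shear modulus divided
  by the bulk shear modulus, in %.

The moduli come from a linear-elasticity boundary-value solve on the
binary occupancy grid: material voxels become trilinear (8-node)
hexahedral elements, the face opposite the loaded face is fully
clamped, and a uniform normal (compression) or tangential (shear)
displacement is prescribed on the loaded face.  The apparent stress is
the reaction force over the full 5 x 5 mm^2 section.  Dividing by the
bulk modulus cancels Young's modulus exactly, so the labels depend only
on geometry and the Poisson ratio (default 0.35, a typical thermoplastic
such as ABS).

A force-controlled variant (distributed 25 N load on the top face) is
available; in linear elasticity it defines the same apparent modulus
for the same boundary-condition set, displacement control simply being
the better-conditioned formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .errors import SolverError
from .geometry import CUBE_EDGE_MM

DEFAULT_POISSON = 0.35
DEFAULT_LOAD_N = 25.0
DEFAULT_LABEL_RESOLUTION = (32, 32, 20)


@dataclass(frozen=True)
class PropertyVector:
    """The three regression targets, all on a 0-100 % scale."""

    porosity: float
    e_rel: float
    g_rel: float

    def as_array(self) -> np.ndarray:
        return np.array([self.porosity, self.e_rel, self.g_rel], dtype=float)


@dataclass(frozen=True)
class LoadCase:
    """Boundary-condition set for one apparent-modulus solve."""

    kind: str = "compression"              # or "shear"
    poisson_ratio: float = DEFAULT_POISSON
    control: str = "displacement"          # or "force"
    applied_load: float = DEFAULT_LOAD_N   # N, force control only
    applied_strain: float = 1e-2           # displacement control

    def __post_init__(self):
        if self.kind not in ("compression", "shear"):
            raise ValueError(f"unknown load kind {self.kind!r}")
        if self.control not in ("displacement", "force"):
            raise ValueError(f"unknown control {self.control!r}")
        if not 0.0 <= self.poisson_ratio <= 0.49:
            raise ValueError("poisson_ratio must lie in [0, 0.49]")


class ModulusResult(NamedTuple):
    value: float          # relative modulus, %
    disconnected: bool    # no material load path between the faces
    iterations: int
    residual: float


def porosity(grid: np.ndarray) -> float:
    """Percentage of void voxels in the working volume."""
    g = np.asarray(grid)
    return 100.0 * (1.0 - g.mean())


# ---------------------------------------------------------------------------
# element stiffness

def hex8_stiffness(hx: float, hy: float, hz: float, e: float, nu: float) -> np.ndarray:
    """24x24 stiffness of a trilinear hexahedral box element (2^3 Gauss).

    Local node ``a`` has binary offsets ``(di, dj, dk)`` with
    ``a = di*4 + dj*2 + dk``, matching the voxel-grid node gathering.
    """
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    offs = np.array([[di, dj, dk] for di in (0, 1) for dj in (0, 1) for dk in (0, 1)])
    nat = 2.0 * offs - 1.0  # natural coordinates of the 8 nodes
    g = 1.0 / np.sqrt(3.0)
    ke = np.zeros((24, 24))
    detj = (hx / 2) * (hy / 2) * (hz / 2)
    scale = np.array([2 / hx, 2 / hy, 2 / hz])
    for gx in (-g, g):
        for gy in (-g, g):
            for gz in (-g, g):
                xi = np.array([gx, gy, gz])
                # dN/dxi for each node, then to physical coords
                dN = np.empty((8, 3))
                for a in range(8):
                    na = nat[a]
                    dN[a, 0] = na[0] * (1 + na[1] * xi[1]) * (1 + na[2] * xi[2]) / 8
                    dN[a, 1] = na[1] * (1 + na[0] * xi[0]) * (1 + na[2] * xi[2]) / 8
                    dN[a, 2] = na[2] * (1 + na[0] * xi[0]) * (1 + na[1] * xi[1]) / 8
                dN *= scale
                B = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = dN[a]
                    c = 3 * a
                    B[0, c] = bx
                    B[1, c + 1] = by
                    B[2, c + 2] = bz
                    B[3, c], B[3, c + 1] = by, bx
                    B[4, c + 1], B[4, c + 2] = bz, by
                    B[5, c], B[5, c + 2] = bz, bx
                ke += B.T @ D @ B * detj
    return ke


# ---------------------------------------------------------------------------
# load-path connectivity

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def connected_load_path(grid: np.ndarray) -> np.ndarray:
    """Material voxels belonging to components touching both z faces.

    Returns a masked copy of the grid; voxels with no 6-connected path
    between the fixed (z = 0) and loaded (z = top) faces are removed so
    the stiffness system stays nonsingular.
    """
    g = np.asarray(grid).astype(bool)
    labels, n = ndimage.label(g, structure=_STRUCT6)
    if n == 0:
        return np.zeros_like(g)
    bottom = set(np.unique(labels[:, :, 0])) - {0}
    top = set(np.unique(labels[:, :, -1])) - {0}
    keep = bottom & top
    if not keep:
        return np.zeros_like(g)
    return np.isin(labels, sorted(keep)) & g


def effective_modulus(grid: np.ndarray, case: LoadCase = None,
                      cube_edge: float = CUBE_EDGE_MM,
                      e_bulk: float = 1.0,
                      rtol: float = 1e-8, maxiter: int = 20000) -> ModulusResult:
    """Apparent relative modulus of a binary occupancy grid, in %.

    The bottom face (z = 0) is fully clamped.  Under displacement
    control a uniform displacement is prescribed on the top-face
    material nodes — normal for compression, tangential (+x) for shear —
    and the apparent stress is the reaction over the full cell section.
    Under force control the total ``applied_load`` is distributed over
    the top-face material nodes by tributary area and the apparent
    strain read from their mean displacement.
    """
    case = case or LoadCase()
    g = connected_load_path(grid)
    if not g.any():
        return ModulusResult(0.0, True, 0, 0.0)

    nx, ny, nz = g.shape
    hx, hy, hz = cube_edge / nx, cube_edge / ny, cube_edge / nz
    height = cube_edge
    area = cube_edge * cube_edge
    nu = case.poisson_ratio
    ke = hex8_stiffness(hx, hy, hz, e_bulk, nu)

    nnx, nny, nnz = nx + 1, ny + 1, nz + 1

    def node_id(i, j, k):
        return (i * nny + j) * nnz + k

    els = np.argwhere(g)
    offs = np.array([[di, dj, dk] for di in (0, 1) for dj in (0, 1) for dk in (0, 1)])
    nodes8 = node_id(els[:, 0, None] + offs[None, :, 0],
                     els[:, 1, None] + offs[None, :, 1],
                     els[:, 2, None] + offs[None, :, 2])          # (E, 8)
    edofs = (3 * nodes8[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = np.tile(ke.ravel(), len(els))
    ndof = 3 * nnx * nny * nnz
    K = coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()

    used_nodes = np.unique(nodes8)
    used = np.zeros(ndof, dtype=bool)
    for c in range(3):
        used[3 * used_nodes + c] = True

    kk = used_nodes % nnz
    bottom_nodes = used_nodes[kk == 0]
    top_nodes = used_nodes[kk == nnz - 1]

    u = np.zeros(ndof)
    fixed = np.zeros(ndof, dtype=bool)
    fixed[(3 * bottom_nodes[:, None] + np.arange(3)).ravel()] = True

    tangential = case.kind == "shear"
    comp = 0 if tangential else 2  # prescribed displacement component on top
    top_dofs = 3 * top_nodes + comp

    if case.control == "displacement":
        delta = case.applied_strain * height
        u[top_dofs] = delta if tangential else -delta
        fixed[top_dofs] = True
        f_ext = np.zeros(ndof)
    else:
        # tributary weights: number of adjacent top-layer material voxels
        top_layer = g[:, :, -1]
        w = np.zeros((nnx, nny))
        for di in (0, 1):
            for dj in (0, 1):
                w[di:nx + di, dj:ny + dj] += top_layer
        wn = w.ravel()[top_nodes // nnz]  # node (i, j) index = id // nnz
        wn = wn / wn.sum()
        f_ext = np.zeros(ndof)
        sign = 1.0 if tangential else -1.0
        f_ext[top_dofs] = sign * case.applied_load * wn

    free = used & ~fixed
    Kff = K[free][:, free]
    rhs = f_ext[free] - K[free][:, fixed] @ u[fixed]
    diag = np.asarray(Kff.diagonal())
    diag[diag <= 0] = 1.0
    M = LinearOperator(Kff.shape, matvec=lambda v: v / diag)
    it_count = [0]

    def _cb(_):
        it_count[0] += 1

    uf, info = cg(Kff, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=M, callback=_cb)
    if info != 0:
        res = float(np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-30))
        raise SolverError(
            f"conjugate gradients did not converge ({it_count[0]} iterations, "
            f"relative residual {res:.3e})")
    u[free] = uf
    residual = float(np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-30))

    if case.control == "displacement":
        reactions = K @ u
        force = abs(float(reactions[top_dofs].sum()))
        strain = case.applied_strain
    else:
        wn_full = np.zeros(ndof)
        wn_full[top_dofs] = wn
        mean_disp = abs(float(u[top_dofs] @ wn))
        strain = mean_disp / height
        force = case.applied_load
        if strain <= 0:
            return ModulusResult(0.0, False, it_count[0], residual)

    stress = force / area
    apparent = stress / strain
    if tangential:
        bulk = e_bulk / (2.0 * (1.0 + nu))
    else:
        bulk = e_bulk
    return ModulusResult(100.0 * apparent / bulk, False, it_count[0], residual)


def characterize(mesh, resolution=DEFAULT_LABEL_RESOLUTION,
                 poisson_ratio: float = DEFAULT_POISSON,
                 control: str = "displacement",
                 cube_edge: float = CUBE_EDGE_MM) -> PropertyVector:
    """Porosity and both relative moduli of a unit-cell mesh.

    The mesh is sliced at the characterization resolution (which may
    differ from the CNN input resolution) and the labels computed on
    the resulting occupancy grid.  Deterministic for a given mesh and
    configuration.
    """
    from .tomography import slice_mesh, stack_to_grid

    nx, ny, nz = resolution
    if nx != ny:
        raise ValueError("lateral resolution must be square")
    stack = slice_mesh(mesh, n_slices=nz, spacing=cube_edge / nz, resolution=nx,
                       cube_edge=cube_edge)
    grid = stack_to_grid(stack)
    return characterize_grid(grid, poisson_ratio=poisson_ratio, control=control,
                             cube_edge=cube_edge)


def characterize_grid(grid: np.ndarray,
                      poisson_ratio: float = DEFAULT_POISSON,
                      control: str = "displacement",
                      cube_edge: float = CUBE_EDGE_MM) -> PropertyVector:
    """Labels straight from an occupancy grid (no slicing step)."""
    por = porosity(grid)
    e = effective_modulus(grid, LoadCase("compression", poisson_ratio, control),
                          cube_edge=cube_edge)
    s = effective_modulus(grid, LoadCase("shear", poisson_ratio, control),
                          cube_edge=cube_edge)
    return PropertyVector(por, e.value, s.value)
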