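"""Structured hexahedral meshes for the thin bonded substrate layer.

Meshes are tensor-product grids over x, y, z coordinate vectors with z in
[0, h]; the top surface (z = h) carries the measurement lattice, the bottom
(z = 0) is bonded to the rigid backing.  Node (i, j, k) has id
i + j*(nx+1) + k*(nx+1)*(ny+1); elements use VTK hexahedron ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshingError(ValueError):
    pass


@dataclass
class HexMesh:
    nodes: np.ndarray                 # (Nn, 3) coordinates, mm
    elems: np.ndarray                 # (Ne, 8) connectivity
    node_sets: dict = field(default_factory=dict)
    xs: np.ndarray | None = None      # 1D grid coordinate vectors
    ys: np.ndarray | None = None
    zs: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def thickness(self) -> float:
        return float(self.zs[-1])

    @property
    def spacing(self) -> float | None:
        """Uniform in-plane spacing, or None for graded grids."""
        dx = np.diff(self.xs)
        dy = np.diff(self.ys)
        if np.allclose(dx, dx[0], rtol=1e-9) and np.allclose(dy, dx[0], rtol=1e-9):
            return float(dx[0])
        return None

    def top_nodes_grid(self):
        """Top-surface node ids arranged on the (ny+1, nx+1) lattice."""
        nx1, ny1 = len(self.xs), len(self.ys)
        k = len(self.zs) - 1
        ids = np.arange(nx1 * ny1) + k * nx1 * ny1
        return ids.reshape(ny1, nx1)

    def nodal_areas_top(self) -> np.ndarray:
        """Tributary area (mm^2) of each top-surface node, lattice-shaped."""
        def trib(c):
            d = np.diff(c)
            t = np.empty(len(c))
            t[0], t[-1] = d[0] / 2, d[-1] / 2
            t[1:-1] = (d[:-1] + d[1:]) / 2
            return t
        return np.outer(trib(self.ys), trib(self.xs))


def mesh_from_coords(xs, ys, zs) -> HexMesh:
    """Tensor-product hexahedral mesh from strictly increasing coordinate vectors."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    for name, c in (("x", xs), ("y", ys), ("z", zs)):
        if c.size < 2 or np.any(np.diff(c) <= 0):
            raise MeshingError(f"{name} coordinates must be strictly increasing, >= 2 values")
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # node id = i + j*(nx+1) + k*(nx+1)*(ny+1)
    nodes = np.stack([X.transpose(2, 1, 0).ravel(),
                      Y.transpose(2, 1, 0).ravel(),
                      Z.transpose(2, 1, 0).ravel()], axis=1)

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()

    def nid(ii, jj, kk):
        return ii + jj * (nx + 1) + kk * (nx + 1) * (ny + 1)

    elems = np.stack([
        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
    ], axis=1).astype(np.int64)

    ids = np.arange(nodes.shape[0])
    kidx = ids // ((nx + 1) * (ny + 1))
    rem = ids % ((nx + 1) * (ny + 1))
    jidx = rem // (nx + 1)
    iidx = rem % (nx + 1)
    sets = {
        "bottom": ids[kidx == 0],
        "top": ids[kidx == nz],
        "lateral": ids[(iidx == 0) | (iidx == nx) | (jidx == 0) | (jidx == ny)],
        "x_faces": ids[(iidx == 0) | (iidx == nx)],
        "y_faces": ids[(jidx == 0) | (jidx == ny)],
    }
    return HexMesh(nodes=nodes, elems=elems, node_sets=sets, xs=xs, ys=ys, zs=zs)


def build_grid_mesh(lx: float, ly: float, h: float, spacing: float, nz: int = 3,
                    origin=(0.0, 0.0)) -> HexMesh:
    """Uniform grid mesh whose top-surface (x, y) lattice matches a DIC subset grid.

    ``lx``/``ly`` must be integer multiples of ``spacing`` (the DIC subset
    interval times the pixel scale, 0.15 mm in the reference setup).
    """
    if nz < 1:
        raise MeshingError("nz must be >= 1")
    nx, ny = lx / spacing, ly / spacing
    if abs(nx - round(nx)) > 1e-6 * nx or abs(ny - round(ny)) > 1e-6 * ny:
        raise MeshingError(f"lx={lx}, ly={ly} are not multiples of spacing={spacing}")
    nx, ny = int(round(nx)), int(round(ny))
    xs = origin[0] + spacing * np.arange(nx + 1)
    ys = origin[1] + spacing * np.arange(ny + 1)
    zs = np.linspace(0.0, h, nz + 1)
    return mesh_from_coords(xs, ys, zs)


def build_graded_mesh(core_halfwidth: float, extent_halfwidth: float, spacing: float,
                      h: float, nz: int = 3, growth: float = 1.35) -> HexMesh:
    """Centred mesh with a uniform fine core and geometrically graded margins.

    The core (|x|, |y| <= core_halfwidth) keeps the DIC lattice spacing so
    nodal quantities there are directly comparable with uniform-grid runs;
    outside, element size grows by ``growth`` per ring until the lateral
    extent reaches ``extent_halfwidth``.
    """
    n_core = int(round(core_halfwidth / spacing))
    if abs(n_core * spacing - core_halfwidth) > 1e-9:
        raise MeshingError("core_halfwidth must be a multiple of spacing")
    pos = [spacing * i for i in range(n_core + 1)]
    d = spacing
    while pos[-1] < extent_halfwidth:
        d *= growth
        pos.append(min(pos[-1] + d, extent_halfwidth) if pos[-1] + d > extent_halfwidth * 0.995
                   else pos[-1] + d)
        if pos[-1] >= extent_halfwidth * 0.995:
            pos[-1] = extent_halfwidth
            break
    half = np.asarray(pos)
    xs = np.concatenate([-half[::-1], half[1:]])
    zs = np.linspace(0.0, h, nz + 1)
    return mesh_from_coords(xs, xs.copy(), zs)


def element_jacobians_positive(mesh: HexMesh) -> bool:
    """True if every element has positive Jacobian at all Gauss points."""
    from .fe import precompute
    pre = precompute(mesh)
    return bool(np.all(pre.wdet > 0))


def write_vtk(path, mesh: HexMesh, point_data: dict | None = None) -> None:
    """Write mesh plus nodal vector/scalar fields as legacy ASCII VTK."""
    n, e = mesh.n_nodes, mesh.n_elems
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntfm3d unstructured grid\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {e} {9 * e}\n")
        np.savetxt(f, np.column_stack([np.full(e, 8), mesh.elems]), fmt="%d")
        f.write(f"CELL_TYPES {e}\n")
        np.savetxt(f, np.full(e, 12), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr.reshape(-1, 1), fmt="%.9g")
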