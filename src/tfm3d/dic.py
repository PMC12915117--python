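"""Ingestion and conditioning of subset-grid displacement fields.

Stereo-DIC software tracks square pixel subsets on a regular lattice (subset
interval L_i pixels apart) and reports, per subset centre, its coordinates
and 3D displacement vector.  This module reads such delimited-text tables,
validates the lattice, optionally smooths the fields, and maps subset
centres one-to-one onto the finite-element top-surface nodes — the FE grid
is built to coincide with the measurement lattice, so no interpolation is
ever applied.

Canonical column names: subset_id, x, y, z, u, v, w (a dialect option
accepts the uppercase DIC-software-style variants).  Internal units are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .fe import DirichletBC, fix_bottom
from .mesh import HexMesh


class FormatError(ValueError):
    pass


class MappingError(ValueError):
    pass


_COLUMN_ALIASES = {
    "subset_id": {"subset_id", "id", "point_id", "subset"},
    "x": {"x", "coordinate_x", "model_x"},
    "y": {"y", "coordinate_y", "model_y"},
    "z": {"z", "coordinate_z", "model_z"},
    "u": {"u", "displacement_x", "disp_x", "ux"},
    "v": {"v", "displacement_y", "disp_y", "uy"},
    "w": {"w", "displacement_z", "disp_z", "uz"},
    "valid": {"valid", "sigma", "status", "gamma"},
}


@dataclass
class DisplacementGrid:
    """Regular in-plane lattice of 3D surface displacement vectors (mm).

    ``u``, ``v``, ``w`` and ``mask`` are (ny, nx) arrays over the lattice
    ``y`` (rows) x ``x`` (columns); ``mask`` marks subsets with a valid
    measurement.
    """

    x: np.ndarray            # (nx,) lattice coordinates, mm
    y: np.ndarray            # (ny,)
    u: np.ndarray            # (ny, nx) displacement components, mm
    v: np.ndarray
    w: np.ndarray
    mask: np.ndarray = None  # (ny, nx) bool
    z: np.ndarray | None = None          # optional out-of-plane subset coordinate
    pixel_scale: float | None = None     # mm per pixel
    subset_size: int | None = None       # L_s, px
    subset_interval: int | None = None   # L_i, px

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        for name in ("u", "v", "w"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.mask is None:
            self.mask = np.ones((len(self.y), len(self.x)), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (len(self.y), len(self.x))
        for name in ("u", "v", "w", "mask"):
            if getattr(self, name).shape != shape:
                raise FormatError(f"{name} must have lattice shape {shape}")
        self._check_lattice()
        if not np.all(np.isfinite(np.stack([self.u, self.v, self.w])[:, self.mask])):
            raise FormatError("non-finite displacements inside the valid mask")

    def _check_lattice(self):
        for name, c in (("x", self.x), ("y", self.y)):
            d = np.diff(c)
            if len(d) == 0 or np.any(d <= 0):
                raise FormatError(f"{name} lattice must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-4, atol=1e-9):
                raise FormatError(f"irregular {name} lattice spacing")
        if not np.isclose(np.diff(self.x)[0], np.diff(self.y)[0], rtol=1e-4):
            raise FormatError("x and y lattice spacings differ")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self):
        return self.mask.shape

    def displacements(self) -> np.ndarray:
        """(ny, nx, 3) stacked displacement field."""
        return np.stack([self.u, self.v, self.w], axis=-1)


def read_dic_table(path, units: str = "mm", pixel_scale: float | None = None,
                   dialect: str = "auto") -> DisplacementGrid:
    """Read a delimited displacement table into a validated grid.

    ``units``: 'mm' or 'px'; pixel-unit files need ``pixel_scale`` (mm/px).
    Comma- or whitespace-delimited with a header; canonical or uppercase
    DIC-style column names.
    """
    with open(path) as fh:
        header = next((ln for ln in fh if ln.strip() and not ln.startswith("#")), "")
    sep = "," if "," in header else r"\s+"
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    cols = {}
    for raw in df.columns:
        key = str(raw).strip().lower()
        for canon, aliases in _COLUMN_ALIASES.items():
            if key in aliases:
                cols[canon] = raw
    missing = {"x", "y", "u", "v", "w"} - set(cols)
    if missing:
        raise FormatError(
            f"{path}: missing columns {sorted(missing)}; accepted names: "
            + "; ".join(f"{k}: {sorted(v)}" for k, v in _COLUMN_ALIASES.items()))
    if units == "px":
        if pixel_scale is None:
            raise FormatError("pixel-unit files require pixel_scale (mm/px)")
        scale = pixel_scale
    elif units == "mm":
        scale = 1.0
    else:
        raise FormatError(f"unknown units {units!r} (use 'mm' or 'px')")

    xs = np.unique(np.round(df[cols["x"]].to_numpy() * scale, 9))
    ys = np.unique(np.round(df[cols["y"]].to_numpy() * scale, 9))
    nx, ny = len(xs), len(ys)
    if nx * ny < len(df):
        raise FormatError(f"{path}: duplicate subset centres")

    def grid_index(vals, lattice):
        idx = np.searchsorted(lattice, vals)
        idx = np.clip(idx, 0, len(lattice) - 1)
        left = np.clip(idx - 1, 0, len(lattice) - 1)
        idx = np.where(np.abs(vals - lattice[left]) < np.abs(vals - lattice[idx]), left, idx)
        if np.any(np.abs(lattice[idx] - vals) > 1e-6 * max(lattice[-1] - lattice[0], 1.0)):
            raise FormatError(f"{path}: points off the inferred lattice")
        return idx

    ix = grid_index(np.round(df[cols["x"]].to_numpy() * scale, 9), xs)
    iy = grid_index(np.round(df[cols["y"]].to_numpy() * scale, 9), ys)

    comp = {}
    mask = np.zeros((ny, nx), dtype=bool)
    for name in ("u", "v", "w"):
        arr = np.full((ny, nx), np.nan)
        arr[iy, ix] = df[cols[name]].to_numpy() * scale
        comp[name] = arr
    mask[iy, ix] = True
    if "valid" in cols:
        vcol = df[cols["valid"]].to_numpy()
        mask[iy, ix] &= np.isfinite(vcol) & (vcol >= 0)
    mask &= np.all(np.isfinite(np.stack(list(comp.values()))), axis=0)
    for name in comp:
        comp[name] = np.where(mask, comp[name], 0.0)
    z = None
    if "z" in cols:
        z = np.full((ny, nx), np.nan)
        z[iy, ix] = df[cols["z"]].to_numpy() * scale
    return DisplacementGrid(x=xs, y=ys, mask=mask, z=z, **comp)


def write_dic_table(grid: DisplacementGrid, path, delimiter: str = ",") -> None:
    """Write a grid back to the canonical delimited format (masked points only)."""
    iy, ix = np.nonzero(grid.mask)
    df = pd.DataFrame({
        "subset_id": np.arange(len(ix)),
        "x": grid.x[ix],
        "y": grid.y[iy],
        "u": grid.u[iy, ix],
        "v": grid.v[iy, ix],
        "w": grid.w[iy, ix],
    })
    if grid.z is not None:
        df.insert(3, "z", grid.z[iy, ix])
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def smooth_grid(grid: DisplacementGrid, method: str = "gaussian",
                size: float = 1.0) -> DisplacementGrid:
    """Spatially filter the displacement components on the lattice.

    ``method``: 'none' (identity), 'gaussian' (std = ``size`` lattice steps,
    mask-normalised so holes do not bleed zeros), or 'median' (window of
    ``2*size+1`` steps).  Lattice and mask are never altered.
    """
    if method == "none":
        return grid
    out = {}
    m = grid.mask.astype(float)
    for name in ("u", "v", "w"):
        f = getattr(grid, name)
        if method == "gaussian":
            num = ndimage.gaussian_filter(f * m, sigma=size, mode="nearest")
            den = ndimage.gaussian_filter(m, sigma=size, mode="nearest")
            sm = np.where(grid.mask, num / np.maximum(den, 1e-12), 0.0)
        elif method == "median":
            k = 2 * int(round(size)) + 1
            sm = np.where(grid.mask, ndimage.median_filter(f, size=k, mode="nearest"), 0.0)
        else:
            raise ValueError(f"unknown smoothing method {method!r}")
        out[name] = sm
    return dc_replace(grid, u=out["u"], v=out["v"], w=out["w"])


@dataclass
class MappedBC:
    """Dirichlet boundary conditions for the FE top surface plus the
    subset-to-node correspondence table."""

    bc: DirichletBC
    node_ids: np.ndarray       # constrained top-surface node ids
    subset_index: np.ndarray   # (n, 2) (iy, ix) lattice index per node


def map_to_bc(grid: DisplacementGrid, mesh: HexMesh, fix_base: bool = True) -> MappedBC:
    """Assign each masked subset-centre displacement to the coincident top node.

    The mesh top lattice must be congruent with the measurement lattice
    (same spacing, node positions within 1e-6 of subset centres) — the
    mapping is a pure re-indexing, displacement values are untouched.
    Unmasked top nodes stay unconstrained; the bottom face is fixed when
    ``fix_base`` (every inversion requires it).
    """
    top = mesh.top_nodes_grid()
    ny, nx = top.shape
    if (ny, nx) != grid.shape:
        raise MappingError(f"lattice shape mismatch: mesh top {ny}x{nx} vs grid {grid.shape}")
    tol = 1e-6 * grid.spacing
    dx = np.abs(mesh.xs - grid.x).max()
    dy = np.abs(mesh.ys - grid.y).max()
    if dx > tol or dy > tol:
        raise MappingError(f"lattice offset: max |dx|={dx:.3e} mm, |dy|={dy:.3e} mm")
    bc = fix_bottom(mesh) if fix_base else DirichletBC(mesh.n_nodes)
    iy, ix = np.nonzero(grid.mask)
    ids = top[iy, ix]
    disp = np.stack([grid.u[iy, ix], grid.v[iy, ix], grid.w[iy, ix]], axis=1)
    bc.prescribe(ids, disp)
    return MappedBC(bc=bc, node_ids=ids, subset_index=np.stack([iy, ix], axis=1))


def write_vtk_points(path, x, y, vectors: dict, z=None) -> None:
    """Write a lattice of points with named vector fields as legacy ASCII VTK.

    ``vectors`` maps field names to (ny, nx, 3) arrays on the x/y lattice;
    useful for inspecting displacement grids and traction maps in ParaView.
    """
    X, Y = np.meshgrid(np.asarray(x), np.asarray(y))
    Z = np.zeros_like(X) if z is None else np.asarray(z)
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    n = len(pts)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntfm3d point lattice\nASCII\n")
        f.write(f"DATASET POLYDATA\nPOINTS {n} double\n")
        np.savetxt(f, pts, fmt="%.9g")
        f.write(f"POINT_DATA {n}\n")
        for name, arr in vectors.items():
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, np.asarray(arr).reshape(-1, 3), fmt="%.9g")


def savgol_smooth_curve(series, window: int = 1501, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing for force-extension curves.

    The default window (1501 points, cubic) suits load-cell traces sampled
    at tens of Hz over minutes; short series fall back to the largest valid
    odd window.
    """
    y = np.asarray(series, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    n = len(y)
    if n <= polyorder + 1:
        return y.copy()
    if window > n:
        window = n if n % 2 == 1 else n - 1
        if window <= polyorder:
            return y.copy()
    return signal.savgol_filter(y, window_length=window, polyorder=polyorder)
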