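"""Displacement-to-traction inversion and downstream analyses.

The core operation maps a measured surface-displacement grid onto the
coincident top nodes of a substrate FE model, solves the resulting
Dirichlet problem, and reads the interfacial traction map off the nodal
reaction forces — the discrete forces conjugate to the prescribed
displacements.  Summed over the interface these give the resultant traction
force RF = (RF_X, RF_Y, RF_Z), its magnitude and its elevation angle above
the substrate plane, the quantities reported for the experiments.

Also here: cross-section profiles through the traction map, stiffness
(E, nu) sensitivity sweeps against a known applied force, and
hyperelastic-vs-linear constitutive comparisons on identical boundary
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fe
from .dic import DisplacementGrid, MappedBC, map_to_bc, smooth_grid
from .materials import LinearElasticMaterial, OgdenMaterial, linear_equivalent
from .mesh import HexMesh, mesh_from_coords

#: lattice spacing (mm) at which nodal force peaks are comparable across runs
REFERENCE_SPACING = 0.15


@dataclass
class TractionMap:
    """Per-top-node interfacial force vectors and their resultants.

    Forces follow the convention "exerted by the adherend on the substrate";
    nodal values are discretisation-dependent and comparable only at equal
    lattice spacing (a warning flag is set away from the 0.15 mm reference).
    """

    coords: np.ndarray       # (n, 2) node x, y (mm)
    forces: np.ndarray       # (n, 3) N
    lattice_shape: tuple     # (ny, nx)
    x: np.ndarray
    y: np.ndarray
    spacing: float
    meta: dict = field(default_factory=dict)

    @property
    def resultant(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.resultant))

    @property
    def direction_deg(self) -> float:
        return resultant_direction(self.resultant)

    @property
    def peak_force(self) -> float:
        """Largest nodal force magnitude (N)."""
        return float(np.linalg.norm(self.forces, axis=1).max())

    def force_grid(self) -> np.ndarray:
        """(ny, nx, 3) nodal forces on the lattice."""
        return self.forces.reshape(self.lattice_shape + (3,))


def resultant_magnitude(components) -> float:
    """Euclidean norm of the resultant components, reported to 3 decimals."""
    return round(float(np.linalg.norm(np.asarray(components, dtype=float))), 3)


def resultant_direction(components) -> float:
    """Elevation angle (deg) of the resultant above the substrate plane.

    angle = arctan(|RF_Z| / sqrt(RF_X^2 + RF_Y^2)), in [0, 90], rounded to
    whole degrees as reported for the stage-point tables.
    """
    c = np.asarray(components, dtype=float)
    rf_xy = float(np.hypot(c[0], c[1]))
    if rf_xy == 0.0 and c[2] == 0.0:
        raise ValueError("direction undefined for a zero resultant")
    return round(float(np.degrees(np.arctan2(abs(c[2]), rf_xy))))


def deviation(rf: float, af: float) -> float:
    """Relative deviation |RF - AF| / AF x 100 (percent)."""
    if af <= 0:
        raise ValueError("applied force AF must be positive")
    return abs(rf - af) / af * 100.0


def invert(grid: DisplacementGrid, material, h: float, nz: int = 3,
           smoothing: str = "none", smoothing_size: float = 1.0,
           options: fe.SolverOptions | None = None) -> TractionMap:
    """Invert a displacement grid into an interfacial traction map.

    Builds the substrate mesh congruent with the measurement lattice
    (top nodes exactly on subset centres), prescribes the masked
    displacements, solves, and extracts top-surface reactions.
    """
    if smoothing != "none":
        grid = smooth_grid(grid, method=smoothing, size=smoothing_size)
    mesh = mesh_from_coords(grid.x, grid.y, np.linspace(0.0, h, nz + 1))
    mapped = map_to_bc(grid, mesh)
    result = fe.solve_dirichlet(mesh, material, mapped.bc, options=options)
    top, forces = fe.extract_top_reactions(result, mesh)
    spacing = grid.spacing
    meta = {
        "material": repr(material),
        "h_mm": h, "nz": nz, "smoothing": smoothing,
        "peak_principal_strain": result.peak_principal_strain,
        "nonreference_spacing_warning": not np.isclose(spacing, REFERENCE_SPACING),
    }
    return TractionMap(coords=mesh.nodes[top][:, :2], forces=forces,
                       lattice_shape=grid.shape, x=grid.x, y=grid.y,
                       spacing=spacing, meta=meta)


@dataclass
class Profile:
    """Ordered nodal tractions along an X-Z or Y-Z cut through the map."""

    axis: str                # 'x' (cut along x at fixed y) or 'y'
    coord: float             # the fixed coordinate of the cut (mm)
    positions: np.ndarray    # (n,) along-cut coordinates
    forces: np.ndarray       # (n, 3)

    @property
    def in_plane(self) -> np.ndarray:
        return self.forces[:, 0] if self.axis == "x" else self.forces[:, 1]

    @property
    def out_of_plane(self) -> np.ndarray:
        return self.forces[:, 2]


def cross_section_profile(tmap: TractionMap, axis: str = "x",
                          coord: float = 0.0) -> Profile:
    """Traction vectors along a lattice line (X-Z or Y-Z plane cut)."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    fixed = tmap.y if axis == "x" else tmap.x
    k = int(np.argmin(np.abs(fixed - coord)))
    if abs(fixed[k] - coord) > 0.5 * tmap.spacing + 1e-9:
        raise ValueError(f"cut at {axis}={coord} mm lies outside the lattice")
    fg = tmap.force_grid()
    forces = fg[k, :, :] if axis == "x" else fg[:, k, :]
    positions = tmap.x if axis == "x" else tmap.y
    return Profile(axis=axis, coord=float(fixed[k]), positions=positions,
                   forces=forces)


@dataclass
class SensitivityReport:
    """Traction-map summaries over a stiffness-parameter grid."""

    rows: list               # dicts: E, nu, model, RF components, RF, deviation %, angle
    applied_force: float

    def as_table(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


def sensitivity_sweep(grid: DisplacementGrid, applied_force: float, h: float,
                      materials: list, nz: int = 3) -> SensitivityReport:
    """Re-invert one grid under each candidate material; report deviations.

    ``materials`` is a list of Ogden or linear-elastic materials (e.g. the
    same G0 at several Poisson ratios); deviation = |RF - AF|/AF x 100
    against the known applied force.
    """
    rows = []
    for mat in materials:
        tmap = invert(grid, mat, h=h, nz=nz)
        rf = tmap.resultant
        if isinstance(mat, LinearElasticMaterial):
            E, nu, model = mat.E, mat.nu, "linear"
        else:
            E, nu, model = mat.youngs_modulus, mat.poisson, "ogden"
        rows.append({
            "E_MPa": E, "nu": nu, "model": model,
            "RF_X": rf[0], "RF_Y": rf[1], "RF_Z": rf[2],
            "RF": tmap.magnitude,
            "deviation_pct": deviation(tmap.magnitude, applied_force),
            "direction_deg": tmap.direction_deg,
            "peak_force_N": tmap.peak_force,
        })
    return SensitivityReport(rows=rows, applied_force=applied_force)


@dataclass
class ModelComparison:
    """Hyperelastic vs linear-elastic inversion of the same grid."""

    hyper: TractionMap
    linear: TractionMap
    peak_strain: float                  # max principal nominal strain (hyperelastic solve)

    @property
    def local_deviation(self) -> np.ndarray:
        """(F_hyper - F_linear)/F_linear per node, on nodes with measurable force."""
        fh = np.linalg.norm(self.hyper.forces, axis=1)
        fl = np.linalg.norm(self.linear.forces, axis=1)
        floor = 1e-3 * max(fl.max(), 1e-30)
        valid = fl > floor
        out = np.full_like(fh, np.nan)
        out[valid] = (fh[valid] - fl[valid]) / fl[valid]
        return out

    @property
    def resultant_rel_diff(self) -> float:
        """(RF_linear - RF_hyper)/RF_hyper — negative when the linear model
        under-reads the traction."""
        return (self.linear.magnitude - self.hyper.magnitude) / self.hyper.magnitude


def compare_constitutive(grid: DisplacementGrid, ogden: OgdenMaterial, h: float,
                         linear: LinearElasticMaterial | None = None,
                         nz: int = 3) -> ModelComparison:
    """Invert one grid with both constitutive models on identical BCs.

    The linear model defaults to the Ogden model's derived (E, nu) so the
    comparison isolates constitutive nonlinearity.
    """
    linear = linear or linear_equivalent(ogden)
    tm_h = invert(grid, ogden, h=h, nz=nz)
    tm_l = invert(grid, linear, h=h, nz=nz)
    return ModelComparison(hyper=tm_h, linear=tm_l,
                           peak_strain=tm_h.meta["peak_principal_strain"])


def traction_map_to_csv(tmap: TractionMap, path) -> None:
    """Write the nodal traction map as CSV (node, x, y, fx, fy, fz)."""
    import pandas as pd
    df = pd.DataFrame({
        "node": np.arange(len(tmap.forces)),
        "x_mm": tmap.coords[:, 0], "y_mm": tmap.coords[:, 1],
        "fx_N": tmap.forces[:, 0], "fy_N": tmap.forces[:, 1],
        "fz_N": tmap.forces[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.10g")
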