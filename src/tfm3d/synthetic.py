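"""Synthetic DIC-format displacement fields with exactly known ground truth.

Two forward scenarios emulate the physical experiments end to end:

* ``sphere_indent`` — a rigid steel ball resting on the substrate under its
  own (optionally buoyancy-reduced) weight, solved with frictionless
  contact; the benchmark validation case.
* ``plaque_pull`` — a shear-dominated traction distribution over an
  elliptical adhesive footprint pulled at a shallow angle, mimicking a
  mussel plaque loaded through its thread.

Fields are forward FE solutions sampled at the DIC subset-centre lattice
(exact nodal values, no interpolation), so the discrete resultant acting on
the substrate is known exactly and the whole inverse pipeline can be tested
against it.  Measurement noise is added as i.i.d. per-axis Gaussian
perturbations, seeded for bit-reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import fe
from .dic import DisplacementGrid
from .materials import AVERAGE_PDMS
from .mesh import build_graded_mesh, build_grid_mesh

GRAVITY = 9.81          # m/s^2
WATER_DENSITY = 1000.0  # kg/m^3


def ball_weight(mass_g: float) -> float:
    """Gravitational force (N) of a ball of the given mass in grams."""
    return mass_g * 1e-3 * GRAVITY


def buoyant_force(diameter_mm: float, rho: float = WATER_DENSITY) -> float:
    """Buoyant force (N) on a fully immersed sphere."""
    r_m = diameter_mm * 1e-3 / 2.0
    return rho * (4.0 / 3.0) * np.pi * r_m**3 * GRAVITY


def submerged_net_force(mass_g: float, diameter_mm: float,
                        rho: float = WATER_DENSITY) -> float:
    """Net downward force (N) of an immersed ball: weight minus buoyancy."""
    return ball_weight(mass_g) - buoyant_force(diameter_mm, rho)


@dataclass
class SyntheticScenario:
    """Configuration of a forward-simulated measurement.

    Defaults reproduce the reference experimental conditions: 0.3 mm
    substrate with the batch-average Ogden model, 0.15 mm DIC lattice,
    a 17 mm steel ball (20.6 g) for indentation, and a 2.8 x 2.0 mm
    elliptical plaque pulled at 15 degrees with up to 0.19 N.
    """

    kind: str = "sphere_indent"
    material: object = AVERAGE_PDMS
    h: float = 0.3                   # substrate thickness, mm
    spacing: float = 0.15            # DIC lattice spacing, mm
    nz: int = 3
    seed: int = 0
    noise_std_um: float | tuple = 0.0

    # sphere_indent parameters
    sphere_radius: float = 8.5       # mm
    net_force: float = ball_weight(20.6)          # N
    window_halfwidth: float = 2.4    # sampled (uniform) lattice half-extent, mm
    extent_halfwidth: float = 10.0   # forward-domain half-extent, mm

    # plaque_pull parameters
    ellipse_axes: tuple = (2.8, 2.0)  # full axis lengths, mm
    pull_angle_deg: float = 15.0      # elevation of the resultant above the plane
    pull_magnitude: float = 0.19      # N
    domain_halfwidth: float = 3.0     # uniform mesh half-extent, mm
    moment_lever: float = 0.5         # height (mm) of the pull above the interface

    def __post_init__(self):
        if self.kind not in ("sphere_indent", "plaque_pull"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        std = np.broadcast_to(np.asarray(self.noise_std_um, dtype=float), (3,))
        if np.any(std < 0):
            raise ValueError("noise std must be non-negative")


@dataclass
class GroundTruth:
    """Exact loading behind a synthetic dataset (stored alongside it)."""

    resultant: np.ndarray            # (3,) applied force on the substrate, N
    tractions: np.ndarray            # (ny, nx, 3) true nodal forces on the lattice, N
    displacements: np.ndarray        # (ny, nx, 3) noise-free field, mm
    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.resultant))

    def to_json(self, path) -> None:
        payload = {
            "resultant_N": list(map(float, self.resultant)),
            "x_mm": self.x.tolist(),
            "y_mm": self.y.tolist(),
            "tractions_N": self.tractions.tolist(),
            "displacements_mm": self.displacements.tolist(),
            "meta": self.meta,
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            d = json.load(f)
        return cls(resultant=np.array(d["resultant_N"]),
                   tractions=np.array(d["tractions_N"]),
                   displacements=np.array(d["displacements_mm"]),
                   x=np.array(d["x_mm"]), y=np.array(d["y_mm"]),
                   meta=d.get("meta", {}))


def _sample_window(mesh, values, halfwidth):
    """Restrict a top-lattice field to the uniform |x|,|y| <= halfwidth window."""
    keep_x = np.abs(mesh.xs) <= halfwidth + 1e-9
    keep_y = np.abs(mesh.ys) <= halfwidth + 1e-9
    return values[np.ix_(keep_y, keep_x)], mesh.xs[keep_x], mesh.ys[keep_y]


def gen_sphere_indent(scenario: SyntheticScenario):
    """Forward frictionless sphere indentation sampled as a DIC grid.

    Returns ``(DisplacementGrid, GroundTruth)``; the grid carries noise if
    the scenario requests it, the ground truth never does.
    """
    sc = scenario
    if sc.kind != "sphere_indent":
        raise ValueError("scenario kind must be 'sphere_indent'")
    if sc.extent_halfwidth > sc.window_halfwidth + 1e-9:
        mesh = build_graded_mesh(sc.window_halfwidth, sc.extent_halfwidth,
                                 sc.spacing, sc.h, nz=sc.nz)
    else:
        w = 2.0 * sc.window_halfwidth
        mesh = build_grid_mesh(w, w, sc.h, sc.spacing, nz=sc.nz,
                               origin=(-sc.window_halfwidth, -sc.window_halfwidth))
    sphere = fe.RigidSphere(radius=sc.sphere_radius)
    res = fe.solve_sphere_indentation(mesh, sc.material, sphere, sc.net_force)

    top = mesh.top_nodes_grid()
    disp = res.u[top]                       # (ny, nx, 3)
    forces = res.contact.forces[top]        # contact force on substrate per node
    disp_w, xs, ys = _sample_window(mesh, disp, sc.window_halfwidth)
    forces_w, _, _ = _sample_window(mesh, forces, sc.window_halfwidth)

    # the exact discrete resultant is the summed contact force actually applied
    truth = GroundTruth(
        resultant=res.contact.forces.sum(axis=0),
        tractions=forces_w, displacements=disp_w, x=xs, y=ys,
        meta={"kind": sc.kind, "net_force_N": sc.net_force,
              "penetration_depth_mm": res.contact.penetration_depth,
              "patch_radius_mm": res.contact.patch_radius,
              "peak_principal_strain": res.peak_principal_strain},
    )
    grid = DisplacementGrid(x=xs, y=ys, u=disp_w[..., 0], v=disp_w[..., 1],
                            w=disp_w[..., 2])
    grid = add_noise(grid, sc.noise_std_um, sc.seed)
    return grid, truth


def plaque_traction_field(mesh, axes, angle_deg, magnitude, moment_lever=1.0):
    """Nodal force distribution of the plaque scenario on the mesh top lattice.

    A smooth paraboloid weight, zero at the elliptical rim (avoiding
    mesh-dependent edge singularities), carries a uniform pull direction
    (-cos(angle), 0, sin(angle)): shear-dominated toward -X with a small
    upward normal component, as in a thread pulled at a shallow angle.
    Because the pull acts ``moment_lever`` mm above the interface, the shear
    resultant also transfers a tilting moment, carried by a linearly varying
    normal traction: uplift (tension) on the trailing +X side, push-down
    (compression) on the leading -X side.  Returns (ny, nx, 3) nodal forces
    summing exactly to the resultant (the moment term is self-equilibrating
    in force).
    """
    a, b = axes[0] / 2.0, axes[1] / 2.0
    ang = np.deg2rad(angle_deg)
    direction = np.array([-np.cos(ang), 0.0, np.sin(ang)])
    X, Y = np.meshgrid(mesh.xs, mesh.ys)
    r2 = (X / a) ** 2 + (Y / b) ** 2
    weight = np.where(r2 < 1.0, 1.0 - r2, 0.0) * mesh.nodal_areas_top()
    if weight.sum() <= 0:
        raise ValueError("elliptical patch does not cover any lattice node")
    weight = weight / weight.sum()
    f = magnitude * weight[..., None] * direction
    if moment_lever > 0.0 and magnitude > 0.0:
        xbar = (weight * X).sum()
        var = (weight * (X - xbar) ** 2).sum()
        if var > 0:
            m_y = abs(magnitude * direction[0]) * moment_lever
            f[..., 2] += (m_y / var) * weight * (X - xbar)
    return f


def gen_plaque_pull(scenario: SyntheticScenario):
    """Forward plaque-pull (Neumann) solve sampled as a DIC grid."""
    sc = scenario
    if sc.kind != "plaque_pull":
        raise ValueError("scenario kind must be 'plaque_pull'")
    w = 2.0 * sc.domain_halfwidth
    mesh = build_grid_mesh(w, w, sc.h, sc.spacing, nz=sc.nz,
                           origin=(-sc.domain_halfwidth, -sc.domain_halfwidth))
    top = mesh.top_nodes_grid()
    f_nodal = plaque_traction_field(mesh, sc.ellipse_axes, sc.pull_angle_deg,
                                    sc.pull_magnitude, moment_lever=sc.moment_lever)
    f_ext = np.zeros((mesh.n_nodes, 3))
    f_ext[top.ravel()] = f_nodal.reshape(-1, 3)
    if sc.pull_magnitude == 0.0:
        res_u = np.zeros((mesh.n_nodes, 3))
        peak_strain = 0.0
    else:
        res = fe.solve_neumann(mesh, sc.material, f_ext)
        res_u = res.u
        peak_strain = res.peak_principal_strain

    disp = res_u[top]
    truth = GroundTruth(
        resultant=f_nodal.sum(axis=(0, 1)),
        tractions=f_nodal, displacements=disp, x=mesh.xs, y=mesh.ys,
        meta={"kind": sc.kind, "pull_angle_deg": sc.pull_angle_deg,
              "pull_magnitude_N": sc.pull_magnitude,
              "ellipse_axes_mm": list(sc.ellipse_axes),
              "peak_principal_strain": peak_strain},
    )
    grid = DisplacementGrid(x=mesh.xs, y=mesh.ys, u=disp[..., 0],
                            v=disp[..., 1], w=disp[..., 2])
    grid = add_noise(grid, sc.noise_std_um, sc.seed)
    return grid, truth


def add_noise(grid: DisplacementGrid, std_um, seed: int) -> DisplacementGrid:
    """Add i.i.d. per-axis Gaussian noise (std in micrometres) to a grid."""
    std = np.broadcast_to(np.asarray(std_um, dtype=float), (3,))
    if np.all(std == 0.0):
        return grid
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape + (3,)) * std * 1e-3  # um -> mm
    noise[~grid.mask] = 0.0
    return dc_replace(grid,
                      u=grid.u + noise[..., 0],
                      v=grid.v + noise[..., 1],
                      w=grid.w + noise[..., 2])
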