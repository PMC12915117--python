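"""Hexahedral finite-element solver for the thin bonded substrate layer.

Trilinear 8-node hexahedra with 2x2x2 Gauss quadrature.  Near
incompressibility (Poisson ratio ~0.45) is handled with the mean-dilatation
(Q1P0) treatment: the isochoric Ogden response is evaluated per Gauss point
while a single element pressure p = U'(Jbar) acts on the element-average
volume ratio Jbar.  Because the isochoric stretches are invariant under the
volume-preserving rescaling of F, this is an exact, element-local
formulation with an analytic consistent tangent (rank-one volumetric
coupling), so Newton converges quadratically.

Supported problems
------------------
* displacement-driven (Dirichlet) solves — the traction inversion step;
* nodal-force (Neumann) solves — forward synthetic loading;
* frictionless rigid-sphere penalty contact with an outer iteration on the
  penetration depth until the total vertical reaction matches a target
  force — the validation forward problem.

Units: mm, N, MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import (
    LinearElasticMaterial,
    OgdenMaterial,
    ogden_iso_pk2,
    volumetric_pressure,
)
from .foundation import oedometric_modulus
from .mesh import HexMesh

_GP = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
               dtype=float) / np.sqrt(3.0)
# natural coordinates of the 8 nodes in VTK hexahedron order
_XI_N = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                  [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)


class SolverError(RuntimeError):
    pass


class ContactError(SolverError):
    pass


def _shape_grads():
    """dN/dxi at each Gauss point: (8 gp, 8 nodes, 3)."""
    g = np.empty((8, 8, 3))
    for q, xi in enumerate(_GP):
        for a, xa in enumerate(_XI_N):
            t = 0.125 * np.array([
                xa[0] * (1 + xi[1] * xa[1]) * (1 + xi[2] * xa[2]),
                (1 + xi[0] * xa[0]) * xa[1] * (1 + xi[2] * xa[2]),
                (1 + xi[0] * xa[0]) * (1 + xi[1] * xa[1]) * xa[2],
            ])
            g[q, a] = t
    return g


_DNDXI = _shape_grads()


@dataclass
class Precomputed:
    dNdX: np.ndarray   # (Ne, 8gp, 8nodes, 3)
    wdet: np.ndarray   # (Ne, 8gp) quadrature weight x |J|
    ve: np.ndarray     # (Ne,) element reference volumes
    edof: np.ndarray   # (Ne, 24) global dof indices


def precompute(mesh: HexMesh) -> Precomputed:
    Xe = mesh.nodes[mesh.elems]                      # (Ne, 8, 3)
    jac = np.einsum("gam,eaJ->egmJ", _DNDXI, Xe)     # dX_J/dxi_m
    det = np.linalg.det(jac)
    if np.any(det <= 0):
        raise SolverError("non-positive element Jacobian")
    inv = np.linalg.inv(jac)
    dNdX = np.einsum("gam,egmJ->egaJ", _DNDXI, inv)
    wdet = det  # all quadrature weights are 1
    edof = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 24)
    return Precomputed(dNdX=dNdX, wdet=wdet, ve=wdet.sum(axis=1), edof=edof)


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------


@dataclass
class DirichletBC:
    """Per-component prescribed displacements keyed by node id."""

    n_nodes: int
    mask: np.ndarray = None   # (Nn, 3) bool
    value: np.ndarray = None  # (Nn, 3) mm

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.zeros((self.n_nodes, 3), dtype=bool)
        if self.value is None:
            self.value = np.zeros((self.n_nodes, 3))

    def fix(self, node_ids, components=(0, 1, 2), value=0.0):
        ids = np.asarray(node_ids, dtype=int)
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_nodes):
            raise IndexError("node id out of range")
        for c in components:
            self.mask[ids, c] = True
            self.value[ids, c] = value
        return self

    def prescribe(self, node_ids, disp, components=(0, 1, 2)):
        """Prescribe displacement vectors (n, 3) at the given nodes."""
        ids = np.asarray(node_ids, dtype=int)
        disp = np.asarray(disp, dtype=float)
        for c in components:
            self.mask[ids, c] = True
            self.value[ids, c] = disp[..., c]
        return self


def fix_bottom(mesh: HexMesh) -> DirichletBC:
    return DirichletBC(mesh.n_nodes).fix(mesh.node_sets["bottom"])


@dataclass
class ConvergenceRecord:
    step: float
    iterations: int
    residuals: list


@dataclass
class SolveResult:
    """Converged displacement state with reactions on constrained dofs."""

    mesh: HexMesh
    u: np.ndarray                  # (Nn, 3) mm
    reactions: np.ndarray          # (Nn, 3) N, nonzero only on constrained dofs
    fixed_mask: np.ndarray         # (Nn, 3) bool
    f_ext: np.ndarray              # (Nn, 3) external nodal forces (N)
    principal_strain: np.ndarray   # (Ne,) max principal nominal strain per element
    log: list = field(default_factory=list)
    contact: "ContactReport | None" = None

    @property
    def peak_principal_strain(self) -> float:
        return float(self.principal_strain.max()) if self.principal_strain.size else 0.0


@dataclass
class ContactReport:
    penetration_depth: float   # mm
    patch_radius: float        # mm
    total_force: float         # N (vertical, magnitude)
    forces: np.ndarray         # (Nn, 3) contact nodal forces on the substrate


@dataclass
class SolverOptions:
    rtol: float = 1.0e-8
    atol: float = 1.0e-12
    max_iter: int = 30
    max_bisect: int = 4
    n_steps: int = 1
    du_cap: float | None = None  # max |du|_inf per Newton iteration (mm)


@dataclass
class RigidSphere:
    """Analytic rigid sphere indenter (frictionless)."""

    radius: float
    friction: str = "frictionless"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.friction != "frictionless":
            raise NotImplementedError("only frictionless contact is supported")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _assemble_ogden(mesh, pre, mat: OgdenMaterial, u, want_tangent=True):
    """Q1P0 residual (internal force) and consistent tangent for Ogden."""
    ue = u.reshape(-1, 3)[mesh.elems]                    # (Ne, 8, 3)
    F = np.eye(3) + np.einsum("eai,egaJ->egiJ", ue, pre.dNdX)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise SolverError("element inversion (det F <= 0) during Newton")
    C = np.einsum("egkI,egkJ->egIJ", F, F)
    S_iso, C4_iso = ogden_iso_pk2(mat, C, want_tangent=want_tangent)
    FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)

    Jbar = np.einsum("eg,eg->e", pre.wdet, J) / pre.ve
    p, dp = volumetric_pressure(mat, Jbar)

    P = np.einsum("egiA,egAJ->egiJ", F, S_iso) \
        + (p[:, None] * J)[..., None, None] * FinvT
    r_el = np.einsum("eg,egiJ,egaJ->eai", pre.wdet, P, pre.dNdX)

    if not want_tangent:
        return r_el, None, F, J

    # first-PK tangent A_iJkL (isochoric + constant-pressure volumetric parts),
    # built with batched matmuls (hot path)
    ne = F.shape[0]
    m = ne * 8
    Ff = F.reshape(m, 3, 3)
    C4f = C4_iso.reshape(m, 3, 27)
    t1 = (Ff @ C4f).reshape(m, 3, 3, 3, 3)              # i,J,B,L = F_iA C4_AJBL
    t1 = np.ascontiguousarray(t1.transpose(0, 1, 2, 4, 3)).reshape(m, 27, 3)
    A = 2.0 * (t1 @ Ff.transpose(0, 2, 1)).reshape(m, 3, 3, 3, 3).transpose(0, 1, 2, 4, 3)
    A = np.ascontiguousarray(A)                          # (m, i, J, k, L)
    Sf = S_iso.reshape(m, 3, 3)
    for i in range(3):                                   # geometric term d_ik S_LJ
        A[:, i, :, i, :] += Sf
    Fit = FinvT.reshape(m, 9)
    o1 = (Fit[:, :, None] * Fit[:, None, :]).reshape(m, 3, 3, 3, 3)
    pj = (p[:, None] * J).reshape(m)[:, None, None, None, None]
    A += pj * (o1 - o1.transpose(0, 1, 4, 3, 2))

    # K_g[(a i),(b k)] = B_aJ A_iJkL B_bL via two batched GEMMs
    B = pre.dNdX.reshape(m, 8, 3)
    Ar = np.ascontiguousarray(A.transpose(0, 2, 1, 3, 4)).reshape(m, 3, 27)  # J,(i k L)
    X = (B @ Ar).reshape(m, 72, 3)                       # (a i k), L
    Y = (X @ B.transpose(0, 2, 1)).reshape(m, 8, 3, 3, 8)  # a,i,k,b
    Kg = np.ascontiguousarray(Y.transpose(0, 1, 2, 4, 3)).reshape(ne, 8, 24, 24)
    K_el = np.einsum("eg,egab->eab", pre.wdet, Kg)
    # rank-one volumetric coupling: p depends on the element-average J
    b = np.einsum("eg,eg,egiJ,egaJ->eai", pre.wdet, J, FinvT, pre.dNdX).reshape(-1, 24)
    K_el += (dp / pre.ve)[:, None, None] * b[:, :, None] * b[:, None, :]
    return r_el, K_el, F, J


def _assemble_linear_K(mesh, pre, mat: LinearElasticMaterial):
    """Small-strain stiffness with B-bar (element-mean volumetric strain)."""
    G, K = mat.shear_modulus, mat.bulk_modulus
    dN, w = pre.dNdX, pre.wdet
    gram = np.einsum("eg,egaJ,egbJ->eab", w, dN, dN)           # grad(Na).grad(Nb)
    cross = np.einsum("eg,egak,egbi->eaibk", w, dN, dN)
    diag = np.einsum("eab,ik->eaibk", gram, np.eye(3))
    outer = np.einsum("eg,egai,egbk->eaibk", w, dN, dN)
    K_el = G * (diag + cross) - (2.0 * G / 3.0) * outer
    bbar = np.einsum("eg,egai->eai", w, dN) / pre.ve[:, None, None]
    bbar = bbar.reshape(-1, 24)
    K_el = K_el.reshape(-1, 24, 24) + (K * pre.ve)[:, None, None] * bbar[:, :, None] * bbar[:, None, :]
    return K_el


def _to_csr(pre, K_el, ndof):
    rows = np.repeat(pre.edof[:, :, None], 24, axis=2)
    cols = np.repeat(pre.edof[:, None, :], 24, axis=1)
    K = sp.coo_matrix((K_el.ravel(), (rows.ravel(), cols.ravel())), shape=(ndof, ndof))
    return K.tocsr()


def _scatter(pre, r_el, ndof):
    r = np.zeros(ndof)
    np.add.at(r, pre.edof.ravel(), r_el.reshape(-1, 24).ravel())
    return r


def _principal_strain_field(mesh, pre, u, material):
    """Per-element max principal nominal strain.

    Reported as the largest principal-stretch deviation max_i |lambda_i - 1|
    (|eigenvalue| of the strain tensor in the linear case) so that
    compression- and tension-dominated states are measured alike.
    """
    ue = u.reshape(-1, 3)[mesh.elems]
    H = np.einsum("eai,egaJ->egiJ", ue, pre.dNdX)
    if isinstance(material, LinearElasticMaterial):
        eps = 0.5 * (H + np.swapaxes(H, -1, -2))
        ev = np.abs(np.linalg.eigvalsh(eps)).max(axis=-1)
        return ev.max(axis=1)
    F = np.eye(3) + H
    C = np.einsum("egkI,egkJ->egIJ", F, F)
    lam = np.sqrt(np.linalg.eigvalsh(C))
    return np.abs(lam - 1.0).max(axis=(-1, -2))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _solve_linear(mesh, pre, mat, bc, f_ext, opts):
    ndof = 3 * mesh.n_nodes
    K_el = _assemble_linear_K(mesh, pre, mat)
    K = _to_csr(pre, K_el, ndof)
    fixed = bc.mask.ravel()
    free = ~fixed
    u = np.zeros(ndof)
    u[fixed] = bc.value.ravel()[fixed]
    rhs = f_ext.ravel()[free] - K[free][:, fixed] @ u[fixed]
    Kff = K[free][:, free].tocsc()
    u[free] = splu(Kff, permc_spec="MMD_AT_PLUS_A").solve(rhs)
    full = K @ u - f_ext.ravel()
    reactions = np.where(fixed, full, 0.0).reshape(-1, 3)
    return u.reshape(-1, 3), reactions, [ConvergenceRecord(1.0, 1, [0.0])]


def _newton(mesh, pre, mat, fixed, fixed_vals, f_ext, u0, opts, contact=None):
    """Newton solve at a fixed load/BC level.  Returns (u, log) or raises."""
    ndof = 3 * mesh.n_nodes
    free = ~fixed
    u = u0.copy()
    u[fixed] = fixed_vals[fixed]
    residuals = []
    ref = max(np.linalg.norm(f_ext), opts.atol)

    def system_at(uvec):
        r_el, K_el, _, _ = _assemble_ogden(mesh, pre, mat, uvec)
        r = _scatter(pre, r_el, ndof) - f_ext
        K = _to_csr(pre, K_el, ndof)
        if contact is not None:
            fc, Kc = contact(uvec)
            r -= fc
            K = K + Kc
        return r, K

    r, K = system_at(u)
    for it in range(opts.max_iter):
        rn = np.linalg.norm(r[free])
        residuals.append(rn)
        ref = max(ref, np.linalg.norm(r[fixed]))
        if rn <= opts.rtol * ref + opts.atol:
            return u, residuals
        if it > 4 and rn > 1.0e4 * min(residuals):
            raise SolverError("Newton diverging; enable load stepping")
        du = splu(K[free][:, free].tocsc(), permc_spec="MMD_AT_PLUS_A").solve(-r[free])
        # trust-region style cap keeps penalty-contact steps stable
        scale = 1.0
        if opts.du_cap is not None:
            scale = min(1.0, opts.du_cap / max(np.abs(du).max(), 1e-30))
        scale_floor = scale / 64.0
        while True:
            u_try = u.copy()
            u_try[free] += scale * du
            try:
                r, K = system_at(u_try)
                break
            except SolverError:
                scale /= 2.0
                if scale < scale_floor:
                    raise
        u = u_try
    raise SolverError(f"Newton did not converge in {opts.max_iter} iterations "
                      f"(last residual {residuals[-1]:.3e}); enable load stepping")


def _stepped_newton(mesh, pre, mat, bc, f_ext, opts, u0=None):
    """Incremental application of prescribed displacements/forces with
    automatic 2x substepping on Newton divergence."""
    ndof = 3 * mesh.n_nodes
    fixed = bc.mask.ravel()
    target_vals = bc.value.ravel()
    u = np.zeros(ndof) if u0 is None else u0.copy()
    log = []
    frac_done, frac_step = 0.0, 1.0 / opts.n_steps
    bisect = 0
    while frac_done < 1.0 - 1e-12:
        frac = min(1.0, frac_done + frac_step)
        try:
            u_new, residuals = _newton(mesh, pre, mat, fixed, frac * target_vals,
                                       frac * f_ext.ravel(), u, opts)
            u = u_new
            log.append(ConvergenceRecord(frac, len(residuals), residuals))
            frac_done = frac
        except SolverError:
            bisect += 1
            if bisect > opts.max_bisect:
                raise
            frac_step /= 2.0
    return u, log


def solve_dirichlet(mesh: HexMesh, material, bc: DirichletBC,
                    options: SolverOptions | None = None,
                    f_ext: np.ndarray | None = None) -> SolveResult:
    """Solve the layer under prescribed displacements (and optional nodal forces).

    Reactions are reported at every constrained dof; the sign convention is
    the force exerted *on* the substrate by whatever enforces the constraint
    (the adherend on the top surface, the backing at the bottom).
    """
    opts = options or SolverOptions()
    pre = precompute(mesh)
    ndof = 3 * mesh.n_nodes
    f_ext = np.zeros((mesh.n_nodes, 3)) if f_ext is None else np.asarray(f_ext, dtype=float)
    if isinstance(material, LinearElasticMaterial):
        u, reactions, log = _solve_linear(mesh, pre, material, bc, f_ext, opts)
    else:
        u_flat, log = _stepped_newton(mesh, pre, material, bc, f_ext, opts)
        r_el, _, _, _ = _assemble_ogden(mesh, pre, material, u_flat, want_tangent=False)
        full = _scatter(pre, r_el, ndof) - f_ext.ravel()
        reactions = np.where(bc.mask.ravel(), full, 0.0).reshape(-1, 3)
        u = u_flat.reshape(-1, 3)
    strain = _principal_strain_field(mesh, pre, u, material)
    return SolveResult(mesh=mesh, u=u, reactions=reactions, fixed_mask=bc.mask,
                       f_ext=f_ext, principal_strain=strain, log=log)


def solve_neumann(mesh: HexMesh, material, f_ext: np.ndarray, bc: DirichletBC | None = None,
                  options: SolverOptions | None = None) -> SolveResult:
    """Solve under applied nodal forces with the bottom surface fixed."""
    bc = bc if bc is not None else fix_bottom(mesh)
    return solve_dirichlet(mesh, material, bc, options=options, f_ext=f_ext)


def extract_top_reactions(result: SolveResult, mesh: HexMesh | None = None):
    """Per-top-node reaction force vectors (N) and their node ids.

    Only meaningful on solves where the top surface carried Dirichlet
    constraints; requesting unconstrained nodes is a contract error.
    """
    mesh = mesh or result.mesh
    top = mesh.node_sets["top"]
    if not result.fixed_mask[top].any():
        raise ValueError("top surface carries no constrained dofs in this solve")
    return top, result.reactions[top]


def max_principal_strain(result: SolveResult):
    """Per-element max principal nominal strain field and its peak value."""
    return result.principal_strain, result.peak_principal_strain


# ---------------------------------------------------------------------------
# rigid-sphere contact
# ---------------------------------------------------------------------------


def _make_contact(mesh, top_ids, center, radius, kpen_per_node):
    X = mesh.nodes[top_ids]
    ndof = 3 * mesh.n_nodes
    dofs = (3 * top_ids[:, None] + np.arange(3))

    def contact(u):
        x = X + u.reshape(-1, 3)[top_ids]
        d = x - center
        r = np.linalg.norm(d, axis=1)
        g = r - radius
        active = g < 0
        f = np.zeros(ndof)
        if not active.any():
            return f, sp.csr_matrix((ndof, ndof))
        n = d[active] / r[active, None]
        kp = kpen_per_node[active]
        fa = -(kp * g[active])[:, None] * n
        np.add.at(f, dofs[active].ravel(), fa.ravel())
        # consistent tangent of the penalty force
        nn = n[:, :, None] * n[:, None, :]
        blocks = kp[:, None, None] * (nn + (g[active] / r[active])[:, None, None]
                                      * (np.eye(3) - nn))
        rows = np.repeat(dofs[active][:, :, None], 3, axis=2)
        cols = np.repeat(dofs[active][:, None, :], 3, axis=1)
        Kc = sp.coo_matrix((blocks.ravel(), (rows.ravel(), cols.ravel())),
                           shape=(ndof, ndof)).tocsr()
        return f, Kc

    return contact


def solve_sphere_indentation(mesh: HexMesh, material, sphere: RigidSphere,
                             target_force: float, options: SolverOptions | None = None,
                             force_rtol: float = 0.005, center_xy=(0.0, 0.0),
                             penalty_factor: float = 100.0) -> SolveResult:
    """Frictionless rigid-sphere indentation to a prescribed total normal force.

    A node-on-analytic-sphere penalty enforces contact; an outer secant
    iteration adjusts the penetration depth until the summed vertical
    contact force matches ``target_force`` within ``force_rtol``.
    """
    if target_force <= 0:
        raise ValueError("target_force must be positive")
    opts = options or SolverOptions()
    pre = precompute(mesh)
    h = mesh.thickness
    top_ids = mesh.top_nodes_grid().ravel()
    if isinstance(material, LinearElasticMaterial):
        E, nu = material.E, material.nu
    else:
        E, nu = material.youngs_modulus, material.poisson
    M = oedometric_modulus(E, nu)
    elem_height = h / (len(mesh.zs) - 1)
    areas = mesh.nodal_areas_top().ravel()
    kpen = penalty_factor * (M / elem_height) * areas

    # Winkler-type first guess: F ~ (M/h) * pi * R * d^2
    d_est = np.sqrt(target_force * h / (np.pi * sphere.radius * M))
    extent = min(mesh.xs[-1] - center_xy[0], mesh.ys[-1] - center_xy[1])
    if np.sqrt(2 * sphere.radius * d_est) > 0.8 * extent:
        raise ContactError("expected contact patch exceeds the mesh extent")

    bc = fix_bottom(mesh)
    fixed = bc.mask.ravel()
    u = np.zeros(3 * mesh.n_nodes)
    log = []

    # intermediate depth solves need only enough accuracy for the force
    # iteration; the final state is polished at the full tolerance.  The
    # Newton step cap stabilises the penalty contact after depth jumps.
    du_cap = 0.3 * elem_height
    opts = SolverOptions(rtol=opts.rtol, atol=opts.atol, max_iter=opts.max_iter,
                         max_bisect=opts.max_bisect, du_cap=du_cap)
    opts_coarse = SolverOptions(rtol=1.0e-5, atol=opts.atol, max_iter=opts.max_iter,
                                max_bisect=opts.max_bisect, du_cap=du_cap)

    def solve_at(depth, u0, newton_opts):
        center = np.array([center_xy[0], center_xy[1], h + sphere.radius - depth])
        contact = _make_contact(mesh, top_ids, center, sphere.radius, kpen)
        u_new, residuals = _newton(mesh, pre, material, fixed, bc.value.ravel(),
                                   np.zeros(3 * mesh.n_nodes), u0, newton_opts,
                                   contact=contact)
        fc, _ = contact(u_new)
        return u_new, fc, residuals

    def advance(depth_from, depth_to, u0, newton_opts, max_splits=6):
        """Move the indenter from one converged depth to another, bisecting
        the depth increment whenever Newton fails."""
        u_cur, cur = u0, depth_from
        pending = [depth_to]
        splits = 0
        fc_last = residuals_last = None
        while pending:
            d = pending[-1]
            try:
                u_cur, fc_last, residuals_last = solve_at(d, u_cur, newton_opts)
                cur = d
                pending.pop()
            except SolverError:
                splits += 1
                if splits > max_splits:
                    raise
                pending.append(0.5 * (cur + d))
        return u_cur, fc_last, residuals_last

    # ramp up to the estimated depth, then secant on (depth, force)
    history = []
    depth = d_est
    u, fc, residuals = advance(0.0, d_est, u, opts_coarse)
    log.append(ConvergenceRecord(1.0, len(residuals), residuals))
    F = -fc.reshape(-1, 3)[:, 2].sum()
    history.append((depth, F))
    for it in range(20):
        if abs(F - target_force) <= force_rtol * target_force:
            break
        if len(history) >= 2 and history[-2][1] != history[-1][1]:
            (d0, F0), (d1, F1) = history[-2], history[-1]
            d_new = d1 + (target_force - F1) * (d1 - d0) / (F1 - F0)
        else:
            d_new = depth * np.sqrt(target_force / max(F, 1e-12))
        d_new = float(np.clip(d_new, 0.3 * depth, 3.0 * depth))
        u, fc, residuals = advance(depth, d_new, u, opts_coarse)
        depth = d_new
        F = -fc.reshape(-1, 3)[:, 2].sum()
        history.append((depth, F))
        log.append(ConvergenceRecord(1.0, len(residuals), residuals))
    else:
        raise ContactError(f"force iteration did not converge: F={F:.4g} N "
                           f"vs target {target_force:.4g} N")
    # polish the converged depth at the full tolerance
    u, fc, residuals = solve_at(depth, u, opts)
    F = -fc.reshape(-1, 3)[:, 2].sum()
    log.append(ConvergenceRecord(1.0, len(residuals), residuals))

    fc3 = fc.reshape(-1, 3)
    active = np.abs(fc3[top_ids, 2]) > 0
    xy = mesh.nodes[top_ids][active, :2] - np.asarray(center_xy)
    patch_r = float(np.max(np.linalg.norm(xy, axis=1))) if active.any() else 0.0
    ndof = 3 * mesh.n_nodes
    r_el, _, _, _ = _assemble_ogden(mesh, pre, material, u, want_tangent=False) \
        if isinstance(material, OgdenMaterial) else (None,) * 4
    if r_el is not None:
        full = _scatter(pre, r_el, ndof) - fc
        reactions = np.where(fixed, full, 0.0).reshape(-1, 3)
    else:  # pragma: no cover - linear contact not used in practice
        reactions = np.zeros((mesh.n_nodes, 3))
    strain = _principal_strain_field(mesh, precompute(mesh), u.reshape(-1, 3), material)
    report = ContactReport(penetration_depth=depth, patch_radius=patch_r,
                           total_force=F, forces=fc3)
    return SolveResult(mesh=mesh, u=u.reshape(-1, 3), reactions=reactions,
                       fixed_mask=bc.mask, f_ext=fc3, principal_strain=strain,
                       log=log, contact=report)


# ---------------------------------------------------------------------------
# calibration helper
# ---------------------------------------------------------------------------


def confined_layer_stiffness(E: float, nu: float, h: float, sigma: float = 1.0e-3,
                             nz: int = 3) -> float:
    """Effective stiffness sigma/delta_z of a laterally confined bonded layer.

    Bottom fixed, lateral faces normal-fixed, uniform vertical pressure on
    top — the uniform-pressure calibration configuration.  A single element
    column suffices by symmetry.  Returns k_FE in N/mm^3.
    """
    from .mesh import mesh_from_coords
    m = mesh_from_coords([0.0, h], [0.0, h], np.linspace(0, h, nz + 1))
    bc = fix_bottom(m)
    bc.fix(m.node_sets["x_faces"], components=(0,))
    bc.fix(m.node_sets["y_faces"], components=(1,))
    f = np.zeros((m.n_nodes, 3))
    f[m.node_sets["top"], 2] = -sigma * h * h / 4.0  # 4 corner nodes share the face
    mat = LinearElasticMaterial(E=E, nu=nu)
    res = solve_dirichlet(m, mat, bc, f_ext=f)
    dz = -res.u[m.node_sets["top"], 2].mean()
    return sigma / dz
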