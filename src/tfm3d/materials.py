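"""Constitutive models for the deformable substrate layer.

The substrate (PDMS in the target application) is modelled either as a
two-term nearly-incompressible Ogden hyperelastic solid or, for comparison
studies, as a small-strain linear-elastic solid.

The Ogden strain-energy density used throughout is the deviatoric-stretch
form

    W = sum_p (2 mu_p / alpha_p**2) * (lb1**a_p + lb2**a_p + lb3**a_p - 3)
        + (1/D) * (J - 1)**2,        lb_i = J**(-1/3) * lambda_i,

so that the initial shear modulus is G0 = sum_p mu_p and the initial bulk
modulus is K = 2/D.  Small-strain Young's modulus and Poisson's ratio follow
from (G0, K) by the usual isotropic relations.

Units: stresses in MPa, energies in MPa (= N*mm/mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares


class InvalidDeformationError(ValueError):
    """Raised for non-physical kinematic input (stretch <= 0, det F <= 0)."""


class FitError(RuntimeError):
    """Raised when material fitting fails to converge; carries best candidate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# material types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OgdenMaterial:
    """Two-term (or N-term) Ogden material, nearly incompressible.

    Parameters
    ----------
    mu : shear-like constants mu_p in MPa (sum must be positive)
    alpha : dimensionless exponents alpha_p
    D : incompressibility parameter in 1/MPa (K = 2/D)
    """

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    D: float

    def __post_init__(self):
        mu = tuple(float(m) for m in self.mu)
        alpha = tuple(float(a) for a in self.alpha)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        if len(mu) != len(alpha):
            raise ValueError("mu and alpha must have the same length")
        if self.D <= 0:
            raise ValueError("D must be positive (K = 2/D)")
        if sum(mu) <= 0:
            raise ValueError("sum(mu_p) = G0 must be positive")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError(f"derived Poisson ratio {self.poisson:.4f} outside (0, 0.5)")

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def shear_modulus(self) -> float:
        """Initial (small-strain) shear modulus G0 = sum mu_p."""
        return float(sum(self.mu))

    @property
    def bulk_modulus(self) -> float:
        """Initial bulk modulus K = 2/D."""
        return 2.0 / self.D

    @property
    def poisson(self) -> float:
        G0, K = self.shear_modulus, self.bulk_modulus
        return (3.0 * K - 2.0 * G0) / (2.0 * (3.0 * K + G0))

    @property
    def youngs_modulus(self) -> float:
        return 2.0 * self.shear_modulus * (1.0 + self.poisson)


@dataclass(frozen=True)
class LinearElasticMaterial:
    """Isotropic Hookean solid (E in MPa, 0 <= nu < 0.5)."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def bulk_modulus(self) -> float:
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def lame_lambda(self) -> float:
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))


#: Ogden constants of the substrate material model used in the validation
#: studies (mu_p in MPa, D in 1/MPa); G0 = 0.4705 MPa, nu = 0.45.
TABLE_PDMS = OgdenMaterial(mu=(4.71e-4, 0.47), alpha=(14.79, 4.84), D=0.44)

#: Batch-average substrate model (G0 = 0.475 MPa, E = 1.38 MPa at nu = 0.45)
#: with upper/lower bounds from sample-to-sample variation.
AVERAGE_PDMS = OgdenMaterial(mu=(4.71e-4, 0.475), alpha=(14.79, 4.84), D=0.44 * 0.4705 / 0.475)
UPPER_PDMS = OgdenMaterial(mu=(4.94e-4, 0.494), alpha=(14.79, 4.84), D=0.44 * 0.4705 / 0.494)
LOWER_PDMS = OgdenMaterial(mu=(3.89e-4, 0.432), alpha=(14.79, 4.84), D=0.44 * 0.4705 / 0.432)


def D_from_poisson(G0: float, nu: float) -> float:
    """Incompressibility parameter D giving Poisson ratio ``nu`` at modulus G0."""
    if not 0.0 < nu < 0.5:
        raise ValueError("nu must lie in (0, 0.5)")
    K = 2.0 * G0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
    return 2.0 / K


def derived_poisson(mat: OgdenMaterial) -> float:
    """Small-strain Poisson ratio nu = (3K - 2G0) / (2(3K + G0)), K = 2/D."""
    return mat.poisson


def linear_equivalent(mat: OgdenMaterial) -> LinearElasticMaterial:
    """Linear-elastic material with the Ogden model's derived (E, nu)."""
    return LinearElasticMaterial(E=mat.youngs_modulus, nu=mat.poisson)


# ---------------------------------------------------------------------------
# energies and closed-form stresses
# ---------------------------------------------------------------------------


def strain_energy(mat: OgdenMaterial, stretches: Sequence[float], J: float | None = None) -> float:
    """Strain-energy density W for given principal stretches (and volume ratio).

    If ``J`` is omitted it defaults to the product of the stretches.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,) or np.any(lam <= 0):
        raise InvalidDeformationError("three positive principal stretches required")
    if J is None:
        J = float(np.prod(lam))
    if J <= 0:
        raise InvalidDeformationError("volume ratio J must be positive")
    lb = lam * J ** (-1.0 / 3.0)
    W = (1.0 / mat.D) * (J - 1.0) ** 2
    for m, a in zip(mat.mu, mat.alpha):
        W += (2.0 * m / a**2) * (np.sum(lb**a) - 3.0)
    return float(W)


def uniaxial_nominal_stress(mat: OgdenMaterial, stretch):
    """Nominal (first Piola) stress P(lambda) in incompressible uniaxial tension.

    With lambda2 = lambda3 = lambda**(-1/2):
        P = sum_p (2 mu_p / alpha_p) * (lam**(a_p - 1) - lam**(-a_p/2 - 1))
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise InvalidDeformationError("stretch must be positive")
    P = np.zeros_like(lam)
    for m, a in zip(mat.mu, mat.alpha):
        P = P + (2.0 * m / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return P if P.ndim else float(P)


# ---------------------------------------------------------------------------
# spectral stress and consistent tangent (batched)
# ---------------------------------------------------------------------------

_EIG_TOL = 1.0e-7   # |lam_i - lam_j| below which stretches count as repeated
_EIG_PERT = 1.0e-8  # relative perturbation applied to repeated stretches


def _principal_stretches(C):
    """Eigen-decomposition of right Cauchy-Green tensors C (..., 3, 3).

    Returns (lam, N) with lam (..., 3) ascending principal stretches and
    N (..., 3, 3) whose columns are the eigenvectors.
    """
    c, N = np.linalg.eigh(C)
    c = np.maximum(c, 1.0e-16)
    return np.sqrt(c), N


def _perturb_repeated(lam):
    """Split (near-)repeated stretches so spectral-tangent denominators are safe.

    The stress itself is regular at coincident stretches; only the tangent's
    (s_i - s_j)/(c_i - c_j) terms need distinct eigenvalues, so the perturbed
    stretches are used for the tangent alone (error O(1e-8) in the tangent,
    none in the residual).
    """
    pert = np.zeros_like(lam)
    close01 = np.abs(lam[..., 1] - lam[..., 0]) < _EIG_TOL
    close12 = np.abs(lam[..., 2] - lam[..., 1]) < _EIG_TOL
    pert[..., 0] -= np.where(close01, _EIG_PERT, 0.0)
    pert[..., 2] += np.where(close12, _EIG_PERT, 0.0)
    return lam * (1.0 + pert)


def ogden_iso_pk2(mat: OgdenMaterial, C, want_tangent: bool = True):
    """Isochoric 2nd Piola-Kirchhoff stress (and material tangent) from C.

    Parameters
    ----------
    C : (..., 3, 3) right Cauchy-Green tensors.

    Returns
    -------
    S : (..., 3, 3) isochoric 2nd PK stress.
    C4 : (..., 3, 3, 3, 3) tangent dS/dC (minor-symmetric), or None.
    """
    lam0, N = _principal_stretches(C)
    mu = np.asarray(mat.mu)
    al = np.asarray(mat.alpha)

    def principal_s(lam):
        c = lam**2
        J = lam[..., 0] * lam[..., 1] * lam[..., 2]
        lb = lam * J[..., None] ** (-1.0 / 3.0)
        # e[..., p, i] = lb_i ** alpha_p
        e = lb[..., None, :] ** al[..., :, None]
        ebar = e.mean(axis=-1)  # (..., p)
        # beta_i = lam_i dW/dlam_i = sum_p (2 mu_p / a_p) (e_pi - ebar_p)
        beta = np.einsum("p,...pi->...i", 2.0 * mu / al, e - ebar[..., None])
        return c, e, ebar, beta, beta / c

    _, _, _, _, s0 = principal_s(lam0)
    M = np.einsum("...ai,...bi->...iab", N, N)  # M[..., i] = N_i outer N_i
    S = np.einsum("...i,...iab->...ab", s0, M)

    if not want_tangent:
        return S, None

    lam = _perturb_repeated(lam0)
    c, e, ebar, beta, s = principal_s(lam)
    # dbeta_i/dlam_j = sum_p (2 mu_p / lam_j) [e_pi d_ij - (e_pi + e_pj)/3 + ebar_p/3]
    d3 = np.eye(3)
    bracket = (
        np.einsum("...pi,ij->...pij", e, d3)
        - (e[..., :, :, None] + e[..., :, None, :]) / 3.0
        + ebar[..., None, None] / 3.0
    )
    dbeta = np.einsum("p,...pij->...ij", 2.0 * mu, bracket) / lam[..., None, :]
    # ds_i/dc_j = dbeta_i/dlam_j / (2 lam_j c_i) - d_ij beta_i / c_i^2
    dsdc = dbeta / (2.0 * lam[..., None, :] * c[..., :, None])
    idx = np.arange(3)
    dsdc[..., idx, idx] -= beta / c**2

    # batched-matmul evaluation of the spectral sums (hot path)
    shape = C.shape[:-2]
    mflat = int(np.prod(shape)) if shape else 1
    Mv = M.reshape(mflat, 3, 9)
    P1 = np.swapaxes(dsdc.reshape(mflat, 3, 3), -1, -2) @ Mv      # j,(ab)
    C4 = np.swapaxes(P1, -1, -2) @ Mv   # (ab),(cd): sum_j P1[j,ab] M[j,cd]
    C4 = C4.reshape(shape + (3, 3, 3, 3))
    # off-diagonal (eigenvector rotation) part
    dc = c[..., :, None] - c[..., None, :]
    np.einsum("...ii->...i", dc)[...] = 1.0  # avoid /0 on diagonal
    g = (s[..., :, None] - s[..., None, :]) / dc
    g[..., idx, idx] = 0.0
    R = g.reshape(mflat, 3, 3) @ Mv                                # i,(bd) = sum_j g_ij M_j
    T = (np.swapaxes(Mv, -1, -2) @ R).reshape(shape + (3, 3, 3, 3))  # a,c,b,d
    axes = tuple(range(len(shape)))
    Gterm = 0.5 * (np.transpose(T, axes + (len(shape), len(shape) + 2, len(shape) + 1, len(shape) + 3))
                   + np.transpose(T, axes + (len(shape), len(shape) + 2, len(shape) + 3, len(shape) + 1)))
    C4 = C4 + Gterm
    return S, C4


def volumetric_pressure(mat: OgdenMaterial, J):
    """U'(J) and U''(J) for U = (1/D)(J-1)^2."""
    return (2.0 / mat.D) * (np.asarray(J) - 1.0), 2.0 / mat.D * np.ones_like(np.asarray(J, dtype=float))


def ogden_pk2(mat: OgdenMaterial, C, want_tangent: bool = True):
    """Full (isochoric + volumetric) 2nd PK stress and tangent dS/dC."""
    S, C4 = ogden_iso_pk2(mat, C, want_tangent)
    Cinv = np.linalg.inv(C)
    J = np.sqrt(np.linalg.det(C))
    p, dp = volumetric_pressure(mat, J)
    S = S + (p * J)[..., None, None] * Cinv
    if not want_tangent:
        return S, None
    coeff = (dp * J + p) * J / 2.0
    C4 = C4 + coeff[..., None, None, None, None] * np.einsum("...ab,...cd->...abcd", Cinv, Cinv)
    CiCi = 0.5 * (
        np.einsum("...ac,...bd->...abcd", Cinv, Cinv)
        + np.einsum("...ad,...bc->...abcd", Cinv, Cinv)
    )
    C4 = C4 - (p * J)[..., None, None, None, None] * CiCi
    return S, C4


def cauchy_stress_and_tangent(mat, F):
    """Cauchy stress and first-Piola tangent A = dP/dF for a deformation gradient.

    For an :class:`OgdenMaterial` the stress comes from the spectral
    decomposition; for a :class:`LinearElasticMaterial` the small-strain
    Hookean law sigma = lambda tr(eps) I + 2 mu eps with eps = sym(F - I).

    Returns ``(sigma, A)`` with sigma (..., 3, 3) in MPa and A (..., 3, 3, 3, 3).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidDeformationError("det F must be positive")
    if isinstance(mat, LinearElasticMaterial):
        eps = 0.5 * (F + np.swapaxes(F, -1, -2)) - np.eye(3)
        tr = np.trace(eps, axis1=-2, axis2=-1)
        sigma = mat.lame_lambda * tr[..., None, None] * np.eye(3) + 2.0 * mat.shear_modulus * eps
        I = np.eye(3)
        A = mat.lame_lambda * np.einsum("ab,cd->abcd", I, I) + mat.shear_modulus * (
            np.einsum("ac,bd->abcd", I, I) + np.einsum("ad,bc->abcd", I, I)
        )
        A = np.broadcast_to(A, F.shape + (3, 3)).copy()
        return sigma, A
    C = np.swapaxes(F, -1, -2) @ F
    S, C4 = ogden_pk2(mat, C, want_tangent=True)
    P = F @ S
    sigma = (P @ np.swapaxes(F, -1, -2)) / J[..., None, None]
    # A_iJkL = d_ik S_LJ + 2 F_iA F_kB C4_AJBL
    d3 = np.eye(3)
    A = np.einsum("ik,...LJ->...iJkL", d3, S) + 2.0 * np.einsum(
        "...iA,...AJBL,...kB->...iJkL", F, C4, F
    )
    return sigma, A


# ---------------------------------------------------------------------------
# uniaxial test data and fitting
# ---------------------------------------------------------------------------


@dataclass
class UniaxialDataset:
    """Nominal strain/stress pairs from a uniaxial tension test."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.size < 4:
            raise ValueError("strain and stress must be equal-length arrays of >= 4 points")
        if self.strain[0] < 0 or np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be ascending and start at >= 0")

    @property
    def stretch(self) -> np.ndarray:
        return 1.0 + self.strain


def read_uniaxial(path) -> UniaxialDataset:
    """Read a 2-column delimited text file (strain, stress_MPa); '#' comments."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (strain, stress_MPa)")
    return UniaxialDataset(strain=arr[:, 0], stress=arr[:, 1])


def write_uniaxial(data: UniaxialDataset, path) -> None:
    np.savetxt(path, np.column_stack([data.strain, data.stress]),
               header="strain stress_MPa", comments="# ")


@dataclass
class FitDiagnostics:
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    n_starts: int = 0
    converged: bool = True


def fit_ogden(data: UniaxialDataset, order: int = 2, nu_target: float = 0.45,
              seed: int = 20240101, n_starts: int = 8):
    """Fit an N-term Ogden model to uniaxial nominal stress-strain data.

    Least squares on (mu_p, alpha_p) with multi-start (seeded); D is set from
    ``nu_target`` via K = 2 G0 (1+nu)/(3(1-2nu)) since uniaxial data carries
    no volumetric information.  Returns (OgdenMaterial, FitDiagnostics).
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    lam = data.stretch
    y = data.stress
    scale = max(float(np.max(np.abs(y))), 1e-12)

    def model(params):
        mu, al = params[:order], params[order:]
        P = np.zeros_like(lam)
        for m, a in zip(mu, al):
            P += (2.0 * m / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
        return P

    def resid(params):
        return (model(params) - y) / scale

    rng = np.random.default_rng(seed)
    lo = np.concatenate([np.full(order, 1e-6), np.full(order, 0.1)])
    hi = np.concatenate([np.full(order, 10.0), np.full(order, 30.0)])
    best, best_cost = None, np.inf
    # a deterministic sensible start plus seeded random restarts
    starts = [np.concatenate([np.full(order, 0.3 / order), np.linspace(2.0, 12.0, order)])]
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(2 * order) * (hi - lo) * np.array([0.1] * order + [1.0] * order))
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if sol.cost < best_cost and np.sum(sol.x[:order]) > 0:
            best, best_cost = sol, sol.cost
    if best is None:
        raise FitError("Ogden fit failed to converge from any start")
    mu = best.x[:order]
    al = best.x[order:]
    G0 = float(np.sum(mu))
    mat = OgdenMaterial(mu=tuple(mu), alpha=tuple(al), D=D_from_poisson(G0, nu_target))
    res = model(best.x) - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else 1.0
    diag = FitDiagnostics(r_squared=r2, residuals=res, n_starts=len(starts))
    if r2 < 0.5:
        raise FitError(f"Ogden fit did not reach an acceptable R^2 ({r2:.3f})", best=(mat, diag))
    return mat, diag
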