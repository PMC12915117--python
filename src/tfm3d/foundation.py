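"""Elastic-foundation design model for the deformable substrate layer.

A thin elastomer layer bonded to a rigid backing responds to a uniform
vertical contact stress sigma like a bed of springs (Winkler foundation)
with stiffness k = sigma / delta_z.  The classical estimate k = E/h ignores
lateral confinement; the Timoshenko finite-thickness correction gives
k_T = (E/h)(1 - nu^2), and an FE-calibrated correction factor alpha(nu)
closes the remaining gap:

    k = E / (h (1 - nu^2) alpha(nu)),   alpha(nu) = -12.50 nu^2 + 6.35 nu,

equivalently k = (E/h) * theta(nu) with theta = 1 / ((1 - nu^2) alpha).
For a laterally confined layer this reproduces the oedometric stiffness
M/h with M = E(1-nu)/((1+nu)(1-2nu)).

On top of the stiffness model sit the noise-to-deformation ratios used to
choose substrate modulus and thickness: psi_z (normal loading), psi_x
(shear loading) and the combined upper bound psi; designs target psi below
~10% so that measurement noise stays small against the deformations it has
to resolve.

Units: E, sigma, t in MPa; h in mm; noise eta in micrometres (converted to
mm internally); stiffness k in N/mm^3 (= MPa/mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

UM_TO_MM = 1.0e-3


class DesignDomainError(ValueError):
    """Raised when a design quantity is undefined for the given inputs."""


@dataclass(frozen=True)
class SubstrateSpec:
    """Deformable-layer geometry and small-strain stiffness."""

    E: float   # Young's modulus, MPa
    nu: float  # Poisson's ratio
    h: float   # layer thickness, mm

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")
        if self.h <= 0:
            raise ValueError("h must be positive")


@dataclass(frozen=True)
class LoadSpec:
    """Interfacial load level: normal contact stress and shear traction (MPa)."""

    sigma: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        if self.sigma < 0 or self.t < 0:
            raise ValueError("sigma and t must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Per-axis displacement measurement noise (micrometres)."""

    eta_x: float = 0.0
    eta_y: float = 0.0
    eta_z: float = 0.0

    def __post_init__(self):
        if min(self.eta_x, self.eta_y, self.eta_z) < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def eta_max(self) -> float:
        return max(self.eta_x, self.eta_y, self.eta_z)


def winkler_k(sub: SubstrateSpec) -> float:
    """Classical Winkler stiffness k = E/h (N/mm^3)."""
    return sub.E / sub.h


def timoshenko_k(sub: SubstrateSpec) -> float:
    """Finite-thickness corrected stiffness k_T = (E/h)(1 - nu^2)."""
    return (sub.E / sub.h) * (1.0 - sub.nu**2)


def alpha_poly(nu: float) -> float:
    """FE-calibrated correction factor alpha(nu) = -12.50 nu^2 + 6.35 nu."""
    if not 0.0 < nu < 0.5:
        raise DesignDomainError("nu must lie in (0, 0.5)")
    return -12.50 * nu**2 + 6.35 * nu


def alpha_closed_form(nu: float) -> float:
    """Closed-form oedometric correction (1+nu)(1-2nu)/((1-nu)(1-nu^2)).

    Equals [E/(h(1-nu^2))] / (M/h) for the confined-compression modulus M;
    serves as the analytical oracle for the FE calibration.
    """
    return (1.0 + nu) * (1.0 - 2.0 * nu) / ((1.0 - nu) * (1.0 - nu**2))


def oedometric_modulus(E: float, nu: float) -> float:
    """Confined-compression (oedometric) modulus M = E(1-nu)/((1+nu)(1-2nu))."""
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass
class AlphaCalibration:
    """Result of FE calibration of the Winkler correction factor alpha(nu)."""

    nu_grid: np.ndarray
    k_fe: np.ndarray          # effective stiffness sigma/delta_z per nu (N/mm^3)
    alpha: np.ndarray         # [E/(h(1-nu^2))] / k_fe
    coeffs: tuple[float, float]  # (a2, a1) of the fit a2*nu^2 + a1*nu
    r_squared: float

    def __call__(self, nu: float) -> float:
        a2, a1 = self.coeffs
        return a2 * nu**2 + a1 * nu


class CalibrationError(RuntimeError):
    pass


def calibrate_alpha(nu_grid: Sequence[float] = (0.30, 0.35, 0.40, 0.45),
                    E: float = 1.7, h: float = 0.3,
                    fe_solver: Callable[[float, float, float], float] | None = None,
                    ) -> AlphaCalibration:
    """Calibrate alpha(nu) from bonded-layer uniform-pressure FE solves.

    For each Poisson ratio a laterally confined layer (bottom fixed, side
    faces normal-fixed) is compressed by a uniform top pressure; the
    effective stiffness k_FE = sigma/delta_z is extracted and
    alpha = [E/(h(1-nu^2))]/k_FE fitted with a quadratic through the origin.

    ``fe_solver(E, nu, h) -> k_FE`` may be injected; the default runs the
    package's own hexahedral solver.
    """
    nu_grid = np.asarray(nu_grid, dtype=float)
    if np.any(nu_grid <= 0) or np.any(nu_grid >= 0.5):
        raise ValueError("nu grid must lie within (0, 0.5)")
    if fe_solver is None:
        from .fe import confined_layer_stiffness
        fe_solver = confined_layer_stiffness
    k_fe = []
    for nu in nu_grid:
        try:
            k_fe.append(fe_solver(E, float(nu), h))
        except Exception as exc:  # pragma: no cover - solver failure path
            raise CalibrationError(f"FE calibration failed at nu={nu}: {exc}") from exc
    k_fe = np.asarray(k_fe)
    alpha = (E / (h * (1.0 - nu_grid**2))) / k_fe
    # least squares a2*nu^2 + a1*nu, constrained through the origin
    X = np.column_stack([nu_grid**2, nu_grid])
    coeffs, *_ = np.linalg.lstsq(X, alpha, rcond=None)
    fit = X @ coeffs
    ss_res = float(np.sum((alpha - fit) ** 2))
    ss_tot = float(np.sum((alpha - alpha.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AlphaCalibration(nu_grid=nu_grid, k_fe=k_fe, alpha=alpha,
                            coeffs=(float(coeffs[0]), float(coeffs[1])), r_squared=r2)


def theta(nu: float, calibration: AlphaCalibration | None = None) -> float:
    """Unified stiffness coefficient theta(nu) = 1 / ((1 - nu^2) alpha(nu)).

    The modified foundation stiffness is k = (E/h) * theta(nu); with the
    default polynomial alpha this reproduces the FE-calibrated confined-layer
    stiffness (about 3.8x the naive E/h at nu = 0.45).
    """
    a = calibration(nu) if calibration is not None else alpha_poly(nu)
    if a <= 0:
        raise DesignDomainError(f"alpha(nu={nu}) = {a} is not positive")
    return 1.0 / ((1.0 - nu**2) * a)


def foundation_k(sub: SubstrateSpec, calibration: AlphaCalibration | None = None) -> float:
    """Modified Winkler stiffness k = (E/h) theta(nu) in N/mm^3."""
    return (sub.E / sub.h) * theta(sub.nu, calibration)


def psi_z(sub: SubstrateSpec, load: LoadSpec, noise: NoiseSpec) -> float:
    """Noise-to-deformation ratio in Z: eta_z * E * theta(nu) / (sigma * h)."""
    if load.sigma <= 0:
        raise DesignDomainError("psi_z undefined for sigma = 0")
    return noise.eta_z * UM_TO_MM * sub.E * theta(sub.nu) / (load.sigma * sub.h)


def psi_x(sub: SubstrateSpec, load: LoadSpec, noise: NoiseSpec) -> float:
    """Noise-to-deformation ratio in X under shear: eta_x G / (t h)."""
    if load.t <= 0:
        raise DesignDomainError("psi_x undefined for t = 0")
    G = sub.E / (2.0 * (1.0 + sub.nu))
    return noise.eta_x * UM_TO_MM * G / (load.t * sub.h)


def psi_bound(sub: SubstrateSpec, load: LoadSpec, noise: NoiseSpec) -> float:
    """Upper bound on the combined noise-to-deformation ratio psi.

    psi <= (E eta_max / h) sqrt(3 / (2 (2(1+nu) t)^2 + (sigma/theta)^2)),
    assuming equal in-plane deformations and per-axis noise <= eta_max.
    """
    denom = 2.0 * (2.0 * (1.0 + sub.nu) * load.t) ** 2 + (load.sigma / theta(sub.nu)) ** 2
    if denom <= 0:
        raise DesignDomainError("psi bound undefined: sigma and t both zero")
    return (sub.E * noise.eta_max * UM_TO_MM / sub.h) * math.sqrt(3.0 / denom)


def design_thickness(E: float, nu: float, load: LoadSpec, noise: NoiseSpec,
                     psi_target: float) -> float:
    """Smallest thickness h (mm) with psi_bound <= psi_target.

    The bound scales as 1/h, so the minimum is closed-form.
    """
    if not 0.0 < psi_target < 1.0:
        raise ValueError("psi_target must lie in (0, 1)")
    ref = SubstrateSpec(E=E, nu=nu, h=1.0)
    return psi_bound(ref, load, noise) / psi_target
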