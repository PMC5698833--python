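"""Forward mechanics of a fluid-filled hemispherical corneal shell.

The cornea is idealised as a thin, homogeneous, isotropic spherical shell of
radius ``R`` and uniform thickness ``t`` (the central corneal thickness),
clamped at the limbus (the equator) and filled with incompressible fluid at
pressure ``p`` (the intraocular pressure).  An air puff applies a resultant
force ``P`` at the apex.  At maximal deformation the apex region is inverted:
a mirror-image dimple of half-angle ``alpha`` hangs below the ridge circle at
polar angle ``alpha``.

The deformation is described by three ingredients (a Rayleigh--Ritz ansatz):

* the rigid dimple inversion itself, with apex travel
  ``Delta_1 = 2 R (1 - cos(alpha))`` and swept volume ``Delta_V1`` equal to
  minus twice the spherical-cap volume of depth ``Delta_1 / 2``;
* uniform membrane strains ``w_i`` (inverted cap) and ``w_o`` (outer shell),
  normalised as ``w_i_bar = w_i / R``, ``w_o_bar = w_o / R``, which stretch or
  shrink the two shell portions and move the apex by ``Delta_2``;
* narrow edge bending zones at the dimple ridge (a kink of angle ``2 alpha``
  shared by the cap edge and the outer-shell edge) and at the clamped limbus,
  which store bending energy ``UB`` and add the apex travel ``Delta_4``.

Equilibrium is the stationary point of the total potential

    Pi = US + UB + UP + Upr

with the membrane stretch energy ``US``, the edge bending energy ``UB``, the
work ``UP = -P (Delta_1 + Delta_2 + Delta_4)`` of the puff force and the work
``Upr = -p (Delta_V1 + ... + Delta_V4)`` of the fluid pressure.  The edge
bending energy is built from the classical spherical-shell edge-effect
(boundary-layer) influence coefficients: an edge at polar angle ``phi_e``
loaded by a horizontal force ``H`` and meridional moment ``M_phi`` responds
with

    h   = (2 mu R sin^2(phi_e) H + 2 mu^2 sin(phi_e) M_phi) / (E t)
    chi = (2 mu^2 sin(phi_e) H + 4 mu^3 M_phi / R) / (E t)

where ``mu = (3 (1 - nu^2))**0.25 * sqrt(R / t)`` is the edge-zone parameter;
``mu**2 = lam / 2`` with the shell slenderness ``lam = R / c`` and bending
length ``c = t / sqrt(12 (1 - nu^2))``.  Inverting these relations gives an
edge stiffness; the ridge absorbs the imposed kink ``2 alpha`` and the
horizontal mismatch ``R sin(alpha) (w_o_bar - w_i_bar)`` through its two edge
zones in series, while the clamped limbus suppresses the membrane edge
displacement ``R w_o_bar``.

Two load models are supported.  In the default (clinical) one the measured
IOP enters through the normalised pressure ``p_bar = p R^2 / (E t^2)`` and
the puff force is tied to it by the small-deformation equilibrium
``P_bar = 2 pi (1 - cos(alpha)) p_bar``; under that tie the load work terms
cancel from the apex-strain equation and the reduced equilibrium for
``(w_i_bar, w_o_bar)`` is a symmetric positive-definite 2x2 system.  In the
volume-conserving variant the puff force is prescribed and ``p_bar`` is the
unknown that keeps the enclosed fluid volume constant.

Units: geometry in mm, moduli in MPa, pressures in Pa at this module's
boundary (converted from mmHg by callers), forces in N, energies reported in
microjoule.  The normalised equilibrium depends only on the dimensionless
group ``(lam, alpha, nu, p_bar)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import ALPHA_MIN

__all__ = [
    "GeometryError",
    "InvalidPoissonError",
    "InvalidModulusError",
    "SingularGeometryError",
    "ConvergenceError",
    "ThinShellWarning",
    "ModelValidityWarning",
    "CornealGeometry",
    "NormalizedState",
    "Loads",
    "DeflectionBreakdown",
    "EnergyBreakdown",
    "BendingEdgeState",
    "derived_shell_params",
    "dimple_deflection",
    "dimple_volume",
    "stretch_energy",
    "pressure_drag",
    "bending_terms",
    "total_potential",
    "assemble_full_system",
    "equilibrium_force",
    "solve_reduced",
    "solve_volume_conserving",
    "total_deflection",
    "deflection_breakdown",
    "forward_deflection",
    "bending_edge_states",
]


class GeometryError(ValueError):
    """Inconsistent or nonphysical shell geometry."""


class InvalidPoissonError(GeometryError):
    """Poisson's ratio outside the physically admissible open interval."""


class InvalidModulusError(ValueError):
    """Nonpositive Young's modulus."""


class SingularGeometryError(GeometryError):
    """Dimple angle so small that the cot(alpha) edge terms are singular."""


class ConvergenceError(RuntimeError):
    """Equilibrium solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last scaled residual {residual:.3e})")
        self.residual = residual


class ThinShellWarning(UserWarning):
    """Shell is not thin (t/R >= 5%); membrane-theory accuracy degrades."""


class ModelValidityWarning(UserWarning):
    """Ridge kink 2*alpha at or beyond pi/3; neglected bending terms grow."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CornealGeometry:
    """Spherical-shell geometry of one cornea.

    Parameters
    ----------
    R : shell radius of curvature (mm).
    t : shell thickness (mm); clinical CCT in micrometres divided by 1000.
    alpha : meridional half-angle of the inverted dimple edge (rad).
    nu : Poisson's ratio (dimensionless), default 0.49.
    """

    R: float
    t: float
    alpha: float
    nu: float = 0.49

    def __post_init__(self) -> None:
        if not (self.nu > -1.0 and self.nu < 0.5):
            raise InvalidPoissonError(
                f"Poisson's ratio must lie in (-1, 0.5), got {self.nu}"
            )
        if not self.R > 0:
            raise GeometryError("shell radius R must be positive")
        if not self.t > 0:
            raise GeometryError("shell thickness t must be positive")
        if not (0.0 < self.alpha < math.pi / 2):
            raise GeometryError("dimple angle alpha must lie in (0, pi/2)")
        if self.t / self.R >= 0.05:
            warnings.warn(
                "shell is not thin: t/R >= 5%, membrane theory degrades",
                ThinShellWarning,
                stacklevel=2,
            )
        if 2.0 * self.alpha >= math.pi / 3:
            warnings.warn(
                "ridge kink 2*alpha >= pi/3: neglected bending energy grows",
                ModelValidityWarning,
                stacklevel=2,
            )

    @property
    def c(self) -> float:
        """Bending length c = t / sqrt(12 (1 - nu^2)) (mm)."""
        return self.t / math.sqrt(12.0 * (1.0 - self.nu**2))

    @property
    def lam(self) -> float:
        """Shell slenderness lam = R / c (dimensionless)."""
        return self.R / self.c

    @classmethod
    def from_clinical(
        cls, R_mm: float, cct_um: float, alpha_rad: float, nu: float = 0.49
    ) -> "CornealGeometry":
        """Build from clinical units (radius mm, CCT micrometres)."""
        return cls(R=R_mm, t=cct_um / 1000.0, alpha=alpha_rad, nu=nu)


@dataclass(frozen=True)
class NormalizedState:
    """Solution vector of the shell equilibrium.

    ``w_i_bar`` and ``w_o_bar`` are the normalised radial strain displacements
    of the inverted cap and the outer shell, ``p_bar = p R^2 / (E t^2)`` the
    normalised fluid pressure, and ``y3``/``y4`` the normalised ridge rotation
    and horizontal displacement (identically zero in the reduced model).
    """

    w_i_bar: float
    w_o_bar: float
    p_bar: float
    y3: float = 0.0
    y4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w_i_bar", "w_o_bar", "p_bar", "y3", "y4"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"NormalizedState.{name} must be finite")

    @property
    def dw_bar(self) -> float:
        """Strain mismatch across the ridge, dw_bar = w_o_bar - w_i_bar."""
        return self.w_o_bar - self.w_i_bar


@dataclass(frozen=True)
class Loads:
    """Apex force and fluid pressure, physical and normalised.

    ``P`` in newton, ``p`` in pascal, ``P_bar = P / (E t^2)`` and
    ``p_star = P_bar / (2 pi) - (1 - cos(alpha)) p_bar``; ``p_star`` vanishes
    identically when the small-deformation force tie is imposed.
    """

    P: float
    p: float
    P_bar: float
    p_bar: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.p < 0:
            raise ValueError("loads must be nonnegative")

    def p_star(self, alpha: float) -> float:
        return self.P_bar / (2.0 * math.pi) - (1.0 - math.cos(alpha)) * self.p_bar


def make_loads(
    geom: CornealGeometry, P_newton: float, p_pascal: float, E_mpa: float
) -> Loads:
    """Build :class:`Loads` for a geometry, normalising by ``E t^2`` (and
    ``R^2`` for the pressure)."""
    E_pa = E_mpa * 1e6
    t_m = geom.t * 1e-3
    R_m = geom.R * 1e-3
    et2 = E_pa * t_m**2
    return Loads(
        P=P_newton,
        p=p_pascal,
        P_bar=P_newton / et2,
        p_bar=p_pascal * R_m**2 / et2,
    )


@dataclass(frozen=True)
class DeflectionBreakdown:
    """Apex-deflection components (mm) and volume changes (mm^3)."""

    d1: float
    d2: float
    d4: float
    dv1: float
    dv2: float
    dv3: float
    dv4: float

    @property
    def total(self) -> float:
        """Total apex deflection Delta = Delta_1 + Delta_2 + Delta_4 (mm)."""
        return self.d1 + self.d2 + self.d4

    @property
    def volume_residual(self) -> float:
        """Net enclosed-volume change (mm^3); ~0 in volume-conserving mode."""
        return self.dv1 + self.dv2 + self.dv3 + self.dv4


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential-energy components in microjoule."""

    US: float
    UB: float
    UP: float
    Upr: float

    @property
    def Pi_total(self) -> float:
        return self.US + self.UB + self.UP + self.Upr


@dataclass(frozen=True)
class BendingEdgeState:
    """Edge-zone loads and displacements at one bending edge.

    ``M_phi`` is the meridional edge moment per unit length (N), ``H`` the
    horizontal edge force per unit length (N/m), ``chi`` the edge rotation
    (rad), ``h`` the horizontal edge displacement (mm) and ``phi_e`` the
    meridional edge angle, one of alpha, pi - alpha, pi/2.
    """

    M_phi: float
    H: float
    chi: float
    h: float
    phi_e: float


# --------------------------------------------------------------------------
# elementary components


def derived_shell_params(geom: CornealGeometry) -> tuple[float, float]:
    """Return the bending length ``c`` (mm) and slenderness ``lam = R/c``."""
    return geom.c, geom.lam


def dimple_deflection(geom: CornealGeometry) -> float:
    """Apex travel of the rigid mirror inversion, ``2 R (1 - cos(alpha))``
    (mm)."""
    return 2.0 * geom.R * (1.0 - math.cos(geom.alpha))


def dimple_volume(geom: CornealGeometry, d1: float | None = None) -> float:
    """Volume swept by the dimple inversion (mm^3, negative).

    Equals minus twice the spherical-cap volume of depth ``d1 / 2`` on a
    sphere of radius ``R``; in closed form ``-pi R d1^2 (6 - d1/R) / 12``.
    """
    if d1 is None:
        d1 = dimple_deflection(geom)
    if d1 < 0 or d1 > 2.0 * geom.R:
        raise GeometryError("dimple depth d1 must lie in [0, 2R]")
    return -math.pi * geom.R * d1**2 * (6.0 - d1 / geom.R) / 12.0


def stretch_energy(
    geom: CornealGeometry, E_mpa: float, state: NormalizedState
) -> float:
    """Membrane stretch energy (microjoule).

    ``US = 2 pi E t R^2 / (1 - nu) * (w_i_bar^2 (1 - cos a) + w_o_bar^2 cos a)``
    from equibiaxial strains ``w_bar`` on the cap (polar angle 0..alpha) and
    the outer shell (alpha..pi/2).
    """
    a = geom.alpha
    E_pa = E_mpa * 1e6
    pref = 2.0 * math.pi * E_pa * (geom.t * 1e-3) * (geom.R * 1e-3) ** 2
    us = (
        pref
        / (1.0 - geom.nu)
        * (
            state.w_i_bar**2 * (1.0 - math.cos(a))
            + state.w_o_bar**2 * math.cos(a)
        )
    )
    return us * 1e6


def pressure_drag(
    geom: CornealGeometry, state: NormalizedState
) -> tuple[float, float, float]:
    """Strain-induced apex travel and the two membrane volume changes.

    Returns ``(d2, dv2, dv3)``: the apex moves by
    ``Delta_2 = R (w_i_bar (1 - cos a) - w_o_bar cos a)`` (mm) as the ridge
    circle rides on the strained outer shell; the cap sweep changes the
    volume by ``Delta_V2 = -2 pi R^2 Delta_2 (1 - cos a)`` and the outer
    swelling adds ``Delta_V3 = 2 pi R^3 w_o_bar cos a`` (mm^3).
    """
    a = geom.alpha
    d2 = geom.R * (
        state.w_i_bar * (1.0 - math.cos(a)) - state.w_o_bar * math.cos(a)
    )
    dv2 = -2.0 * math.pi * geom.R**2 * d2 * (1.0 - math.cos(a))
    dv3 = 2.0 * math.pi * geom.R**3 * state.w_o_bar * math.cos(a)
    return d2, dv2, dv3


def _d4_coefficient(geom: CornealGeometry, delta4_form: str) -> float:
    if delta4_form == "lam_scaled":
        return geom.lam * math.sqrt(2.0) / 4.0
    if delta4_form == "unscaled":
        return math.sqrt(2.0) / 4.0
    raise ValueError(f"unknown delta4_form {delta4_form!r}")


def bending_terms(
    geom: CornealGeometry,
    E_mpa: float,
    state: NormalizedState,
    delta4_form: str = "lam_scaled",
) -> tuple[float, float, float]:
    """Edge bending energy, bending apex travel and its volume change.

    Returns ``(UB, d4, dv4)`` with UB in microjoule, d4 in mm, dv4 in mm^3.

    With ``y3 = y4 = 0`` the bending energy reduces to the quadratic
    boundary-layer form

        UB = (pi E t R^2 sin a / 2) * ( sqrt(2/lam) dw^2 - (4 a / lam) dw
             + 2 (2/lam)**1.5 a^2 )  +  pi E t R^2 sqrt(2/lam) w_o_bar^2

    (``dw = w_o_bar - w_i_bar``): the first group is the ridge kink ``2 a``
    and horizontal mismatch ``R sin(a) dw`` pushed through the two edge zones
    in series, the last term the clamped-limbus zone.  UB is linear in E.
    The apex travel of the bent edges is ``d4 = -R (lam sqrt(2)/4) w_o_bar^2``
    (configurable: ``delta4_form="unscaled"`` drops lam) and
    ``dv4 = -2 pi R^2 d4 (1 - cos a)``.
    """
    a = geom.alpha
    lam = geom.lam
    dw = state.dw_bar
    E_pa = E_mpa * 1e6
    pref = math.pi * E_pa * (geom.t * 1e-3) * (geom.R * 1e-3) ** 2
    ridge = (
        pref
        * math.sin(a)
        / 2.0
        * (
            math.sqrt(2.0 / lam) * dw**2
            - (4.0 * a / lam) * dw
            + 2.0 * (2.0 / lam) ** 1.5 * a**2
        )
    )
    limbus = pref * math.sqrt(2.0 / lam) * state.w_o_bar**2
    ub = (ridge + limbus) * 1e6
    d4 = -geom.R * _d4_coefficient(geom, delta4_form) * state.w_o_bar**2
    dv4 = -2.0 * math.pi * geom.R**2 * d4 * (1.0 - math.cos(a))
    return ub, d4, dv4


def deflection_breakdown(
    geom: CornealGeometry,
    state: NormalizedState,
    delta4_form: str = "lam_scaled",
) -> DeflectionBreakdown:
    """Assemble all deflection and volume components for a state."""
    d1 = dimple_deflection(geom)
    dv1 = dimple_volume(geom, d1)
    d2, dv2, dv3 = pressure_drag(geom, state)
    # d4/dv4 are purely geometric; reuse bending_terms with E = 1.
    _, d4, dv4 = bending_terms(geom, 1.0, state, delta4_form)
    return DeflectionBreakdown(d1=d1, d2=d2, d4=d4, dv1=dv1, dv2=dv2, dv3=dv3, dv4=dv4)


def total_deflection(
    geom: CornealGeometry,
    state: NormalizedState,
    delta4_form: str = "lam_scaled",
) -> float:
    """Total apex deflection ``Delta = Delta_1 + Delta_2 + Delta_4`` (mm)."""
    return deflection_breakdown(geom, state, delta4_form).total


def total_potential(
    geom: CornealGeometry,
    E_mpa: float,
    loads: Loads,
    state: NormalizedState,
    delta4_form: str = "lam_scaled",
) -> EnergyBreakdown:
    """Total potential energy breakdown (microjoule).

    ``UP = -P (Delta_1 + Delta_2 + Delta_4)`` and
    ``Upr = -p (Delta_V1 + Delta_V2 + Delta_V3 + Delta_V4)``.
    """
    us = stretch_energy(geom, E_mpa, state)
    ub, _, _ = bending_terms(geom, E_mpa, state, delta4_form)
    br = deflection_breakdown(geom, state, delta4_form)
    up = -loads.P * br.total * 1e-3 * 1e6  # N * m -> J -> uJ
    upr = -loads.p * br.volume_residual * 1e-9 * 1e6  # Pa * m^3 -> J -> uJ
    return EnergyBreakdown(US=us, UB=ub, UP=up, Upr=upr)


# --------------------------------------------------------------------------
# normalised equilibrium


def equilibrium_force(alpha: float, p_bar: float) -> float:
    """Small-deformation force tie ``P_bar = 2 pi (1 - cos(alpha)) p_bar``."""
    if not (0.0 <= alpha < math.pi / 2):
        raise GeometryError("alpha must lie in [0, pi/2)")
    return 2.0 * math.pi * (1.0 - math.cos(alpha)) * p_bar


def _check_alpha(geom: CornealGeometry, alpha_min: float) -> None:
    if geom.alpha < alpha_min:
        raise SingularGeometryError(
            f"alpha = {geom.alpha:.2e} rad below the cot(alpha) guard "
            f"{alpha_min:.0e}"
        )


def reduced_system(
    geom: CornealGeometry, p_bar: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled 2x2 equilibrium for ``(w_i_bar, w_o_bar)`` under the force tie.

    The stationarity conditions of the reconstructed potential, divided by
    the common factor ``2 pi E t R^2 sin(a) sqrt(2/lam)``, read ``M w = b``
    with the symmetric positive-definite

        M = [[ 1/2 + G (1 - cos a)/sin a ,  -1/2                          ],
             [ -1/2                      ,  1/2 + 1/sin a + G cos a/sin a ]]

    where ``G = sqrt(2 lam) / (1 - nu)``, and

        b = [ -a / sqrt(2 lam),
              +a / sqrt(2 lam) + (t/c) cot(a) p_bar / sqrt(2 lam) ].

    Under the force tie the load work cancels exactly from the first row and
    the quadratic edge-travel terms cancel between ``UP`` and ``Upr``, so the
    system is linear.
    """
    a = geom.alpha
    lam = geom.lam
    sa, ca = math.sin(a), math.cos(a)
    G = math.sqrt(2.0 * lam) / (1.0 - geom.nu)
    toc = geom.t / geom.c  # = sqrt(12 (1 - nu^2))
    M = np.array(
        [
            [0.5 + G * (1.0 - ca) / sa, -0.5],
            [-0.5, 0.5 + 1.0 / sa + G * ca / sa],
        ]
    )
    root = math.sqrt(2.0 * lam)
    b = np.array(
        [
            -a / root,
            a / root + toc * (ca / sa) * p_bar / root,
        ]
    )
    return M, b


def solve_reduced(
    geom: CornealGeometry,
    p_bar: float,
    tol: float = 1e-10,
    max_iter: int = 200,
    alpha_min: float = ALPHA_MIN,
) -> NormalizedState:
    """Solve the reduced equilibrium for ``(w_i_bar, w_o_bar)``.

    Damped Newton iteration on the scaled residual ``F(w) = M w - b`` from
    zero initial strains, halving the step whenever the residual grows;
    raises :class:`ConvergenceError` if the scaled residual does not fall
    below ``tol`` within ``max_iter`` iterations.  (On the tied, linear
    system Newton converges in a single full step; the damping machinery
    matters for the nonlinear volume-conserving variant which shares it.)
    """
    if p_bar < 0:
        raise ValueError("p_bar must be nonnegative")
    _check_alpha(geom, alpha_min)
    M, b = reduced_system(geom, p_bar)
    scale = max(1.0, float(np.linalg.norm(b)))

    def residual(w: np.ndarray) -> np.ndarray:
        return M @ w - b

    w = np.zeros(2)
    res = residual(w)
    res_norm = float(np.linalg.norm(res)) / scale
    for _ in range(max_iter):
        if res_norm < tol:
            return NormalizedState(
                w_i_bar=float(w[0]), w_o_bar=float(w[1]), p_bar=p_bar
            )
        step = np.linalg.solve(M, -res)
        damping = 1.0
        while True:
            w_new = w + damping * step
            res_new = residual(w_new)
            new_norm = float(np.linalg.norm(res_new)) / scale
            if new_norm < res_norm or damping < 1e-8:
                break
            damping *= 0.5
        w, res, res_norm = w_new, res_new, new_norm
    if res_norm < tol:
        return NormalizedState(w_i_bar=float(w[0]), w_o_bar=float(w[1]), p_bar=p_bar)
    raise ConvergenceError("reduced equilibrium did not converge", res_norm)


def _scaled_gradient_untied(
    geom: CornealGeometry,
    P_bar: float,
    p_bar: float,
    wi: float,
    wo: float,
    delta4_form: str = "lam_scaled",
) -> tuple[float, float]:
    """Scaled stationarity residuals with independent puff force and
    pressure (no force tie); used by the volume-conserving solve and the
    full-system assembly."""
    a = geom.alpha
    sa, ca = math.sin(a), math.cos(a)
    one_m = 1.0 - ca
    lam = geom.lam
    root2lam = math.sqrt(2.0 * lam)
    coef = _d4_coefficient(geom, delta4_form)
    M, _ = reduced_system(geom, p_bar)
    # bending forcing (independent of loads)
    b1_bend = -a / root2lam
    b2_bend = a / root2lam
    # load gradients / (2 pi E t R^2 sin a sqrt(2/lam))
    toR = geom.t / geom.R
    denom = sa * math.sqrt(2.0 / lam)
    load_i = toR * one_m * (one_m * p_bar - P_bar / (2.0 * math.pi)) / denom
    load_o = (
        toR
        * (
            P_bar * ca / (2.0 * math.pi)
            + P_bar * coef * wo / math.pi
            - p_bar * ca * (2.0 - ca)
            - 2.0 * p_bar * one_m * coef * wo
        )
        / denom
    )
    g1 = M[0, 0] * wi + M[0, 1] * wo - b1_bend + load_i
    g2 = M[1, 0] * wi + M[1, 1] * wo - b2_bend + load_o
    return g1, g2


def _volume_residual_normalized(
    geom: CornealGeometry, wi: float, wo: float, delta4_form: str = "lam_scaled"
) -> float:
    """Net volume change divided by ``2 pi R^3``."""
    ca = math.cos(geom.alpha)
    one_m = 1.0 - ca
    coef = _d4_coefficient(geom, delta4_form)
    dv1 = -(one_m**2 - one_m**3 / 3.0)
    dv2 = -one_m * (wi * one_m - wo * ca)
    dv3 = wo * ca
    dv4 = one_m * coef * wo**2
    return dv1 + dv2 + dv3 + dv4


def solve_volume_conserving(
    geom: CornealGeometry,
    P_bar: float,
    delta4_form: str = "lam_scaled",
    tol: float = 1e-10,
    alpha_min: float = ALPHA_MIN,
) -> NormalizedState:
    """Equilibrium with the fluid pressure as unknown.

    Solves the two stationarity conditions together with exact conservation
    of the incompressible fluid volume for ``(w_i_bar, w_o_bar, p_bar)``
    given the normalised puff force ``P_bar``.  The swelling of the outer
    shell must re-absorb the volume swept by the dimple, so this variant is
    dominated by the inversion geometry; it is exposed for sensitivity
    studies, not as the clinical default.
    """
    _check_alpha(geom, alpha_min)

    def fun(z: np.ndarray) -> list[float]:
        wi, wo, pb = z
        g1, g2 = _scaled_gradient_untied(geom, P_bar, pb, wi, wo, delta4_form)
        vol = _volume_residual_normalized(geom, wi, wo, delta4_form)
        return [g1, g2, vol]

    sol = optimize.root(fun, x0=[0.0, 0.02, 1.0], tol=tol, method="hybr")
    if not sol.success:
        raise ConvergenceError(
            "volume-conserving equilibrium did not converge",
            float(np.linalg.norm(sol.fun)),
        )
    wi, wo, pb = sol.x
    return NormalizedState(w_i_bar=float(wi), w_o_bar=float(wo), p_bar=float(pb))


def assemble_full_system(
    geom: CornealGeometry,
    loads: Loads,
    state: NormalizedState,
    delta4_form: str = "lam_scaled",
    alpha_min: float = ALPHA_MIN,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the 5x5 equilibrium ``A Z = BL + BNL`` for
    ``Z = (w_i_bar, w_o_bar, p_bar, y3, y4)``.

    Rows 1-2 are the scaled stationarity conditions with the pressure column
    kept on the left; row 3 is the fluid-volume balance (its ``w_o_bar``
    column carries the characteristic ``cos(a) (2 - cos(a))`` membrane-sweep
    factor); rows 4-5 tie the edge unknowns to the force imbalance
    ``p_star = P_bar/(2 pi) - (1 - cos a) p_bar`` and vanish identically when
    the small-deformation force tie holds, which is what makes
    ``y3 = y4 = 0`` consistent.  The edge-unknown rows are a structural
    transcription and are experimental: the coupled 5-unknown solve is not on
    the clinical path.

    ``BL`` collects the load- and geometry-linear forcing, ``BNL`` the
    state-dependent (nonlinear) forcing, both evaluated at ``state``.
    """
    _check_alpha(geom, alpha_min)
    a = geom.alpha
    sa, ca = math.sin(a), math.cos(a)
    one_m = 1.0 - ca
    lam = geom.lam
    root2lam = math.sqrt(2.0 * lam)
    coef = _d4_coefficient(geom, delta4_form)
    toR = geom.t / geom.R
    toc = geom.t / geom.c
    denom = sa * math.sqrt(2.0 / lam)
    M, _ = reduced_system(geom, 0.0)

    A = np.zeros((5, 5))
    BL = np.zeros(5)
    BNL = np.zeros(5)

    # apex-strain rows: pressure column on the left, puff force in BL
    A[0, :2] = M[0]
    A[0, 2] = toR * one_m**2 / denom
    BL[0] = -a / root2lam + toR * one_m * (loads.P_bar / (2.0 * math.pi)) / denom

    A[1, :2] = M[1]
    A[1, 2] = -toR * ca * (2.0 - ca) / denom
    BL[1] = a / root2lam - toR * ca * (loads.P_bar / (2.0 * math.pi)) / denom
    p_star = loads.p_star(a)
    BNL[1] = -2.0 * toR * coef * p_star * state.w_o_bar / denom

    # fluid-volume row (divided by 2 pi R^3)
    A[2, 0] = -(one_m**2)
    A[2, 1] = ca * (2.0 - ca)
    BL[2] = one_m**2 - one_m**3 / 3.0
    BNL[2] = -one_m * coef * state.w_o_bar**2

    # edge-unknown rows (experimental structural transcription)
    A[3, 3] = 1.0
    A[4, 4] = 1.0
    BNL[3] = toc * lam * a**2 * p_star / (2.0 * math.sqrt(2.0) * sa**2)
    BNL[4] = -toc * state.dw_bar * p_star / (4.0 * math.sqrt(2.0) * sa**2)

    return A, BL, BNL


def forward_deflection(
    geom: CornealGeometry,
    E_mpa: float,
    p_pascal: float,
    delta4_form: str = "lam_scaled",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Total apex deflection (mm) for a modulus and an internal pressure.

    Forms ``p_bar = p R^2 / (E t^2)``, solves the reduced equilibrium and
    assembles ``Delta``.  ``Delta`` is strictly increasing in E at fixed
    pressure: a stiffer shell strains less, so the strain corrections
    ``Delta_2 + Delta_4 <= 0`` shrink and ``Delta`` approaches the rigid
    inversion travel ``Delta_1`` from below.
    """
    if E_mpa <= 0:
        raise InvalidModulusError("Young's modulus must be positive")
    if p_pascal < 0:
        raise ValueError("internal pressure must be nonnegative")
    p_bar = p_pascal * geom.R**2 / (E_mpa * 1e6 * geom.t**2)
    state = solve_reduced(geom, p_bar, tol=tol, max_iter=max_iter)
    return total_deflection(geom, state, delta4_form)


def bending_edge_states(
    geom: CornealGeometry, state: NormalizedState
) -> tuple[BendingEdgeState, BendingEdgeState, BendingEdgeState]:
    """Edge-zone loads at the three bending edges (ridge pair and limbus).

    The ridge kink ``2 alpha`` and horizontal mismatch ``R sin(a) dw_bar``
    are split equally between the cap-side (``phi_e = alpha``) and
    shell-side (``phi_e = pi - alpha``) edge zones, which carry a common
    ``(H, M_phi)`` pair; the limbus zone (``phi_e = pi/2``) suppresses the
    membrane edge displacement ``R w_o_bar``.  Loads are per unit edge
    length in SI (H in N/m, M_phi in N), displacements in mm and rad.
    Forces are proportional to E; they are reported per unit modulus
    (divide-by-E normalisation) so the state alone determines them.
    """
    a = geom.alpha
    mu = math.sqrt(geom.lam / 2.0)
    R_m = geom.R * 1e-3
    t_m = geom.t * 1e-3

    def stiffness(phi: float) -> np.ndarray:
        s = math.sin(phi)
        # inverse of the edge influence (compliance) matrix, per unit E
        C = np.array(
            [[2.0 * mu * R_m * s**2, 2.0 * mu**2 * s], [2.0 * mu**2 * s, 4.0 * mu**3 / R_m]]
        ) / t_m
        return np.linalg.inv(C)

    h_ridge_m = R_m * math.sin(a) * state.dw_bar
    v_side = np.array([h_ridge_m / 2.0, a])  # each zone takes half the kink
    HM = stiffness(a) @ v_side
    cap = BendingEdgeState(
        M_phi=float(HM[1]), H=float(HM[0]), chi=a, h=h_ridge_m / 2.0 * 1e3,
        phi_e=a,
    )
    shell = BendingEdgeState(
        M_phi=float(HM[1]), H=float(HM[0]), chi=a, h=h_ridge_m / 2.0 * 1e3,
        phi_e=math.pi - a,
    )
    h_limb_m = R_m * state.w_o_bar
    HM_l = stiffness(math.pi / 2.0) @ np.array([h_limb_m, 0.0])
    limbus = BendingEdgeState(
        M_phi=float(HM_l[1]), H=float(HM_l[0]), chi=0.0, h=h_limb_m * 1e3,
        phi_e=math.pi / 2.0,
    )
    return cap, shell, limbus
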