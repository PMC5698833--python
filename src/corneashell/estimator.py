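"""Inverse problem: corneal Young's modulus from one tonometry record.

Given the measured IOP, radius ``R``, central corneal thickness, maximal
apex deflection ``delta`` and dimple half-angle ``alpha``, the estimator
finds the modulus ``E`` whose forward-model deflection matches ``delta``.
Because the model deflection is strictly monotone in ``E`` (it rises towards
the rigid-inversion travel ``Delta_1`` as the shell stiffens), the match is
found by bounded root bracketing on ``log E``; a constrained
sequential-quadratic-programming minimisation of ``|Delta - delta|`` is kept
as a fallback for bracketing failures.  The pressure-stiffening (effective
modulus) correction ``E' = E + T`` with the Rayleigh tension term
``T = p R / (2 t)`` is applied afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import MMHG_TO_PA, RunConfig
from .core_model import (
    CornealGeometry,
    GeometryError,
    dimple_deflection,
    forward_deflection,
    solve_volume_conserving,
    total_deflection,
)
from .geometry import puff_force

__all__ = [
    "MeasurementRecord",
    "ModulusEstimate",
    "ImpossibleDeflectionError",
    "estimate_modulus",
    "rayleigh_correction",
]


class ImpossibleDeflectionError(GeometryError):
    """Measured deflection exceeds the shell diameter."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One subject's tonometry-derived quantities.

    ``iop`` in mmHg, ``R`` in mm, ``cct`` in micrometres, ``delta`` (maximal
    apex deflection) in mm, ``alpha`` in rad, optional ``age`` in years.
    """

    iop: float
    R: float
    cct: float
    delta: float
    alpha: float
    age: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if not self.iop > 0:
            raise ValueError("IOP must be positive")
        if not self.delta > 0:
            raise ValueError("deflection must be positive")
        if not (0.0 < self.alpha < math.pi / 2):
            raise ValueError("alpha must lie in (0, pi/2)")
        if not (300.0 <= self.cct <= 800.0):
            warnings.warn(
                "CCT outside the 300-800 um plausibility band",
                UserWarning,
                stacklevel=2,
            )

    def geometry(self, nu: float = 0.49) -> CornealGeometry:
        return CornealGeometry.from_clinical(self.R, self.cct, self.alpha, nu)


@dataclass(frozen=True)
class ModulusEstimate:
    """Result of one inverse solve.

    ``E`` is the fitted Young's modulus (MPa), ``T`` the pressure tension
    term and ``E_eff = E + T`` the effective modulus (MPa); ``residual`` is
    ``|Delta - delta|`` at the optimum (mm).
    """

    E: float
    T: float
    E_eff: float
    residual: float
    n_iter: int
    converged: bool
    id: str = ""

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("estimated modulus must be positive")
        if self.residual < 0:
            raise ValueError("residual must be nonnegative")


def rayleigh_correction(
    E_mpa: float,
    p_mmhg: float,
    R_mm: float,
    t_um: float,
    mmhg_to_pa: float = MMHG_TO_PA,
) -> tuple[float, float]:
    """Pressure-stiffening correction ``(T, E_eff)`` in MPa.

    The intraocular pressure pre-tensions the shell wall; following
    Rayleigh's classical treatment of pressurised shells the stress
    stiffening adds the membrane tension term ``T = p R / (2 t)`` to the
    material modulus, giving the effective modulus ``E' = E + T``.
    """
    if t_um <= 0:
        raise ZeroDivisionError("thickness must be positive")
    if min(E_mpa, p_mmhg, R_mm) < 0:
        raise ValueError("inputs must be nonnegative")
    T_pa = p_mmhg * mmhg_to_pa * (R_mm * 1e-3) / (2.0 * t_um * 1e-6)
    T = T_pa / 1e6
    return T, E_mpa + T


def _forward_mm(
    geom: CornealGeometry, E_mpa: float, p_pascal: float, cfg: RunConfig
) -> float:
    return forward_deflection(
        geom,
        E_mpa,
        p_pascal,
        delta4_form=cfg.delta4_form,
        tol=cfg.solver_tol,
        max_iter=cfg.max_iter,
    )


def _forward_volume_mode(
    geom: CornealGeometry, E_mpa: float, cfg: RunConfig
) -> float:
    """Deflection in the volume-conserving load model: the puff force is
    computed from the standard jet parameters and the pressure is solved."""
    P = puff_force(
        geom.R,
        geom.alpha,
        puff_pressure_mmhg=cfg.puff_mmhg,
        area_factor=cfg.area_factor,
        mmhg_to_pa=cfg.mmhg_to_pa,
    )
    P_bar = P / (E_mpa * 1e6 * (geom.t * 1e-3) ** 2)
    state = solve_volume_conserving(
        geom, P_bar, delta4_form=cfg.delta4_form, tol=cfg.solver_tol
    )
    return total_deflection(geom, state, cfg.delta4_form)


def estimate_modulus(
    meas: MeasurementRecord, cfg: RunConfig | None = None
) -> ModulusEstimate:
    """Recover the Young's modulus matching one measurement record.

    Minimises ``|Delta(E) - delta|`` over ``E`` in
    ``[cfg.e_lo_mpa, cfg.e_hi_mpa]``.  The search runs in ``log E`` (the
    plausible band spans decades) and exploits the monotonicity of
    ``Delta(E)`` by Brent root bracketing; if no sign change brackets the
    root — the measured deflection lies outside the model's reachable range
    — the estimate is pinned at the nearer bound with ``converged=False``
    rather than raising.  A bounded SQP-style minimisation is the fallback
    when bracketing itself fails.  Deterministic given the configuration.
    """
    cfg = cfg or RunConfig()
    if meas.delta > 2.0 * meas.R:
        raise ImpossibleDeflectionError(
            f"deflection {meas.delta} mm exceeds the shell diameter"
        )
    geom = meas.geometry(cfg.nu)
    p_pa = meas.iop * cfg.mmhg_to_pa

    if cfg.load_model == "volume_conserving":
        def delta_of(E: float) -> float:
            return _forward_volume_mode(geom, E, cfg)
    else:
        def delta_of(E: float) -> float:
            return _forward_mm(geom, E, p_pa, cfg)

    lo, hi = cfg.e_lo_mpa, cfg.e_hi_mpa
    f_lo = delta_of(lo) - meas.delta
    f_hi = delta_of(hi) - meas.delta
    n_iter = 2

    def pinned(E: float, f: float, n: int) -> ModulusEstimate:
        T, e_eff = rayleigh_correction(E, meas.iop, meas.R, meas.cct, cfg.mmhg_to_pa)
        resid = abs(f)
        return ModulusEstimate(
            E=E, T=T, E_eff=e_eff, residual=resid, n_iter=n,
            converged=resid < cfg.residual_tol_mm, id=meas.id,
        )

    if f_lo == 0.0:
        return pinned(lo, 0.0, n_iter)
    if f_hi == 0.0:
        return pinned(hi, 0.0, n_iter)
    if f_lo * f_hi > 0:
        # target outside the reachable deflection range: pin at the nearer
        # bound (measured against the residual)
        if abs(f_lo) < abs(f_hi):
            return pinned(lo, f_lo, n_iter)
        return pinned(hi, f_hi, n_iter)

    def g(logE: float) -> float:
        return delta_of(math.exp(logE)) - meas.delta

    try:
        log_root, info = optimize.brentq(
            g,
            math.log(lo),
            math.log(hi),
            xtol=1e-12,
            full_output=True,
        )
        E_hat = math.exp(log_root)
        n_iter += int(info.iterations)
    except (RuntimeError, ValueError):
        # SQP-style constrained fallback on |Delta - delta|
        res = optimize.minimize(
            lambda z: abs(g(float(z[0]))),
            x0=[math.log(math.sqrt(lo * hi))],
            bounds=[(math.log(lo), math.log(hi))],
            method="SLSQP",
        )
        E_hat = math.exp(float(res.x[0]))
        n_iter += int(res.nit)
    return pinned(E_hat, delta_of(E_hat) - meas.delta, n_iter)
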