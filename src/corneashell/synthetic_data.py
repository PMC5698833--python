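"""Synthetic cohorts and profiles standing in for patient data.

No patient measurements ship with the package, so everything the cohort
would have provided is generated here: noise-free (optionally pixel-
quantised) corneal profile pairs produced by running the forward shell
model, and cohort tables with the covariate distributions and the
IOP-regression structure typical of a healthy noncontact-tonometry
population (subject counts, CCT/radius/modulus means and spreads, and a
linear IOP model in age, CCT and modulus).

All randomness flows through one seeded ``numpy`` generator per call; no
global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MMHG_TO_PA
from .core_model import CornealGeometry, forward_deflection
from .geometry import ProfilePoints, pixelate

__all__ = ["CohortSpec", "simulate_profile", "simulate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Distributional recipe for one synthetic cohort.

    Covariates are drawn from truncated Gaussians (resampling out-of-band
    draws); IOP is generated from the linear model
    ``intercept + b_age * age + b_cct * CCT + b_E * E + N(0, resid_sd)``.
    Defaults emulate a healthy adult cohort: CCT 543 +/- 38 um, radius
    7.17 +/- 1.25 mm, modulus 0.208 +/- 0.079 MPa (spreads derived from
    95% confidence bands via sd = width / 3.92), age 35 +/- 15 years
    truncated at 5, and the published-style IOP coefficients
    (0.034, 0.036, 8.922) about an intercept of -8.106 mmHg with a residual
    sd of 3.18 mmHg chosen so the generated IOP spread matches the cohort's.
    The dimple half-angle is drawn tightly around pi/6; the deflection
    ``delta`` of every record is computed by the forward model (optionally
    quantised to ``pixel``), so records are self-consistent.
    """

    n: int = 100
    seed: int = 0
    age_mean: float = 35.0
    age_sd: float = 15.0
    age_min: float = 5.0
    cct_mean: float = 543.1
    cct_sd: float = 38.0
    r_mean: float = 7.17
    r_sd: float = 1.25
    e_mean: float = 0.208
    e_sd: float = 0.079
    alpha_mean: float = math.pi / 6
    alpha_sd: float = 0.02
    iop_intercept: float = -8.106
    iop_age: float = 0.034
    iop_cct: float = 0.036
    iop_e: float = 8.922
    iop_resid_sd: float = 3.18
    nu: float = 0.49
    pixel: float | None = None

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("cohort size n must be positive")
        for name in ("age_sd", "cct_sd", "r_sd", "e_sd", "alpha_sd", "iop_resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"CohortSpec.{name} must be nonnegative")


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Gaussian draws with out-of-band values resampled."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_profile(
    geom: CornealGeometry,
    E_mpa: float,
    p_mmhg: float,
    pixel: float | None = None,
    span_rad: float = 0.9,
    spacing_mm: float = 0.004,
    delta4_form: str = "lam_scaled",
    mmhg_to_pa: float = MMHG_TO_PA,
) -> tuple[ProfilePoints, ProfilePoints]:
    """Generate an undeformed/deformed anterior-profile pair.

    The undeformed profile is the circular arc of radius ``R`` spanning
    polar angles up to ``span_rad``; the deformed one subtracts a dimple of
    apex depth ``delta`` (from the forward model) shaped like the scaled
    mirror inversion, vanishing exactly at the ridge ``|x| = R sin(alpha)``.
    The sampling grid contains ``x = 0`` and the ridge abscissae exactly, so
    noise-free extraction round-trips ``(R, alpha, delta)`` to numerical
    precision; with ``pixel`` set both profiles are quantised afterwards.
    """
    if span_rad <= geom.alpha or span_rad >= math.pi / 2:
        raise ValueError("span must exceed alpha and stay below pi/2")
    delta = forward_deflection(
        geom, E_mpa, p_mmhg * mmhg_to_pa, delta4_form=delta4_form
    )
    R, alpha = geom.R, geom.alpha
    x_ridge = R * math.sin(alpha)
    x_max = R * math.sin(span_rad)
    n = max(int(math.ceil(x_max / spacing_mm)) + 1, 8)
    half = np.unique(np.concatenate([np.linspace(0.0, x_max, n), [x_ridge]]))
    x = np.concatenate([-half[::-1][:-1], half])
    y_und = np.sqrt(R**2 - x**2)
    bump = np.where(
        np.abs(x) < x_ridge,
        (y_und - R * math.cos(alpha)) / (R * (1.0 - math.cos(alpha))),
        0.0,
    )
    y_def = y_und - delta * bump
    undeformed = ProfilePoints(x=x, y=y_und, label="undeformed")
    deformed = ProfilePoints(x=x, y=y_def, label="deformed")
    if pixel is not None:
        undeformed = pixelate(undeformed, pixel)
        deformed = pixelate(deformed, pixel)
    return undeformed, deformed


#: residual draws are truncated symmetrically at this many sd; symmetric
#: truncation leaves the conditional mean of IOP (hence every regression
#: coefficient) exactly intact
RESID_TRUNC_SD = 2.0

#: smallest admissible apex deflection for a generated record (mm)
MIN_DELTA_MM = 0.02


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table of self-consistent measurement records.

    Columns: ``id, age, iop_mmhg, R_mm, cct_um, alpha_rad, delta_mm,
    E_true`` — everything :class:`~corneashell.estimator.MeasurementRecord`
    needs plus the generating modulus.  Deterministic for a given seed.

    Validity screening is covariate-only: a covariate draw is redrawn when
    the forward deflection at the *worst-case* IOP (linear prediction plus
    the residual truncation bound) would be nonpositive, or when the
    prediction minus the bound drops below 0.5 mmHg.  Because the rejection
    rule never looks at the realised IOP residual, the conditional mean of
    IOP given the covariates — and therefore the generating regression
    coefficients — is preserved exactly; the realised deflection is then
    guaranteed positive by the monotone decrease of deflection in IOP.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    bound = RESID_TRUNC_SD * spec.iop_resid_sd

    def draw_covariates(m: int):
        return (
            _truncated_normal(rng, m, spec.age_mean, spec.age_sd, spec.age_min, 110.0),
            _truncated_normal(rng, m, spec.cct_mean, spec.cct_sd, 300.0, 800.0),
            _truncated_normal(rng, m, spec.r_mean, spec.r_sd, 4.0, 11.0),
            _truncated_normal(rng, m, spec.e_mean, spec.e_sd, 0.02, 2.0),
            _truncated_normal(
                rng, m, spec.alpha_mean, spec.alpha_sd, 0.05, math.pi / 2 - 0.05
            ),
        )

    def prediction(age, cct, e):
        return (
            spec.iop_intercept
            + spec.iop_age * age
            + spec.iop_cct * cct
            + spec.iop_e * e
        )

    def covariates_valid(age_k, cct_k, r_k, e_k, alpha_k) -> bool:
        pred = prediction(age_k, cct_k, e_k)
        if pred - bound < 0.5:
            return False
        geom = CornealGeometry.from_clinical(r_k, cct_k, alpha_k, spec.nu)
        worst = forward_deflection(geom, e_k, (pred + bound) * MMHG_TO_PA)
        return worst > MIN_DELTA_MM

    age, cct, r, e_true, alpha = draw_covariates(n)
    bad = np.array(
        [not covariates_valid(age[k], cct[k], r[k], e_true[k], alpha[k]) for k in range(n)]
    )
    while bad.any():
        idx = np.flatnonzero(bad)
        redraw = draw_covariates(idx.size)
        for j, k in enumerate(idx):
            age[k], cct[k], r[k], e_true[k], alpha[k] = (col[j] for col in redraw)
            bad[k] = not covariates_valid(age[k], cct[k], r[k], e_true[k], alpha[k])

    resid = _truncated_normal(rng, n, 0.0, spec.iop_resid_sd, -bound, bound)
    iop = prediction(age, cct, e_true) + resid

    delta = np.empty(n)
    for k in range(n):
        geom = CornealGeometry.from_clinical(r[k], cct[k], alpha[k], spec.nu)
        delta[k] = forward_deflection(geom, e_true[k], iop[k] * MMHG_TO_PA)
    if spec.pixel is not None:
        px = spec.pixel
        delta = np.copysign(np.floor(np.abs(delta) / px + 0.5), delta) * px

    return pd.DataFrame(
        {
            "id": [f"S{k:05d}" for k in range(n)],
            "age": age,
            "iop_mmhg": iop,
            "R_mm": r,
            "cct_um": cct,
            "alpha_rad": alpha,
            "delta_mm": delta,
            "E_true": e_true,
        }
    )
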