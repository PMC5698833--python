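"""Run-level configuration.

All physical constants and solver knobs used across the package live here so
that a run is fully described by one :class:`RunConfig`.  The defaults are the
study conditions: Poisson's ratio 0.49 for the nearly incompressible corneal
stroma, a 60 mmHg air puff acting on (2/3)^2 of the dimple chord area, and the
0.017 mm Scheimpflug pixel pitch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Conversion factor between clinical and SI pressure units (Pa per mmHg).
MMHG_TO_PA = 133.322

#: Smallest dimple half-angle (rad) before the cot(alpha) edge terms blow up.
ALPHA_MIN = 1e-3

_DELTA4_FORMS = ("lam_scaled", "unscaled")
_LOAD_MODELS = ("iop_normalized", "volume_conserving")


@dataclass
class RunConfig:
    """Physical constants, solver tolerances and model variants for one run.

    Parameters
    ----------
    nu : corneal Poisson's ratio (dimensionless, near-incompressible default).
    puff_mmhg : peak air-puff pressure (mmHg).
    area_factor : fraction of the dimple chord area carrying the puff load,
        accounting for the nonuniform jet pressure profile.
    mmhg_to_pa : pressure unit conversion (Pa per mmHg).
    pixel_mm : Scheimpflug pixel pitch (mm); two-surface resolution floor is
        twice this value.
    e_lo_mpa, e_hi_mpa : search bounds for the Young's modulus (MPa).
    residual_tol_mm : |model deflection - measured deflection| required for a
        converged modulus estimate (mm); well below the 0.034 mm imaging floor.
    solver_tol : scaled residual tolerance of the equilibrium solver.
    max_iter : iteration cap of the damped Newton equilibrium solver.
    alpha_min_rad : guard against the cot(alpha) singularity of the edge terms.
    delta4_form : "lam_scaled" keeps the boundary-layer factor lambda*sqrt(2)/4
        on the quadratic edge-rotation apex term; "unscaled" drops lambda
        (sensitivity variant).
    load_model : "iop_normalized" treats the measured IOP as the pressure in
        the normalized load; "volume_conserving" solves for the pressure that
        conserves the incompressible fluid volume under a given puff force.
    seed : base seed for every stochastic component.
    """

    nu: float = 0.49
    puff_mmhg: float = 60.0
    area_factor: float = (2.0 / 3.0) ** 2
    mmhg_to_pa: float = MMHG_TO_PA
    pixel_mm: float = 0.017
    e_lo_mpa: float = 0.01
    e_hi_mpa: float = 10.0
    residual_tol_mm: float = 1e-4
    solver_tol: float = 1e-10
    max_iter: int = 200
    alpha_min_rad: float = ALPHA_MIN
    delta4_form: str = "lam_scaled"
    load_model: str = "iop_normalized"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nu", "puff_mmhg", "area_factor", "mmhg_to_pa", "pixel_mm",
            "e_lo_mpa", "e_hi_mpa", "residual_tol_mm", "solver_tol",
            "alpha_min_rad",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"RunConfig.{name} must be positive")
        if self.max_iter < 1:
            raise ValueError("RunConfig.max_iter must be >= 1")
        if self.e_lo_mpa >= self.e_hi_mpa:
            raise ValueError("modulus bounds require e_lo_mpa < e_hi_mpa")
        if self.delta4_form not in _DELTA4_FORMS:
            raise ValueError(f"delta4_form must be one of {_DELTA4_FORMS}")
        if self.load_model not in _LOAD_MODELS:
            raise ValueError(f"load_model must be one of {_LOAD_MODELS}")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, logged with every run."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML (or JSON, a YAML subset) config file, then apply
        keyword overrides (CLI flags win over file values)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
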