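"""Corneal profile geometry: from Scheimpflug-style point sets to model inputs.

A noncontact tonometer records cross-sectional anterior-surface profiles of
the cornea before and during the air puff.  This module turns such profiles
(or their chord/sag summary) into the quantities the shell model consumes:
the radius of curvature ``R``, the dimple half-angle ``alpha``, the apex
deflection ``delta`` and the resultant puff force ``P``.  It also models the
imaging resolution: profiles can be quantised to the device pixel grid
(0.017 mm), which bounds the two-surface separation error by 0.034 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import MMHG_TO_PA

__all__ = [
    "ProfileError",
    "FlatProfileError",
    "NoDimpleError",
    "ProfilePoints",
    "ChordSag",
    "fit_radius",
    "meridional_angle",
    "extract_measurement",
    "pixelate",
    "puff_force",
]


class ProfileError(ValueError):
    """Invalid or inconsistent profile geometry."""


class FlatProfileError(ProfileError):
    """Zero or negative sagittal depth; no circle can be fitted."""


class NoDimpleError(ProfileError):
    """Deformed profile never drops below the undeformed one by more than
    the detection threshold; no dimple extent can be delimited."""


#: window half-width around x = 0 in which the apex is sought (mm)
APEX_WINDOW_MM = 1.0


@dataclass(frozen=True)
class ProfilePoints:
    """Ordered anterior-surface points of one profile.

    ``x`` and ``y`` in mm, apex near ``x = 0``; ``label`` is either
    ``"undeformed"`` or ``"deformed"``.
    """

    x: np.ndarray
    y: np.ndarray
    label: str = "undeformed"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ProfileError("x and y must be 1-D arrays of equal length")
        if x.size < 3:
            raise ProfileError("a profile needs at least 3 points")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ProfileError("profile coordinates must be finite")
        if not np.all(np.diff(x) > 0):
            raise ProfileError("x must be strictly increasing")

    def apex_index(self) -> int:
        """Index of the apex: extremal (maximal) y within |x| < 1 mm,
        falling back to the global maximum when no point lies in the
        window.  The window makes the pick robust to edge noise."""
        in_window = np.abs(self.x) < APEX_WINDOW_MM
        if np.any(in_window):
            idx = np.flatnonzero(in_window)
            return int(idx[np.argmax(self.y[idx])])
        return int(np.argmax(self.y))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n")
            fh.write("x_mm,y_mm\n")
            for xi, yi in zip(self.x, self.y):
                fh.write(f"{float(xi)!r},{float(yi)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProfilePoints":
        label = "undeformed"
        rows: list[tuple[float, float]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "label:" in line:
                    label = line.split("label:", 1)[1].strip()
                continue
            if line.lower().startswith("x_mm"):
                continue
            a, b = line.split(",")
            rows.append((float(a), float(b)))
        arr = np.array(rows)
        return cls(x=arr[:, 0], y=arr[:, 1], label=label)


@dataclass(frozen=True)
class ChordSag:
    """Half-chord ``X`` and sagittal depth ``Y`` of a circular arc (mm)."""

    X: float
    Y: float

    def __post_init__(self) -> None:
        if not self.X > 0:
            raise ProfileError("half-chord X must be positive")
        if not self.Y > 0:
            raise FlatProfileError("sagittal depth Y must be positive")
        if self.Y > self.X:
            import warnings

            warnings.warn(
                "sag exceeds half-chord: outside the shallow-cap regime",
                UserWarning,
                stacklevel=2,
            )


def fit_radius(cs: ChordSag) -> float:
    """Radius of the circle through a chord/sag pair:
    ``R = (X^2 + Y^2) / (2 Y)`` (mm); exact for points on a circle."""
    return (cs.X**2 + cs.Y**2) / (2.0 * cs.Y)


def meridional_angle(X: float, R: float) -> float:
    """Polar half-angle subtended by a half-chord: ``alpha = asin(X / R)``."""
    if not X > 0:
        raise ProfileError("half-chord X must be positive")
    if X > R:
        raise ProfileError(f"half-chord {X} exceeds radius {R}: inconsistent")
    return math.asin(X / R)


def pixelate(profile: ProfilePoints, pixel: float = 0.017) -> ProfilePoints:
    """Quantise a profile to the imaging pixel grid.

    Each coordinate is rounded to the nearest multiple of ``pixel`` with
    ties away from zero (bit-exact, documented rule), so the per-coordinate
    error is at most ``pixel / 2``.  Points whose x collapse onto the same
    pixel column are merged (mean y, re-rounded), mimicking one sample per
    camera column.
    """
    if not pixel > 0:
        raise ValueError("pixel size must be positive")

    def snap(v: np.ndarray) -> np.ndarray:
        # the coordinate/pixel ratio is rounded to 1e-12 first so that
        # decimal ties survive binary representation error
        n = np.round(np.abs(v) / pixel, 12)
        return np.copysign(np.floor(n + 0.5), v) * pixel

    x = snap(profile.x)
    y = snap(profile.y)
    # merge duplicate columns
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    for k in range(ux.size):
        uy[k] = y[inverse == k].mean()
    uy = snap(uy)
    return ProfilePoints(x=ux, y=uy, label=profile.label)


def _chord_sag_of(profile: ProfilePoints) -> ChordSag:
    """Chord/sag summary of a profile, measured from the apex to the ends."""
    i = profile.apex_index()
    X = (profile.x[-1] - profile.x[0]) / 2.0
    Y = profile.y[i] - (profile.y[0] + profile.y[-1]) / 2.0
    return ChordSag(X=float(X), Y=float(Y))


def _edge_zero_crossing(
    x: np.ndarray, depth: np.ndarray, start: int, direction: int
) -> float:
    """Walk outward from sample ``start`` until the dimple depth drops to
    zero and return the linearly interpolated crossing abscissa."""
    i = start
    while 0 <= i + direction < x.size and depth[i + direction] > 0:
        i += direction
    j = i + direction
    if not (0 <= j < x.size):
        return float(x[i])  # dimple reaches the profile end
    d0, d1 = depth[i], depth[j]
    if d0 == d1:
        return float(x[j])
    frac = d0 / (d0 - d1)
    return float(x[i] + frac * (x[j] - x[i]))


def extract_measurement(
    undeformed: ProfilePoints,
    deformed: ProfilePoints,
    depth_threshold: float = 0.017,
) -> tuple[float, float, float]:
    """Recover ``(R, alpha, delta)`` from an undeformed/deformed profile pair.

    ``R`` is fitted from the undeformed chord/sag; ``delta`` is the apex
    displacement between the two profiles; the dimple extent is the
    contiguous region around the apex where the deformed surface lies below
    the undeformed one by more than ``depth_threshold`` (one pixel), with
    each edge refined to the interpolated zero crossing of the depth, and
    ``alpha`` follows from the half-chord of that extent.
    """
    cs = _chord_sag_of(undeformed)
    R = fit_radius(cs)
    apex = undeformed.apex_index()
    x_a = undeformed.x[apex]

    # depth of the deformation, sampled on the undeformed grid
    y_def = np.interp(undeformed.x, deformed.x, deformed.y)
    depth = undeformed.y - y_def
    delta = float(np.interp(x_a, undeformed.x, depth))

    in_dimple = depth > depth_threshold
    if not np.any(in_dimple):
        raise NoDimpleError(
            f"no region deeper than {depth_threshold} mm; apex displacement "
            f"was {delta:.4f} mm"
        )
    # contiguous run containing the deepest sample
    deepest = int(np.argmax(depth))
    lo = deepest
    while lo - 1 >= 0 and in_dimple[lo - 1]:
        lo -= 1
    hi = deepest
    while hi + 1 < depth.size and in_dimple[hi + 1]:
        hi += 1
    x_lo = _edge_zero_crossing(undeformed.x, depth, lo, -1)
    x_hi = _edge_zero_crossing(undeformed.x, depth, hi, +1)
    half_chord = (x_hi - x_lo) / 2.0
    alpha = meridional_angle(half_chord, R)
    return R, alpha, delta


def puff_force(
    R: float,
    alpha: float,
    puff_pressure_mmhg: float = 60.0,
    area_factor: float = (2.0 / 3.0) ** 2,
    mmhg_to_pa: float = MMHG_TO_PA,
) -> float:
    """Resultant air-puff force on the dimple chord area (N).

    The jet acts on the chord disc ``A = pi R^2 sin^2(alpha)``; the factor
    ``(2/3)^2`` accounts for the nonuniform pressure distribution over it.
    """
    if not R > 0:
        raise ProfileError("radius must be positive")
    if not (0.0 <= alpha <= math.pi / 2):
        raise ProfileError("alpha must lie in [0, pi/2]")
    area_m2 = math.pi * (R * 1e-3) ** 2 * math.sin(alpha) ** 2
    return puff_pressure_mmhg * mmhg_to_pa * area_factor * area_m2
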