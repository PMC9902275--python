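"""Rotational fluid-shear hydrogel adhesion model.

A stir bar spins water over an inverted, hydrogel-coated device. At angular
rate omega the fluid at the projected gel perimeter moves at u = omega * r;
with a no-slip condition at the gel surface the velocity falls linearly over
the gap h (Couette profile), so the wall shear stress is

    tau = mu * du/dh = mu * omega * r / h.

Delamination thresholds are the lowest rotation rate at which the gel
detaches; dimpled microtextures (triangle/square/star cross-sections at
fixed depth) raise adhesion by adding sidewall contact area.

Default geometry (r = 7.5 mm = half the 1.5 cm gel width, h = 75.5 mm,
mu = 1.0e-3 Pa s for water) is calibrated so that 125 rpm maps to 1.30 mPa,
the unmodified-gel baseline; the geometry is an explicit input, not a
physical measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShearGeometry",
    "ShearTestRecord",
    "TextureSpec",
    "shear_stress",
    "delamination_threshold",
    "texture_area_gain",
]


@dataclass(frozen=True)
class ShearGeometry:
    """Couette-model geometry: radius to gel edge, gap, fluid viscosity."""

    r_m: float = 7.5e-3
    h_m: float = 7.55e-2
    mu_pa_s: float = 1.0e-3

    def __post_init__(self):
        if self.r_m <= 0 or self.h_m <= 0 or self.mu_pa_s <= 0:
            raise ValueError("geometry parameters must be strictly positive")


@dataclass(frozen=True)
class ShearTestRecord:
    """Outcome of one delamination series, with stress derived from rpm."""

    texture: str
    silanized: bool
    rpm_at_delamination: float
    stress_pa: float
    censored: str = "none"  # "none" | "right" (never delaminated) | "left"


@dataclass(frozen=True)
class TextureSpec:
    """Dimple microtexture: cross-section shape, size, depth and count."""

    shape: str  # "triangle" | "square" | "star"
    radius_um: float  # circumscribed radius of the cross-section
    depth_um: float
    count: int
    base_area_um2: float
    star_points: int = 5
    star_inner_ratio: float = 0.5

    def __post_init__(self):
        if self.depth_um < 0 or self.count < 0:
            raise ValueError("depth and count must be non-negative")
        if self.base_area_um2 <= 0:
            raise ValueError("base contact area must be positive")
        if self.radius_um <= 0:
            raise ValueError("circumscribed radius must be positive")
        if not (0 < self.star_inner_ratio < 1):
            raise ValueError("star inner/outer radius ratio must be in (0, 1)")


def shear_stress(rpm: float, geom: ShearGeometry = ShearGeometry()) -> float:
    """Wall shear stress (Pa) at the gel edge for a stir rate in rpm."""
    if rpm < 0:
        raise ValueError("rpm must be non-negative")
    omega = 2.0 * math.pi * rpm / 60.0
    return geom.mu_pa_s * omega * geom.r_m / geom.h_m


def delamination_threshold(records, geom: ShearGeometry = ShearGeometry(),
                           texture: str = "none",
                           silanized: bool = False) -> ShearTestRecord:
    """Lowest rpm with observed delamination, as a record with shear stress.

    ``records`` is an iterable of (rpm, delaminated flag). If no trial
    delaminated, the record is right-censored at the highest tested rpm
    (e.g. a star-textured gel that outlasts the stir plate's 1200 rpm). If
    the very first tested rpm already delaminated, the threshold is
    left-censored. Delamination below a surviving higher rpm is
    contradictory and rejected.
    """
    recs = sorted((float(rpm), bool(flag)) for rpm, flag in records)
    if not recs:
        raise ValueError("no shear observations")
    rpms = np.array([r for r, _ in recs])
    flags = np.array([f for _, f in recs])
    if flags.any():
        first_fail = int(np.argmax(flags))
        if not flags[first_fail:].all():
            surv = rpms[first_fail:][~flags[first_fail:]]
            raise ValueError(
                f"contradictory records: delamination at {rpms[first_fail]:g} rpm "
                f"but none at higher rpm {surv.min():g}")
        rpm_thr = float(rpms[first_fail])
        censored = "left" if first_fail == 0 else "none"
    else:
        rpm_thr = float(rpms[-1])
        censored = "right"
    return ShearTestRecord(texture=texture, silanized=silanized,
                           rpm_at_delamination=rpm_thr,
                           stress_pa=shear_stress(rpm_thr, geom),
                           censored=censored)


def _cross_section_perimeter(spec: TextureSpec) -> float:
    """Perimeter (um) of the dimple cross-section from its circumscribed radius."""
    R = spec.radius_um
    if spec.shape == "triangle":
        return 2.0 * 3 * R * math.sin(math.pi / 3)
    if spec.shape == "square":
        return 2.0 * 4 * R * math.sin(math.pi / 4)
    if spec.shape == "star":
        n = spec.star_points
        r_in = spec.star_inner_ratio * R
        edge = math.sqrt(R * R + r_in * r_in
                         - 2.0 * R * r_in * math.cos(math.pi / n))
        return 2.0 * n * edge
    raise ValueError(f"unknown texture shape {spec.shape!r}")


def texture_area_gain(spec: TextureSpec) -> float:
    """Percent increase in contact area from dimple sidewalls.

    gain% = 100 * count * perimeter * depth / base_area: each dimple adds a
    sidewall band equal to its cross-section perimeter times its depth.
    """
    perim = _cross_section_perimeter(spec)
    return 100.0 * spec.count * perim * spec.depth_um / spec.base_area_um2
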