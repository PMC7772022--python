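"""Sideways-fall impact attributes.

Computes the fall-related attribute chain for one subject:

* ``STH``  trochanteric soft-tissue thickness from BMI (linear
  regression for women: STH = 2.3451 * BMI - 33.4440, mm);
* ``FPK``  peak impact force from a single-degree-of-freedom mass-spring
  model of the falling body: the hip hits the ground at
  v = sqrt(2 g h) with h a fixed fraction of body height, and the peak
  elastic force is FPK = v * sqrt(k * m_eff) with m_eff a fixed fraction
  of body mass;
* ``FAT``  force attenuated by the soft tissue, 71 N per mm of STH;
* ``FP``   the net impact force FP = FPK - FAT;
* ``HP``   the pressure applied to the greater trochanter pad,
  HP = FP / (b * t) in MPa with the pad length b and the subject
  out-of-plane thickness t in mm.

The mass-spring internals (stiffness, effective-mass fraction,
hip-height fraction) are calibration constants: only the product of the
mass and height fractions is identifiable from group-mean data, and the
defaults reproduce the published group-mean peak forces to 0.3% with
the pelvis stiffness fixed at the literature-standard 71 kN/m.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .morphometry import PadGeometry

__all__ = [
    "FallAttributes",
    "ImpactModelParams",
    "FallModelError",
    "soft_tissue_thickness",
    "attenuation_force",
    "peak_impact_force",
    "attenuated_force",
    "hip_pressure",
    "fall_chain",
]

log = logging.getLogger(__name__)

STH_SLOPE = 2.3451          # mm per kg/m^2 (female regression)
STH_INTERCEPT = -33.4440    # mm
FAT_PER_MM = 71.0           # N of attenuation per mm of soft tissue


class FallModelError(ValueError):
    """Raised for invalid fall-model inputs."""


@dataclass(frozen=True)
class ImpactModelParams:
    """Internal constants of the mass-spring impact model.

    ``stiffness`` N/m effective pelvis stiffness; ``mass_fraction`` of
    body weight moving with the hip at impact; ``hip_height_fraction``
    of body height fallen by the hip centre; ``gravity`` m/s^2.
    """

    stiffness: float = 71000.0
    mass_fraction: float = 0.5
    hip_height_fraction: float = 0.40294   # calibrated jointly with the above
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if min(self.stiffness, self.mass_fraction,
               self.hip_height_fraction, self.gravity) <= 0:
            raise FallModelError("impact-model parameters must be positive")
        if self.mass_fraction > 1.0:
            raise FallModelError("effective mass fraction cannot exceed 1")


@dataclass(frozen=True)
class FallAttributes:
    sth: float      # mm
    fpk: float      # N
    fat: float      # N
    fp: float       # N
    hp: float       # MPa


def soft_tissue_thickness(bmi: float, gender: str = "female",
                          floor_mm: float = 1.0) -> float:
    """Trochanteric soft-tissue thickness (mm) from BMI.

    Only the female regression is available; lean subjects whose linear
    prediction is non-positive are clamped at ``floor_mm`` with a warning.
    """
    if gender != "female":
        raise FallModelError("soft-tissue relation available for women only")
    sth = STH_SLOPE * bmi + STH_INTERCEPT
    if sth <= 0.0:
        log.warning("non-positive soft-tissue thickness (BMI %.1f); "
                    "clamped to %.1f mm", bmi, floor_mm)
        return floor_mm
    return sth


def attenuation_force(sth: float) -> float:
    """Impact attenuation (N) provided by ``sth`` mm of soft tissue."""
    if sth < 0:
        raise FallModelError("soft-tissue thickness must be non-negative")
    return FAT_PER_MM * sth


def peak_impact_force(weight: float, height: float, gender: str = "female",
                      params: ImpactModelParams | None = None) -> float:
    """Peak impact force (N) of a sideways fall from standing.

    Single-degree-of-freedom impact: v = sqrt(2 g h), FPK = v sqrt(k m).
    Monotonically increasing in both weight and height.
    """
    if weight <= 0 or height <= 0:
        raise FallModelError("weight and height must be positive")
    p = params if params is not None else ImpactModelParams()
    h = p.hip_height_fraction * height / 100.0       # cm -> m
    v = math.sqrt(2.0 * p.gravity * h)               # m/s
    m_eff = p.mass_fraction * weight                 # kg
    return v * math.sqrt(p.stiffness * m_eff)        # N


def attenuated_force(fpk: float, fat: float) -> float:
    """Net impact force FP = FPK - FAT (N); non-positive results are flagged."""
    if fpk <= 0:
        raise FallModelError("peak impact force must be positive")
    if fat < 0:
        raise FallModelError("attenuation force must be non-negative")
    fp = fpk - fat
    if fp <= 0:
        log.warning("attenuation exceeds the peak impact force "
                    "(FPK %.0f N, FAT %.0f N)", fpk, fat)
    return fp


def hip_pressure(fp: float, pads: PadGeometry) -> float:
    """Pad pressure HP = FP / (b t), MPa (b, t in mm, FP in N)."""
    if fp <= 0:
        raise FallModelError("attenuated force must be positive")
    area = pads.b * pads.t
    if area <= 0:
        raise FallModelError("pad area b*t must be positive")
    return fp / area


def fall_chain(weight: float, height: float, bmi: float, pads: PadGeometry,
               gender: str = "female",
               params: ImpactModelParams | None = None) -> FallAttributes:
    """Full STH -> FPK -> FAT -> FP -> HP chain for one subject."""
    sth = soft_tissue_thickness(bmi, gender)
    fpk = peak_impact_force(weight, height, gender, params)
    fat = attenuation_force(sth)
    fp = attenuated_force(fpk, fat)
    hp = hip_pressure(fp, pads) if fp > 0 else 0.0
    return FallAttributes(sth=sth, fpk=fpk, fat=fat, fp=fp, hp=hp)
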