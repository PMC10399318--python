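"""Fluidized-bed design formulas.

The bed holds near-monodisperse grains (the study used ~1 mm poppy seeds at
a loose packing fraction of 0.58) fluidized by upward airflow.  The minimum
fluidization velocity U_f is the superficial gas velocity at which the
pressure drop through the packed bed balances the bed's buoyant weight; it
follows from the Ergun packed-bed pressure-drop relation, whose viscous and
inertial terms make the balance a quadratic in U:

    150 mu U (1-eps)^2 / (eps^3 (phi_s d)^2)
      + 1.75 rho_f U^2 (1-eps) / (eps^3 phi_s d)  =  (rho - rho_f) g (1-eps)

with void fraction eps = 1 - packing fraction, grain sphericity phi_s, grain
material density rho and fluid density/viscosity rho_f, mu.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError

__all__ = ["BedSpec", "ergun_minimum_fluidization", "fluidization_ratio",
           "bulk_density"]


@dataclass(frozen=True)
class BedSpec:
    """Grain, fluid and operating parameters of the fluidized bed (SI).

    Defaults are the study bed: 1 mm grains whose bulk density 570 kg/m^3 at
    packing fraction 0.58 implies a material density of ~983 kg/m^3, in
    20 degC air, operated at a superficial velocity of 0.55 m/s.  Sphericity
    defaults to 1 (air properties and sphericity are standard assumptions,
    not measured quantities; all are overridable).
    """

    grain_diameter: float = 1e-3
    grain_material_density: float = 570.0 / 0.58
    packing_fraction: float = 0.58
    sphericity: float = 1.0
    fluid_density: float = 1.2
    fluid_viscosity: float = 1.8e-5
    g: float = 9.81
    superficial_velocity: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 < self.packing_fraction < 1.0):
            raise ValidationError("packing_fraction must lie in (0, 1)")
        if not (0.0 < self.sphericity <= 1.0):
            raise ValidationError("sphericity must lie in (0, 1]")
        for name in ("grain_diameter", "grain_material_density",
                     "fluid_density", "fluid_viscosity", "g",
                     "superficial_velocity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v!r}")

    @property
    def void_fraction(self) -> float:
        return 1.0 - self.packing_fraction

    def to_dict(self) -> dict:
        return asdict(self)


def bulk_density(packing_fraction: float, material_density: float) -> float:
    """Bulk density phi * rho of the loosely packed grains (kg/m^3)."""
    if not (0.0 < packing_fraction <= 1.0):
        raise ValidationError("packing_fraction must lie in (0, 1]")
    return packing_fraction * material_density


def ergun_minimum_fluidization(bed: BedSpec) -> float:
    """Minimum fluidization velocity U_f (m/s), positive root of the Ergun
    balance.

    Writing the balance per unit (1 - eps), it reduces to
    a U^2 + b U - c = 0 with

        a = 1.75 rho_f / (eps^3 phi_s d)
        b = 150 mu (1-eps) / (eps^3 (phi_s d)^2)
        c = (rho - rho_f) g

    solved in closed form.  Grains no denser than the fluid need no flow to
    be supported: U_f = 0 is returned with a warning.
    """
    eps = bed.void_fraction
    d = bed.sphericity * bed.grain_diameter
    rho, rho_f = bed.grain_material_density, bed.fluid_density
    if rho <= rho_f:
        warnings.warn("grain density does not exceed fluid density; the bed "
                      "is buoyant without flow (U_f = 0)", stacklevel=2)
        return 0.0
    a = 1.75 * rho_f / (eps**3 * d)
    b = 150.0 * bed.fluid_viscosity * (1.0 - eps) / (eps**3 * d**2)
    c = (rho - rho_f) * bed.g
    # cancellation-free form of the positive root (b can dominate sqrt)
    return 2.0 * c / (b + math.sqrt(b * b + 4.0 * a * c))


def fluidization_ratio(bed: BedSpec) -> float:
    """Operating-point ratio U / U_f; > 1 means the bed is fluidized."""
    uf = ergun_minimum_fluidization(bed)
    if uf == 0.0:
        return math.inf
    return bed.superficial_velocity / uf
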