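"""Closed-form physicochemical relations for diffusion-limited dissolution.

All quantities are SI internally: lengths in m, solubilities and
concentrations in kg/m^3 (numerically equal to g/L), energies in J/m^2,
viscosity in Pa s. Unit conversion from the customary bench units
(nm, mg/L, mJ/m^2, g, mL) happens at the I/O boundary, never here.

The relations collected here are:

* Stokes-Einstein diffusion of the dissolved molecule, with the
  hydrodynamic radius estimated from the molar volume assuming a
  spherical molecule;
* the diffusion boundary layer around a sub-micron particle, taken
  equal to the particle radius (particles this small follow the liquid
  flow, so Prandtl-type hydrodynamic boundary layers do not apply);
* the Ostwald-Freundlich (Kelvin-type) increase of solubility with
  curvature, ln(s_app/s0) = 2 sigma_sl V_m / (r R T);
* the dose number Do = m / (s0 V_l), the ratio of solid drug offered
  to the amount the medium could dissolve at thermodynamic solubility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as _const

from .errors import DomainError, ValidationError

__all__ = [
    "BOLTZMANN",
    "GAS_CONSTANT",
    "AVOGADRO",
    "CompoundMedium",
    "hydrodynamic_radius",
    "diffusion_coefficient",
    "boundary_layer_thickness",
    "apparent_solubility",
    "size_at_solubility",
    "dose_number",
]

BOLTZMANN = _const.k  # J/K
GAS_CONSTANT = _const.R  # J/(mol K)
AVOGADRO = _const.N_A  # 1/mol

#: Default equilibration temperature, 22 degC.
DEFAULT_TEMPERATURE_K = 295.15


@dataclass(frozen=True)
class CompoundMedium:
    """Physicochemical constants of a drug compound in a dissolution medium.

    Parameters
    ----------
    molar_volume : float
        Molar volume of the dissolving compound, m^3/mol.
    density : float
        True density of the solid drug, kg/m^3.
    viscosity : float
        Dynamic viscosity of the dissolution medium, Pa s.
    temperature : float
        Absolute temperature, K.
    thermodynamic_solubility : float
        Solubility s0 of coarse crystals (x >> 1 um) in this medium,
        kg/m^3 (1 mg/L = 1e-3 kg/m^3).
    interfacial_energy : float
        Solid-liquid interfacial energy sigma_sl, J/m^2.
    delta_max : float or None
        Optional cap on the diffusion boundary layer thickness, m.
        Default None (uncapped; the boundary layer equals the particle
        radius at every size).
    """

    molar_volume: float
    density: float
    viscosity: float
    temperature: float
    thermodynamic_solubility: float
    interfacial_energy: float
    delta_max: float | None = None

    def __post_init__(self):
        for name in (
            "molar_volume",
            "density",
            "viscosity",
            "temperature",
            "thermodynamic_solubility",
            "interfacial_energy",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if self.delta_max is not None and not self.delta_max > 0:
            raise ValidationError(f"delta_max must be positive or None, got {self.delta_max!r}")

    @property
    def s0(self) -> float:
        """Alias for the thermodynamic solubility, kg/m^3."""
        return self.thermodynamic_solubility

    @property
    def kelvin_length(self) -> float:
        """The length 4 sigma_sl V_m / (R T) in m.

        apparent_solubility(x) = s0 * exp(kelvin_length / x); the
        solubility enhancement is a factor e at x = kelvin_length.
        """
        return (
            4.0
            * self.interfacial_energy
            * self.molar_volume
            / (GAS_CONSTANT * self.temperature)
        )

    def diffusion_coefficient(self) -> float:
        """Stokes-Einstein diffusion coefficient of the solute, m^2/s."""
        r0 = hydrodynamic_radius(self.molar_volume)
        return diffusion_coefficient(self.temperature, self.viscosity, r0)


def hydrodynamic_radius(molar_volume: float) -> float:
    """Radius of a sphere occupying one molecular volume, m.

    r0 = (3 V_m / (4 pi N_A))^(1/3)
    """
    if not molar_volume > 0:
        raise DomainError(f"molar_volume must be positive, got {molar_volume!r}")
    return (3.0 * molar_volume / (4.0 * math.pi * AVOGADRO)) ** (1.0 / 3.0)


def diffusion_coefficient(temperature: float, viscosity: float, r0: float) -> float:
    """Stokes-Einstein diffusion coefficient D = k_B T / (6 pi eta r0), m^2/s."""
    if not (temperature > 0 and viscosity > 0 and r0 > 0):
        raise DomainError(
            "temperature, viscosity and hydrodynamic radius must all be positive"
        )
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * r0)


def boundary_layer_thickness(x, delta_max: float | None = None):
    """Diffusion boundary layer thickness around a particle of diameter ``x``.

    For sub-micron particles the boundary layer is taken equal to the
    particle radius, delta = x/2. An optional cap ``delta_max`` is
    available for sensitivity studies on coarse particles; by default no
    cap is applied.

    Accepts scalars or numpy arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("particle size must be strictly positive")
    delta = x / 2.0
    if delta_max is not None:
        if not delta_max > 0:
            raise DomainError(f"delta_max must be positive, got {delta_max!r}")
        delta = np.minimum(delta, delta_max)
    if delta.ndim == 0:
        return float(delta)
    return delta


def apparent_solubility(x, cm: CompoundMedium):
    """Size-dependent (Ostwald-Freundlich) apparent solubility, kg/m^3.

    s_app(x) = s0 * exp(2 sigma_sl V_m / (r R T)) with r = x/2, i.e. an
    exponent 4 sigma_sl V_m / (x R T). Strictly decreasing in the
    particle diameter ``x`` and approaching s0 as x -> infinity.

    Accepts scalars or numpy arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("particle size must be strictly positive")
    out = cm.s0 * np.exp(cm.kelvin_length / x)
    if out.ndim == 0:
        return float(out)
    return out


def size_at_solubility(c: float, cm: CompoundMedium) -> float:
    """Particle diameter whose apparent solubility equals ``c``, m.

    Exact algebraic inverse of :func:`apparent_solubility`:
    x = 4 sigma_sl V_m / (R T ln(c/s0)). Only defined for c > s0; a
    concentration at or below the thermodynamic solubility corresponds
    to no finite particle size.
    """
    if not c > cm.s0:
        raise DomainError(
            f"concentration {c!r} must exceed the thermodynamic solubility {cm.s0!r}"
        )
    return cm.kelvin_length / math.log(c / cm.s0)


def dose_number(m: float, s0: float, V_l: float) -> float:
    """Dose number Do = m / (s0 V_l), dimensionless.

    ``m`` is the solid drug mass (kg), ``s0`` the thermodynamic
    solubility in the medium (kg/m^3) and ``V_l`` the medium volume
    (m^3). Do < 1 means the medium could dissolve the whole dose.
    """
    if not (s0 > 0 and V_l > 0):
        raise DomainError("s0 and V_l must be strictly positive")
    if m < 0:
        raise DomainError(f"solid mass must be nonnegative, got {m!r}")
    return m / (s0 * V_l)
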