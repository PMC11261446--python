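"""Psychrometric and thermal formulas shared by all pipeline stages.

The quantities here are the physical backbone of ventilated-capsule
sudometry: the saturation water-vapor concentration that drives
evaporative mass transfer, the latent-heat conversion between mass flux
and heat flux, and the one-dimensional thermal-circuit temperature drop
across a water film carrying that heat flux.

Unit conventions follow physiology practice at the interfaces:
temperatures in degrees Celsius, concentrations in g·m⁻³, evaporative
mass flux in mg·min⁻¹·cm⁻², heat flux in W·m⁻². Conversions to SI happen
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysicalConstants",
    "AmbientState",
    "saturation_vapor_concentration",
    "latent_heat_flux",
    "mass_flux_from_heat_flux",
    "film_temperature_drop",
]

#: Specific gas constant of water vapor, J·kg⁻¹·K⁻¹.
R_WATER_VAPOR = 461.52

#: mg·min⁻¹·cm⁻² → kg·s⁻¹·m⁻² (1e-6 kg / 60 s / 1e-4 m²).
_MASS_FLUX_TO_SI = 1e-6 / 60.0 / 1e-4


@dataclass
class PhysicalConstants:
    """Physical constants of the evaporation analysis, all overridable.

    Attributes
    ----------
    latent_heat_sweat : float
        Latent heat of vaporization of sweat, kJ·kg⁻¹ (value near 30 °C).
    water_thermal_conductivity : float
        Thermal conductivity of liquid water, W·m⁻¹·K⁻¹ (value near
        30–34 °C).
    lewis_ratio : float
        Mass-to-heat transfer coefficient ratio h_m/h_t from the Lewis
        analogy, (m·s⁻¹)/(W·m⁻²·K⁻¹).
    head_ht_coefficient : float
        Coefficient ``a`` in the head-averaged convective heat transfer
        correlation h_t = a·V^0.5, W·m⁻²·K⁻¹ per (m·s⁻¹)^0.5.
    """

    latent_heat_sweat: float = 2430.0
    water_thermal_conductivity: float = 0.60
    lewis_ratio: float = 0.00091
    head_ht_coefficient: float = 6.1

    def __post_init__(self) -> None:
        for name in (
            "latent_heat_sweat",
            "water_thermal_conductivity",
            "lewis_ratio",
            "head_ht_coefficient",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class AmbientState:
    """Far-field air state outside the mass boundary layer."""

    temperature: float  # °C
    relative_humidity: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError("relative_humidity must lie in [0, 1]")

    @property
    def vapor_concentration(self) -> float:
        """Far-field water vapor concentration C∞, g·m⁻³."""
        return self.relative_humidity * saturation_vapor_concentration(
            self.temperature
        )


def saturation_pressure_buck(temperature):
    """Arden Buck saturation vapor pressure over liquid water, Pa.

    e_s(T) = 611.21 · exp[(18.678 − T/234.5) · T/(257.14 + T)], T in °C.
    Accurate to better than 0.05% against reference steam tables on
    0–50 °C.
    """
    t = np.asarray(temperature, dtype=float)
    return 611.21 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def saturation_pressure_magnus(temperature):
    """Magnus (WMO form) saturation vapor pressure over water, Pa.

    Provided as an independent correlation for cross-checking Buck.
    """
    t = np.asarray(temperature, dtype=float)
    return 610.94 * np.exp(17.625 * t / (243.04 + t))


def saturation_vapor_concentration(temperature):
    """Saturation water vapor concentration C_sat(T) in g·m⁻³.

    Buck saturation pressure divided by R_v·T (ideal gas). Strictly
    increasing in temperature. Valid on −20 ≤ T ≤ 60 °C.

    Parameters
    ----------
    temperature : float or array
        Surface temperature in °C.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < -20.0) or np.any(t > 60.0):
        raise ValueError("temperature outside supported range [-20, 60] °C")
    p_sat = saturation_pressure_buck(t)
    conc = p_sat / (R_WATER_VAPOR * (t + 273.15)) * 1000.0  # g·m⁻³
    return float(conc) if np.isscalar(temperature) else conc


def latent_heat_flux(mass_flux, latent_heat: float = 2430.0):
    """Convert evaporative mass flux to evaporative heat flux.

    Parameters
    ----------
    mass_flux : float or array
        Evaporation mass flux in mg·min⁻¹·cm⁻².
    latent_heat : float
        Latent heat of vaporization in kJ·kg⁻¹.

    Returns
    -------
    float or array
        Heat flux q″ in W·m⁻². Linear in both arguments; e.g.
        2 mg·min⁻¹·cm⁻² at 2430 kJ·kg⁻¹ gives 810 W·m⁻².
    """
    m = np.asarray(mass_flux, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass_flux must be nonnegative")
    q = m * _MASS_FLUX_TO_SI * latent_heat * 1e3
    return float(q) if np.isscalar(mass_flux) else q


def mass_flux_from_heat_flux(heat_flux, latent_heat: float = 2430.0):
    """Inverse of :func:`latent_heat_flux` (W·m⁻² → mg·min⁻¹·cm⁻²)."""
    q = np.asarray(heat_flux, dtype=float)
    m = q / (latent_heat * 1e3) / _MASS_FLUX_TO_SI
    return float(m) if np.isscalar(heat_flux) else m


def film_temperature_drop(heat_flux, thickness, conductivity: float = 0.60):
    """Temperature drop across a water film carrying a heat flux.

    One-dimensional thermal circuit: ΔT = q″·L/k. For the ~810 W·m⁻²
    flux of intense sweating, a 2-mm film sustains a 2.7 °C drop while a
    60-μm film sustains under a tenth of a degree — the origin of the
    thickness-dependent surface-temperature contrast of sweat puddles in
    MWIR images.

    Parameters
    ----------
    heat_flux : float or array
        q″ in W·m⁻².
    thickness : float or array
        Film thickness L in meters, ≥ 0.
    conductivity : float
        Water thermal conductivity k in W·m⁻¹·K⁻¹, > 0.
    """
    if conductivity <= 0:
        raise ValueError("conductivity must be strictly positive")
    thickness_arr = np.asarray(thickness, dtype=float)
    if np.any(thickness_arr < 0):
        raise ValueError("thickness must be nonnegative")
    dt = np.asarray(heat_flux, dtype=float) * thickness_arr / conductivity
    scalar = np.isscalar(heat_flux) and np.isscalar(thickness)
    return float(dt) if scalar else dt
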