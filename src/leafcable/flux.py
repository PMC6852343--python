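"""Measurement-side computations: transpiration, K_leaf and cuticular g_min.

The evaporative flux method measures whole-leaf conductance by letting a
detached, basally watered blade transpire on a balance: the steady slope
of mass vs time gives the transpiration rate E, and dividing by the leaf
water potential depression it causes gives

    K_leaf = E / (-Psi_leaf)        (mmol m^-2 s^-1 MPa^-1).

Cuticular (minimum) conductance g_min comes from dark mass loss of a
sealed leaf divided by twice its projected area times the leaf-air water
vapour concentration difference, with the leaf interior assumed
saturated at leaf temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .units import DomainError, WATER_MOLAR_MASS_KG_MOL, _check_temperature

__all__ = [
    "MassTimeSeries",
    "LeafEnvironment",
    "FluxError",
    "DEFAULT_STABILIZATION_S",
    "transpiration_rate",
    "kleaf_from_flux",
    "saturation_vapor_concentration",
    "gmin",
]

#: Initial balance segment discarded before fitting the slope (s); mass
#: readings typically stabilize within ~10 min of mounting the leaf.
DEFAULT_STABILIZATION_S = 600.0

_R_GAS = 8.31446  # J mol^-1 K^-1


class FluxError(ValueError):
    """A mass series is unusable for a flux estimate (e.g. gaining mass)."""


@dataclass(frozen=True)
class MassTimeSeries:
    """Balance readings for one leaf: times (s), masses (g), projected area (m^2)."""

    times_s: np.ndarray
    masses_g: np.ndarray
    leaf_area_m2: float

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        m = np.asarray(self.masses_g, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "masses_g", m)
        if t.ndim != 1 or t.shape != m.shape or t.size < 3:
            raise DomainError("need >= 3 paired (time, mass) readings")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(m < 0):
            raise DomainError("masses must be non-negative")
        if self.leaf_area_m2 <= 0:
            raise DomainError("leaf area must be positive")


@dataclass(frozen=True)
class LeafEnvironment:
    """Leaf and air temperature (degC) and relative humidity fraction."""

    t_leaf_c: float
    t_air_c: float
    rh: float

    def __post_init__(self):
        _check_temperature(self.t_leaf_c)
        _check_temperature(self.t_air_c)
        if not (0.0 <= self.rh <= 1.0):
            raise DomainError("relative humidity must be a fraction in [0, 1]")


def mass_loss_slope(
    series: MassTimeSeries,
    window: tuple[float, float] | None = None,
    stabilization_s: float = DEFAULT_STABILIZATION_S,
) -> float:
    """OLS slope of mass vs time (g s^-1) over the analysis window.

    The window defaults to everything after the stabilization segment.
    A non-negative slope (leaf not losing mass) is an error, not a zero.
    """
    t, m = series.times_s, series.masses_g
    if window is None:
        window = (t[0] + stabilization_s, t[-1])
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise FluxError(f"fewer than 3 readings in window [{lo}, {hi}] s")
    slope = linregress(t[sel], m[sel]).slope
    if slope >= 0:
        raise FluxError(f"leaf is not losing mass (slope {slope:.3e} g/s >= 0)")
    return float(slope)


def transpiration_rate(
    series: MassTimeSeries,
    window: tuple[float, float] | None = None,
    stabilization_s: float = DEFAULT_STABILIZATION_S,
) -> float:
    """Transpiration E in mmol m^-2 s^-1 from the balance mass slope.

    |slope| (g s^-1) -> mol s^-1 via the molar mass of water, divided by
    projected leaf area, expressed in mmol.
    """
    slope_g_s = mass_loss_slope(series, window, stabilization_s)
    mol_per_s = -slope_g_s / (WATER_MOLAR_MASS_KG_MOL * 1e3)
    return mol_per_s / series.leaf_area_m2 * 1e3


def kleaf_from_flux(e_mmol: float, psi_mpa: float) -> float:
    """K_leaf = E / (-Psi_leaf), mmol m^-2 s^-1 MPa^-1 (Psi must be < 0)."""
    if e_mmol < 0:
        raise DomainError("transpiration rate must be >= 0")
    if psi_mpa >= 0:
        raise DomainError("a transpiring leaf must have Psi_leaf < 0 MPa")
    return e_mmol / -psi_mpa


def saturation_vapor_concentration(t_c: float) -> float:
    """Saturation water vapour concentration over liquid water, kg m^-3.

    Tetens saturation vapour pressure converted to density with the ideal
    gas law: ~0.0230 kg m^-3 at 25 degC.
    """
    t_c = _check_temperature(t_c)
    e_s_pa = 610.78 * float(np.exp(17.27 * t_c / (t_c + 237.3)))
    return e_s_pa * WATER_MOLAR_MASS_KG_MOL / (_R_GAS * (t_c + 273.15))


def gmin(
    mass_loss_rate_kg_s: float,
    projected_area_m2: float,
    env: LeafEnvironment,
) -> float:
    """Minimum (cuticular) conductance, m s^-1.

    g_min = rate / (2 * area * dC) with dC the leaf-air vapour
    concentration difference; both leaf faces lose water, hence the
    factor 2 on the projected area.  The leaf interior is taken saturated
    at leaf temperature.
    """
    if mass_loss_rate_kg_s <= 0 or projected_area_m2 <= 0:
        raise DomainError("mass loss rate and area must be positive")
    dc = saturation_vapor_concentration(env.t_leaf_c) - env.rh * saturation_vapor_concentration(env.t_air_c)
    if dc <= 0:
        raise DomainError(
            "leaf-air vapour concentration difference must be positive "
            "(air saturated or supersaturated relative to the leaf)"
        )
    return mass_loss_rate_kg_s / (2.0 * projected_area_m2 * dc)
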