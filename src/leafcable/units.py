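"""Physical constants and unit conversions for leaf hydraulic conductances.

Three unit systems coexist in leaf hydraulics work and are bridged here:

* whole-leaf axial (xylem) conductance from conduit anatomy,
  ``m^4 s^-1 MPa^-1`` — a Hagen--Poiseuille quantity not yet referenced
  to any leaf dimension;
* volumetric area-normalised conductance, ``m^3 m^-2 s^-1 MPa^-1``
  (i.e. ``m s^-1 MPa^-1``), the model's internal working unit;
* molar area-normalised conductance, ``mmol m^-2 s^-1 MPa^-1``, the
  reporting unit conventional in the leaf-hydraulics literature.

Conversions depend on the temperature of liquid water through its dynamic
viscosity and molar density; both are evaluated from documented empirical
correlations valid on 0--50 degC, the range of any plausible leaf
measurement.  Functions operate on plain floats whose units are part of
the argument and return names (``kx_raw_m4``, ``k_mmol`` ...); mixing
unit systems is prevented by naming, not by runtime tags.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "WATER_MOLAR_MASS_KG_MOL",
    "DomainError",
    "water_viscosity",
    "water_molar_density",
    "volumetric_to_molar",
    "molar_to_volumetric",
    "normalize_axial",
]

#: Molar mass of water, kg mol^-1.
WATER_MOLAR_MASS_KG_MOL = 18.015e-3

# Density of air-free liquid water at 101.325 kPa, kg m^-3, 0-50 degC in
# 5 degC steps (CRC Handbook style values); linear interpolation between
# nodes is accurate to <0.01% on this range.
_DENSITY_T_C = np.arange(0.0, 55.0, 5.0)
_DENSITY_KG_M3 = np.array(
    [
        999.84, 999.97, 999.70, 999.10, 998.21, 997.05,
        995.65, 994.03, 992.22, 990.21, 988.04,
    ]
)

_T_MIN_C, _T_MAX_C = 0.0, 50.0


class DomainError(ValueError):
    """An input is outside the physical domain an operation is defined on."""


def _check_temperature(t_c: float) -> float:
    t_c = float(t_c)
    if not (_T_MIN_C <= t_c <= _T_MAX_C) or not np.isfinite(t_c):
        raise DomainError(
            f"temperature {t_c!r} degC outside supported range "
            f"[{_T_MIN_C}, {_T_MAX_C}]"
        )
    return t_c


def water_viscosity(t_c: float) -> float:
    """Dynamic viscosity of liquid water, Pa s.

    Vogel three-parameter correlation
    ``eta = 1e-3 * exp(-3.7188 + 578.919 / (T_K - 137.546))`` with T_K in
    kelvin, accurate to ~0.3% on 0--50 degC; eta(20 degC) = 1.0017e-3 Pa s.

    Parameters
    ----------
    t_c
        Water temperature in degrees Celsius, in [0, 50].
    """
    t_c = _check_temperature(t_c)
    t_k = t_c + 273.15
    return 1e-3 * float(np.exp(-3.7188 + 578.919 / (t_k - 137.546)))


def water_molar_density(t_c: float) -> float:
    """Molar density of liquid water, mol m^-3 (55 410 at 20 degC)."""
    t_c = _check_temperature(t_c)
    rho = float(np.interp(t_c, _DENSITY_T_C, _DENSITY_KG_M3))
    return rho / WATER_MOLAR_MASS_KG_MOL


def volumetric_to_molar(k_vol: float, t_c: float = 20.0) -> float:
    """Convert a conductance from m^3 m^-2 s^-1 MPa^-1 to mmol m^-2 s^-1 MPa^-1.

    Multiplies by the molar density of liquid water at ``t_c`` and rescales
    mol -> mmol.  Linear, so applies equally to fluxes.
    """
    k_vol = float(k_vol)
    if k_vol < 0 or not np.isfinite(k_vol):
        raise DomainError(f"conductance must be finite and >= 0, got {k_vol!r}")
    return k_vol * water_molar_density(t_c) * 1e3


def molar_to_volumetric(k_mmol: float, t_c: float = 20.0) -> float:
    """Inverse of :func:`volumetric_to_molar`."""
    k_mmol = float(k_mmol)
    if k_mmol < 0 or not np.isfinite(k_mmol):
        raise DomainError(f"conductance must be finite and >= 0, got {k_mmol!r}")
    return k_mmol / (water_molar_density(t_c) * 1e3)


def normalize_axial(
    kx_raw_m4: float, length_m: float, area_m2: float, t_c: float = 20.0
) -> float:
    """Express whole-leaf axial conductance per unit leaf area in molar units.

    The Hagen--Poiseuille axial conductance (m^4 s^-1 MPa^-1) is divided by
    blade length and projected leaf area, then converted to
    mmol m^-2 s^-1 MPa^-1.  This is the axial value that enters resistance
    partitioning alongside area-normalised whole-leaf and outside-xylem
    conductances.

    Parameters
    ----------
    kx_raw_m4
        Axial conductance, m^4 s^-1 MPa^-1, >= 0.
    length_m, area_m2
        Blade length (m) and projected area (m^2), both > 0.
    t_c
        Temperature for the molar conversion (degC).
    """
    if kx_raw_m4 < 0 or not np.isfinite(kx_raw_m4):
        raise DomainError(f"kx_raw must be finite and >= 0, got {kx_raw_m4!r}")
    if length_m <= 0 or area_m2 <= 0:
        raise DomainError(
            f"length and area must be positive, got {length_m!r}, {area_m2!r}"
        )
    return volumetric_to_molar(kx_raw_m4 / (length_m * area_m2), t_c)
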