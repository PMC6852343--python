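"""Theoretical xylem conductance from tracheid morphometrics and dye surveys.

The axial conductance of a leaf whose only conducting elements are
tracheids is estimated from lumen diameters with the Hagen--Poiseuille
equation,

    K_x = sum_i  pi * d_i^4 / (128 * eta),

summed over the N tracheids of the leaf, where a measured sample of veins
is scaled up to the leaf's full vein census.  This is a maximum,
frictionless-endwall value: pit membranes, tracheid taper and conduit
connectivity are deliberately not modelled.

Dye uptake surveys (stained vs unstained main veins) provide a
field-practical estimate of the embolised fraction; multiplying K_x by
the stained fraction yields the embolism-adjusted conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import DomainError

__all__ = [
    "VeinAnatomy",
    "StainSurvey",
    "count_veins",
    "hagen_poiseuille_kx",
    "percent_embolism",
    "stain_adjusted_kx",
]


@dataclass(frozen=True)
class VeinAnatomy:
    """Vein census inputs and per-vein tracheid diameter samples.

    Parameters
    ----------
    vein_density_per_mm
        Main veins per millimetre across the leaf width (> 0).
    leaf_width_mm
        Leaf blade width in mm (> 0).
    tracheid_diameters_um
        One sequence of lumen diameters (um) per measured vein; every
        diameter > 0 and at least one vein with at least one tracheid.
    """

    vein_density_per_mm: float
    leaf_width_mm: float
    tracheid_diameters_um: tuple = field(default=())

    def __post_init__(self):
        if self.vein_density_per_mm <= 0:
            raise DomainError("vein_density_per_mm must be > 0")
        if self.leaf_width_mm <= 0:
            raise DomainError("leaf_width_mm must be > 0")
        veins = tuple(tuple(float(d) for d in v) for v in self.tracheid_diameters_um)
        object.__setattr__(self, "tracheid_diameters_um", veins)
        if not veins or all(len(v) == 0 for v in veins):
            raise DomainError("at least one vein with >= 1 tracheid diameter required")
        for v in veins:
            if any(d <= 0 or not np.isfinite(d) for d in v):
                raise DomainError("all tracheid diameters must be finite and > 0")

    @property
    def n_veins(self) -> int:
        """Whole-leaf main-vein census (see :func:`count_veins`)."""
        return count_veins(self.vein_density_per_mm, self.leaf_width_mm)


@dataclass(frozen=True)
class StainSurvey:
    """Counts of dye-stained vs total main veins in a leaf section."""

    stained: int
    total: int

    def __post_init__(self):
        if self.total < 1:
            raise DomainError("total vein count must be >= 1")
        if not (0 <= self.stained <= self.total):
            raise DomainError("stained count must be in [0, total]")

    @property
    def stained_fraction(self) -> float:
        return self.stained / self.total


def count_veins(vein_density_per_mm: float, leaf_width_mm: float) -> int:
    """Main veins across the blade: round(density x width), floored at 1."""
    if vein_density_per_mm <= 0 or leaf_width_mm <= 0:
        raise DomainError("vein density and leaf width must be positive")
    return max(1, round(vein_density_per_mm * leaf_width_mm))


def hagen_poiseuille_kx(anatomy: VeinAnatomy, eta_pa_s: float) -> float:
    """Whole-leaf axial xylem conductance, m^4 s^-1 MPa^-1.

    The measured veins give a mean per-vein sum of ``pi d^4 / (128 eta)``,
    which is multiplied by the whole-leaf vein census.  Pressure is in
    MPa, hence the 1e6 factor on the Pa-based Poiseuille term.
    """
    if eta_pa_s <= 0 or not np.isfinite(eta_pa_s):
        raise DomainError("viscosity must be finite and > 0")
    per_vein = [
        np.sum(np.pi * (np.asarray(v, dtype=float) * 1e-6) ** 4) / (128.0 * eta_pa_s)
        for v in anatomy.tracheid_diameters_um
        if len(v) > 0
    ]
    if not per_vein:
        raise DomainError("anatomy contains no tracheid diameters")
    return float(np.mean(per_vein)) * anatomy.n_veins * 1e6


def percent_embolism(survey: StainSurvey) -> float:
    """Unstained main veins as a percentage of all main veins, in [0, 100]."""
    return 100.0 * (survey.total - survey.stained) / survey.total


def stain_adjusted_kx(kx: float, stained_fraction: float) -> float:
    """Scale an axial conductance by the stained (conducting) vein fraction.

    Unit-preserving: applies identically to raw (m^4) and area-normalised
    (mmol) values.
    """
    if not (0.0 <= stained_fraction <= 1.0):
        raise DomainError(f"stained_fraction must be in [0, 1], got {stained_fraction!r}")
    if kx < 0:
        raise DomainError("conductance must be >= 0")
    return kx * stained_fraction
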