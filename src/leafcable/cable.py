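"""Leaky-cable model of leaf water transport.

Water enters a parallel-veined blade at its base, flows axially down the
xylem "cable" and leaks radially through the outside-xylem tissue along
the blade length *l*.  With axial conductance K_x (m^4 s^-1 MPa^-1),
radial (outside-xylem) conductance per unit leaf area k_ox
(m^3 m^-2 s^-1 MPa^-1) and blade width *w* (m), the whole-leaf
conductance is

    K_leaf = k_ox * tanh(alpha*l) / (alpha*l),   alpha = sqrt(w * k_ox / K_x)

so K_leaf <= k_ox always, with equality in the limit of a non-limiting
xylem (alpha*l -> 0).  The model is preferred here to an electrical
series/parallel analogue because the two pathways are neither strictly in
series nor in parallel.

The practical use is inverse: K_leaf is measured (evaporative flux
method) and K_x computed from anatomy; k_ox is then the unique root of
the forward relation, found by damped fixed-point iteration with a
bracketing fallback.  All conductances in this module are volumetric;
convert at the reporting boundary with :mod:`leafcable.units`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .units import DomainError

__all__ = [
    "LeafGeometry",
    "CableState",
    "SensitivityCurve",
    "ConvergenceError",
    "NoHalvingPointError",
    "alpha_length",
    "forward_kleaf",
    "solve_kox",
    "solve_kox_bisection",
    "resistance_fractions",
    "sensitivity_curve",
    "find_halving_fraction",
]

# Below this, tanh(x)/x is 1 to double precision; avoids 0/0.
_SMALL_ALPHA_L = 1e-8


class ConvergenceError(RuntimeError):
    """The inverse solver failed to meet its residual tolerance."""


class NoHalvingPointError(ValueError):
    """The xylem is so non-limiting that K_leaf never falls to 50%."""


@dataclass(frozen=True)
class LeafGeometry:
    """Blade width, length and projected area (m, m, m^2)."""

    width_m: float
    length_m: float
    area_m2: float

    def __post_init__(self):
        if min(self.width_m, self.length_m, self.area_m2) <= 0:
            raise DomainError("leaf width, length and area must all be positive")
        if self.area_m2 > self.width_m * self.length_m * (1 + 1e-9):
            raise DomainError("projected area exceeds the blade bounding box w*l")


@dataclass(frozen=True)
class CableState:
    """A solved cable: measured K_leaf, anatomical K_x and inferred k_ox.

    ``k_leaf`` and ``k_ox`` are volumetric per-leaf-area conductances
    (m^3 m^-2 s^-1 MPa^-1); ``kx_raw_m4`` is the whole-leaf axial value
    (m^4 s^-1 MPa^-1); ``alpha_l`` is the dimensionless cable parameter
    at the solution.
    """

    k_leaf: float
    kx_raw_m4: float
    k_ox: float
    alpha_l: float

    def __post_init__(self):
        if min(self.k_leaf, self.kx_raw_m4, self.k_ox, self.alpha_l) < 0:
            raise DomainError("cable state requires non-negative fields")
        if self.k_ox < self.k_leaf * (1 - 1e-9):
            raise DomainError("solved k_ox cannot fall below k_leaf (tanh(x)/x <= 1)")


@dataclass(frozen=True)
class SensitivityCurve:
    """K_leaf response to scaling K_x at fixed outside-xylem conductance."""

    fractions: np.ndarray
    kleaf_ratio: np.ndarray
    baseline_alpha_l: float


def _tanh_over_x(x: float) -> float:
    return 1.0 if x < _SMALL_ALPHA_L else float(np.tanh(x)) / x


def alpha_length(k_ox: float, kx_raw_m4: float, geom: LeafGeometry) -> float:
    """Dimensionless cable parameter alpha*l = l*sqrt(w*k_ox/K_x)."""
    if k_ox < 0:
        raise DomainError("k_ox must be >= 0")
    if kx_raw_m4 <= 0:
        raise DomainError("kx_raw must be > 0 (alpha diverges at zero)")
    return geom.length_m * float(np.sqrt(geom.width_m * k_ox / kx_raw_m4))


def forward_kleaf(k_ox: float, alpha_l: float) -> float:
    """Whole-leaf conductance k_ox*tanh(alpha*l)/(alpha*l); k_ox at alpha*l=0."""
    if k_ox < 0 or alpha_l < 0:
        raise DomainError("k_ox and alpha_l must be >= 0")
    return k_ox * _tanh_over_x(alpha_l)


def _forward_from_kox(k_ox: float, kx_raw_m4: float, geom: LeafGeometry) -> float:
    return forward_kleaf(k_ox, alpha_length(k_ox, kx_raw_m4, geom))


def _expand_bracket(k_leaf: float, kx_raw_m4: float, geom: LeafGeometry) -> float:
    # g(k_ox) is strictly increasing, g(k_leaf) <= k_leaf: expand upward.
    hi = k_leaf
    for _ in range(200):
        hi *= 2.0
        if _forward_from_kox(hi, kx_raw_m4, geom) >= k_leaf:
            return hi
    raise ConvergenceError("could not bracket the k_ox root")


def solve_kox(
    k_leaf: float,
    kx_raw_m4: float,
    geom: LeafGeometry,
    rtol: float = 1e-12,
    max_iter: int = 10_000,
) -> CableState:
    """Invert the cable model: find k_ox given measured K_leaf and K_x.

    Starts the fixed-point iteration ``k_ox <- K_leaf * alpha_l/tanh(alpha_l)``
    at ``k_ox = K_leaf`` and damps on oscillation; if the iteration stalls,
    falls back to root bracketing (Brent) on the strictly increasing forward
    map.  The returned state satisfies the forward relation to a relative
    residual <= 1e-10.

    Raises
    ------
    ConvergenceError
        If no solver reaches the residual tolerance (never returns a
        partial result).
    """
    if k_leaf <= 0:
        raise DomainError("measured k_leaf must be > 0")
    if kx_raw_m4 <= 0:
        raise DomainError("kx_raw must be > 0")

    k_ox = k_leaf
    damping = 1.0
    prev_step = 0.0
    converged = False
    for _ in range(max_iter):
        al = alpha_length(k_ox, kx_raw_m4, geom)
        target = k_leaf / _tanh_over_x(al)
        step = target - k_ox
        if step * prev_step < 0:  # oscillation: damp
            damping *= 0.5
        k_new = k_ox + damping * step
        if abs(k_new - k_ox) <= rtol * k_ox:
            k_ox = k_new
            converged = True
            break
        prev_step = step
        k_ox = k_new

    if not converged or not np.isfinite(k_ox):
        lo, hi = k_leaf, _expand_bracket(k_leaf, kx_raw_m4, geom)
        k_ox = brentq(
            lambda k: _forward_from_kox(k, kx_raw_m4, geom) - k_leaf,
            lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200,
        )

    residual = abs(_forward_from_kox(k_ox, kx_raw_m4, geom) - k_leaf) / k_leaf
    if residual > 1e-10:
        raise ConvergenceError(f"k_ox solver residual {residual:.3e} > 1e-10")
    # tanh(x)/x <= 1 guarantees k_ox >= k_leaf; clip roundoff at the boundary
    k_ox = max(k_ox, k_leaf)
    return CableState(
        k_leaf=k_leaf,
        kx_raw_m4=kx_raw_m4,
        k_ox=k_ox,
        alpha_l=alpha_length(k_ox, kx_raw_m4, geom),
    )


def solve_kox_bisection(
    k_leaf: float,
    kx_raw_m4: float,
    geom: LeafGeometry,
    tol: float = 1e-12,
) -> CableState:
    """Inverse solve by plain interval bisection on the monotone forward map.

    Independent of the fixed-point path in :func:`solve_kox`; used to
    cross-check it.
    """
    if k_leaf <= 0 or kx_raw_m4 <= 0:
        raise DomainError("k_leaf and kx_raw must be > 0")
    lo, hi = k_leaf, _expand_bracket(k_leaf, kx_raw_m4, geom)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _forward_from_kox(mid, kx_raw_m4, geom) < k_leaf:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * lo:
            break
    k_ox = 0.5 * (lo + hi)
    residual = abs(_forward_from_kox(k_ox, kx_raw_m4, geom) - k_leaf) / k_leaf
    if residual > 1e-10:
        raise ConvergenceError(f"bisection residual {residual:.3e} > 1e-10")
    k_ox = max(k_ox, k_leaf)
    return CableState(k_leaf, kx_raw_m4, k_ox, alpha_length(k_ox, kx_raw_m4, geom))


def resistance_fractions(kx_norm: float, k_ox: float) -> tuple[float, float]:
    """Percent shares of the summed pathway resistances (R = 1/K).

    Both conductances must be on the same area-normalised scale.  Returns
    ``(rx_pct, rox_pct)`` summing to 100.
    """
    if kx_norm <= 0 or k_ox <= 0:
        raise DomainError("resistance fractions need strictly positive conductances")
    rx, rox = 1.0 / kx_norm, 1.0 / k_ox
    total = rx + rox
    return 100.0 * rx / total, 100.0 * rox / total


def _kleaf_ratio(f, alpha_l0: float):
    """K_leaf(f*K_x)/K_leaf(K_x) at fixed k_ox: sqrt(f)*tanh(al0/sqrt(f))/tanh(al0)."""
    f = np.asarray(f, dtype=float)
    root_f = np.sqrt(f)
    return root_f * np.tanh(alpha_l0 / root_f) / np.tanh(alpha_l0)


def sensitivity_curve(
    baseline: "CableState | float",
    fractions=None,
) -> SensitivityCurve:
    """K_leaf sensitivity to K_x degradation at fixed outside-xylem pathway.

    Holding the wet-baseline k_ox constant and scaling K_x by each
    fraction *f* rescales the cable parameter by 1/sqrt(f); the resulting
    K_leaf, relative to baseline, reduces to
    ``sqrt(f) * tanh(al0/sqrt(f)) / tanh(al0)``.

    Parameters
    ----------
    baseline
        Solved :class:`CableState` or the baseline alpha*l directly.
    fractions
        Grid in (0, 1]; default 100 log-spaced points on [0.01, 1].
    """
    alpha_l0 = baseline.alpha_l if isinstance(baseline, CableState) else float(baseline)
    if alpha_l0 <= 0:
        raise DomainError("baseline alpha_l must be > 0")
    if fractions is None:
        fractions = np.logspace(-2, 0, 100)
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise DomainError("fractions must lie in (0, 1]")
    return SensitivityCurve(
        fractions=fractions,
        kleaf_ratio=_kleaf_ratio(fractions, alpha_l0),
        baseline_alpha_l=alpha_l0,
    )


def find_halving_fraction(baseline_alpha_l: float, tol: float = 1e-9) -> float:
    """Fraction of baseline K_x at which K_leaf is halved (k_ox fixed).

    Bisects the strictly increasing ratio curve to |ratio - 0.5| <= tol.

    Raises
    ------
    NoHalvingPointError
        If the ratio stays above 0.5 down to f = 1e-9 (alpha*l so small
        that the xylem never becomes limiting at meaningful fractions).
    """
    if baseline_alpha_l <= 0:
        raise DomainError("baseline_alpha_l must be > 0")
    lo, hi = 1e-9, 1.0
    if _kleaf_ratio(lo, baseline_alpha_l) > 0.5:
        raise NoHalvingPointError(
            "K_leaf ratio exceeds 0.5 for all f >= 1e-9; no halving point"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = float(_kleaf_ratio(mid, baseline_alpha_l))
        if abs(r - 0.5) <= tol:
            return mid
        if r < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
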