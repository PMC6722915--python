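"""Stylet ejection mechanics: shape, elastic restraint, fold threshold.

The stylet is an axisymmetric dart whose radius along the axis follows the
"carrot" profile

    beta(xi) = a * xi * (l - xi) / (d + xi),        0 <= xi <= l,

with end slopes a*l/d (blunt base) and -a*l/(d+l) (tip), and a single apex
of radius beta_x = a*(l + 2d - 2*sqrt(d*(l+d))) at xi1 = sqrt(d*(l+d)) - d.
It is held at the exit orifice by an elastic collar (mini-collagen fibrils)
of Young's modulus Y, cross-section alpha and unstretched radius beta0.

Quasi-static force balance: the Coulomb pressure p pushes the stylet out
with force pi*beta^2*p; the stretched collar, resting on the descending
flank of the stylet at axial position xi_plus(beta) > xi1, pushes back with
force (-dbeta/dxi)|_{xi_plus} * 2*pi*alpha*Y*(beta - beta0)/beta0.  The
balancing pressure p(beta) rises from zero at beta = beta0, peaks, and
falls back to zero at the apex — a saddle-node (fold) structure.  The peak
is the threshold pressure P_thres: above it no static equilibrium exists
and the stylet is ejected.  A closed-form small-collar approximation,

    P_thres ~ (1 - d) * Y * a * alpha / (2 * r0^2),

holds when the collar is much narrower than the apex (beta0 = r0 << beta_x).

Scaled units throughout: lengths in units of the stylet length l, pressures
in units of Y.  SI conversion, when needed, happens at the interface layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .exceptions import DomainError, EjectionError

__all__ = [
    "StyletShape",
    "StyletApex",
    "ElasticRestraint",
    "EquilibriumState",
    "StyletInertia",
    "stylet_radius",
    "stylet_slope",
    "stylet_apex",
    "inverse_axial_position",
    "balance_pressure",
    "equilibrium_radius",
    "displacement",
    "threshold_pressure",
    "max_acceleration",
    "max_acceleration_parametric",
]


@dataclass(frozen=True)
class StyletShape:
    """Carrot-shaped stylet profile parameters.

    ``a`` sets the overall radius scale, ``l`` the stylet length (1 in scaled
    units) and ``d`` the shoulder sharpness: small d pushes the apex toward
    the blunt base and steepens the base slope a*l/d.
    """

    a: float
    l: float = 1.0
    d: float = 0.01

    def __post_init__(self):
        if not self.a > 0:
            raise DomainError("StyletShape.a must be strictly positive")
        if not self.l > 0:
            raise DomainError("StyletShape.l must be strictly positive")
        if not (0 < self.d < self.l):
            raise DomainError("StyletShape.d must satisfy 0 < d < l")


@dataclass(frozen=True)
class StyletApex:
    """Apex location xi1 and maximum radius beta_x of a stylet."""

    xi1: float
    beta_x: float


@dataclass(frozen=True)
class ElasticRestraint:
    """Elastic collar at the exit orifice.

    ``Y``: Young's modulus of the restraining material (the pressure unit in
    scaled mode); ``alpha``: collar cross-section; ``beta0``: unstretched
    collar radius; ``r0``: exit-orifice radius entering the closed-form
    threshold approximation (conventionally equal to beta0).
    """

    Y: float = 1.0
    alpha: float = 1.0
    beta0: float = 0.005
    r0: Optional[float] = None

    def __post_init__(self):
        if self.r0 is None:
            object.__setattr__(self, "r0", self.beta0)
        for name in ("Y", "alpha", "beta0", "r0"):
            if not getattr(self, name) > 0:
                raise DomainError(f"ElasticRestraint.{name} must be strictly positive")


@dataclass(frozen=True)
class EquilibriumState:
    """Static equilibrium of the collar-stylet balance at pressure ``p``."""

    p: float
    beta: float
    xi: float
    delta: float


@dataclass(frozen=True)
class StyletInertia:
    """Stylet mass ``m`` and thrust radius ``Rx`` (defaults to the apex radius)."""

    m: float
    Rx: float

    def __post_init__(self):
        if not self.m > 0:
            raise DomainError("StyletInertia.m must be strictly positive")
        if not self.Rx > 0:
            raise DomainError("StyletInertia.Rx must be strictly positive")


# ---------------------------------------------------------------------------
# shape geometry
# ---------------------------------------------------------------------------

def stylet_radius(xi, shape: StyletShape):
    """Stylet radius beta(xi) = a xi (l - xi) / (d + xi); zero at both ends."""
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < 0) or np.any(xi_arr > shape.l * (1 + 1e-12)):
        raise DomainError("xi outside [0, l]")
    beta = shape.a * xi_arr * (shape.l - xi_arr) / (shape.d + xi_arr)
    return float(beta) if np.isscalar(xi) else beta


def stylet_slope(xi, shape: StyletShape):
    """dbeta/dxi = a (l d - 2 d xi - xi^2) / (d + xi)^2."""
    xi_arr = np.asarray(xi, dtype=float)
    s = shape.a * (shape.l * shape.d - 2 * shape.d * xi_arr - xi_arr**2) / (shape.d + xi_arr) ** 2
    return float(s) if np.isscalar(xi) else s


def stylet_apex(shape: StyletShape) -> StyletApex:
    """Apex of the carrot profile.

    The slope vanishes where xi^2 + 2 d xi - l d = 0, i.e. at
    xi1 = sqrt(d (l + d)) - d, giving the maximum radius
    beta_x = a (l + 2 d - 2 sqrt(d (l + d))).
    """
    s = math.sqrt(shape.d * (shape.l + shape.d))
    xi1 = s - shape.d
    beta_x = shape.a * (shape.l + 2 * shape.d - 2 * s)
    return StyletApex(xi1=xi1, beta_x=beta_x)


def inverse_axial_position(beta: float, shape: StyletShape, branch: str = "descending") -> float:
    """Axial position(s) where the stylet has radius ``beta``.

    Inverts the quadratic a xi^2 + (beta - a l) xi + beta d = 0; the
    ``ascending`` branch returns the root left of the apex (xi <= xi1), the
    ``descending`` branch the root right of it (xi >= xi1, where the collar
    rests during ejection).
    """
    if branch not in ("ascending", "descending"):
        raise ValueError("branch must be 'ascending' or 'descending'")
    apex = stylet_apex(shape)
    if beta < 0 or beta > apex.beta_x * (1 + 1e-12):
        raise DomainError(f"beta={beta} outside [0, beta_x={apex.beta_x}]")
    a, l, d = shape.a, shape.l, shape.d
    half = (a * l - beta) / (2 * a)
    disc = max(half * half - beta * d / a, 0.0)
    root = math.sqrt(disc)
    return half + root if branch == "descending" else half - root


# ---------------------------------------------------------------------------
# force balance and fold threshold
# ---------------------------------------------------------------------------

def balance_pressure(beta, shape: StyletShape, restraint: ElasticRestraint):
    """Pressure at which the collar radius ``beta`` is an equilibrium.

    From the static balance pi beta^2 p = (-dbeta/dxi)|_{xi+} * 2 pi alpha Y
    (beta - beta0)/beta0, with the restoring slope taken at the
    descending-branch contact point xi+(beta):

        p(beta) = 2 alpha Y (beta - beta0) (-beta'(xi+)) / (beta0 beta^2).

    Vanishes at beta = beta0 and at the apex; the maximum in between is the
    fold (threshold) pressure.
    """
    beta_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    apex = stylet_apex(shape)
    a, l, d = shape.a, shape.l, shape.d
    half = (a * l - beta_arr) / (2 * a)
    disc = np.maximum(half * half - beta_arr * d / a, 0.0)
    xi_p = half + np.sqrt(disc)
    slope = shape.a * (l * d - 2 * d * xi_p - xi_p**2) / (d + xi_p) ** 2
    p = 2 * restraint.alpha * restraint.Y * (beta_arr - restraint.beta0) * (-slope) / (
        restraint.beta0 * beta_arr**2
    )
    return float(p[0]) if np.isscalar(beta) else p


def threshold_pressure(
    shape: StyletShape, restraint: ElasticRestraint, method: str = "numeric"
) -> float:
    """Threshold (fold) pressure above which no static equilibrium exists.

    ``numeric``: maximize the balancing pressure over collar radii
    beta in (beta0, beta_x] — coarse sweep followed by golden-section
    refinement (xatol 1e-13 relative to the apex radius).
    ``approx``: the small-collar closed form (1 - d) Y a alpha / (2 r0^2).
    """
    apex = stylet_apex(shape)
    if restraint.beta0 >= apex.beta_x:
        raise DomainError(
            f"beta0={restraint.beta0} must be below the apex radius beta_x={apex.beta_x}: "
            "otherwise the collar never restrains the stylet"
        )
    if method == "approx":
        return (1 - shape.d) * restraint.Y * shape.a * restraint.alpha / (2 * restraint.r0**2)
    if method != "numeric":
        raise ValueError("method must be 'numeric' or 'approx'")

    lo = restraint.beta0 * (1 + 1e-9)
    hi = apex.beta_x
    # coarse geometric sweep: the fold can sit arbitrarily close to beta0
    grid = np.geomspace(lo, hi, 4096)
    p_grid = balance_pressure(grid, shape, restraint)
    i = int(np.argmax(p_grid))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda b: -balance_pressure(b, shape, restraint),
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": 1e-13 * hi},
    )
    return float(-res.fun)


def _fold_radius(shape: StyletShape, restraint: ElasticRestraint) -> tuple[float, float]:
    """Collar radius at the fold and the fold pressure."""
    apex = stylet_apex(shape)
    lo = restraint.beta0 * (1 + 1e-9)
    hi = apex.beta_x
    grid = np.geomspace(lo, hi, 4096)
    p_grid = balance_pressure(grid, shape, restraint)
    i = int(np.argmax(p_grid))
    res = minimize_scalar(
        lambda b: -balance_pressure(b, shape, restraint),
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-13 * hi},
    )
    return float(res.x), float(-res.fun)


def equilibrium_radius(
    p: float, shape: StyletShape, restraint: ElasticRestraint
) -> EquilibriumState:
    """Stable equilibrium collar radius beta(p) on the rising branch.

    At p = 0 the collar is unstretched (beta = beta0); beta increases
    monotonically with p up to the fold radius.  Above the fold pressure an
    :class:`~nemadischarge.exceptions.EjectionError` is raised carrying the
    threshold value.
    """
    if p < 0:
        raise DomainError("pressure must be non-negative")
    b_fold, p_thres = _fold_radius(shape, restraint)
    if p > p_thres:
        raise EjectionError(
            f"no static equilibrium at p={p}: exceeds threshold {p_thres}", threshold=p_thres
        )
    if p == 0:
        beta = restraint.beta0
    else:
        f = lambda b: balance_pressure(b, shape, restraint) - p
        beta = brentq(f, restraint.beta0, b_fold, xtol=1e-15, rtol=1e-14)
    xi = inverse_axial_position(beta, shape, "descending")
    delta = xi - inverse_axial_position(restraint.beta0, shape, "descending")
    return EquilibriumState(p=float(p), beta=float(beta), xi=float(xi), delta=float(delta))


def displacement(p: float, shape: StyletShape, restraint: ElasticRestraint) -> float:
    """Axial displacement delta(p) of the contact point below threshold.

    delta = xi+(beta(p)) - xi+(beta0): the descending-branch contact point
    slides from its rest position toward the apex as the collar dilates, so
    delta is negative and |delta| grows without bound in slope (d|delta|/dp
    diverges) as p approaches the fold.  Raises EjectionError at or above
    the threshold.
    """
    state = equilibrium_radius(p, shape, restraint)
    return state.delta


# ---------------------------------------------------------------------------
# acceleration
# ---------------------------------------------------------------------------

def max_acceleration(p_thres: float, inertia: StyletInertia) -> float:
    """Peak acceleration f_max = P_thres pi Rx^2 / m from the thrust balance."""
    if p_thres <= 0:
        raise DomainError("p_thres must be strictly positive")
    return p_thres * math.pi * inertia.Rx**2 / inertia.m


def max_acceleration_parametric(
    shape: StyletShape, restraint: ElasticRestraint, m: float
) -> float:
    """Peak acceleration from the parametric closed form

        f_max = Y alpha pi a^3 (1 - d)^2 (1.18 + 7 d) / (m r0^2).

    Evaluated verbatim; its numeric prefactor is not derivable from the
    thrust balance composed with the small-collar threshold (the ratio of
    the two estimates is reported by the interface layer, not asserted).
    """
    if m <= 0:
        raise DomainError("m must be strictly positive")
    return (
        restraint.Y
        * restraint.alpha
        * math.pi
        * shape.a**3
        * (1 - shape.d) ** 2
        * (1.18 + 7 * shape.d)
        / (m * restraint.r0**2)
    )
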