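"""Dominant-finger selection by the maximum-amplitude criterion.

A mode ``n`` destabilizes when the droplet radius first reaches ``R_n``
(smallest radius with ``sigma_n > 0``).  Its aggregated amplitude gain over
the growth history is

    zeta_n(r0) = exp( int_{R_n}^{r0} sigma_n(r) * (dt/dr) dr ),

and the dominant mode ``n_d(r0)`` maximizes ``zeta_n(r0)``.  The time-per-
radius factor depends on the growth kinetics:

* exponential growth (uniform constant ``k``): the dimensionless interface
  velocity is ``r0/2`` (time unit ``1/k``), hence ``dt/dr = 2/r``;
* linear radius growth (constant interface speed ``nu``): the dimensionless
  interface speed is 1 (time unit ``l/nu``), hence ``dt/dr = 1``.  The local
  growth rate ``k(t) = 2 nu / r0(t)`` then decays as the droplet grows, and
  the dispersion relation expressed in linear-growth units becomes

      sigma_n(r0) = [ (phi-1)(n-1) - n(n^2-1)/r0^2 + Lambda_n(alpha) ]
                    / ( r0 * (phi + 1 + Lambda_n(alpha) - n*alpha) ),

  where now ``alpha = alpha_dim/(beta*nu)`` is radius-independent: activity
  does not fade as the droplet grows, which is why fingering is
  activity-dominated under slow (linear) kinetics.

For large radii the dominant mode follows closed-form scaling laws with the
constant ``c ~ 0.0595``, the smaller root of ``3c = 3 + ln c``:

* exponential, ``phi > 1``:  ``n_d ~ (c (phi-1))^(1/2) r0^(3/2)``;
* exponential, ``phi = 1``:  ``n_d ~ [(alpha/2)^2 + (alpha/2)^(1/2)]^(1/2) r0^(1/2)``;
* exponential, ``phi < 1``:  no asymptotic finger count - destabilized modes
  restabilize as activity fades and the viscosity mismatch takes over;
* linear:  ``n_d ~ (c (alpha + phi - 1))^(1/2) r0``.

Note the ``c^(1/2)`` prefactor in the linear law: it follows from the same
maximization that yields the ``phi > 1`` exponential law and is confirmed by
the numerical maximization in this package's test-suite.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .dispersion import _sigma_value, lambda_mode
from .errors import ConvergenceError, DomainError, ModeCapError, RegimeError
from .onset import _first_upward_root, _search_floor

__all__ = [
    "KineticsSpec",
    "EXPONENTIAL",
    "LINEAR",
    "get_kinetics",
    "AmplitudeTrajectory",
    "DominantMode",
    "destabilization_radius",
    "amplitude_gain",
    "log_amplitude_gain",
    "amplitude_trajectory",
    "dominant_mode",
    "solve_c",
    "asymptotic_nd",
]


@dataclass(frozen=True)
class KineticsSpec:
    """Growth law of the unperturbed droplet radius.

    ``dt_dr`` is the dimensionless time spent per unit radius increase along
    the unperturbed history; ``sigma`` the dispersion relation in that
    kinetics' own units.
    """

    kind: str  # "exponential" or "linear"

    def dt_dr(self, r: float) -> float:
        if not r > 0:
            raise DomainError(f"radius must be > 0, got {r}")
        return 2.0 / r if self.kind == "exponential" else 1.0

    def activity_x(self, alpha: float, r: float) -> float:
        """Argument of Lambda_n along the history."""
        return 2.0 * alpha / r if self.kind == "exponential" else alpha

    def check_activity(self, alpha: float) -> None:
        """Validity guard for the whole growth history.

        Exponential growth: validity depends on radius (alpha < r/2) and is
        enforced where radii are known.  Linear growth: the condition is
        radius-independent, ``alpha < 1``; ``alpha = 1`` is the marginal
        boundary, evaluable as the continuous limit ``x -> 1`` and accepted.
        """
        if alpha < 0:
            raise DomainError(f"alpha must be >= 0, got {alpha}")
        if self.kind == "linear" and alpha > 1.0:
            raise RegimeError(
                f"linear-growth activity alpha = {alpha} > 1: high-activity "
                f"regime at every radius"
            )

    def sigma(self, n: int, r: float, alpha: float, phi: float) -> float:
        """Mode growth rate in this kinetics' dimensionless units."""
        if self.kind == "exponential":
            return _sigma_value(n, r, alpha, phi)
        self.check_activity(alpha)
        lam = lambda_mode(n, alpha)
        numerator = (phi - 1.0) * (n - 1.0) - n * (n * n - 1.0) / r**2 + lam
        denominator = r * (phi + 1.0 + lam - n * alpha)
        return numerator / denominator

    def floor(self, alpha: float) -> float:
        """Lower radius bound of the valid (low-activity) history."""
        return _search_floor(alpha) if self.kind == "exponential" else 1e-2


EXPONENTIAL = KineticsSpec("exponential")
LINEAR = KineticsSpec("linear")


def get_kinetics(kind: str) -> KineticsSpec:
    table = {"exponential": EXPONENTIAL, "exp": EXPONENTIAL, "linear": LINEAR, "lin": LINEAR}
    try:
        return table[kind]
    except KeyError:
        raise DomainError(f"unknown kinetics {kind!r}") from None


@lru_cache(maxsize=100_000)
def _destab_radius_cached(
    n: int, alpha: float, phi: float, kind: str, r_max: float
) -> float | None:
    kinetics = get_kinetics(kind)
    kinetics.check_activity(alpha)
    if kind == "linear":
        lam = lambda_mode(n, alpha)
        a = (phi - 1.0) * (n - 1.0) + lam
        if a <= 0.0:
            return None
        radius = math.sqrt(n * (n * n - 1.0) / a)
        return radius if radius <= r_max else None
    if alpha == 0.0:
        if phi <= 1.0:
            return None  # passive, non-fingering: sigma_n < 0 for all n >= 2
        radius = (n * (n + 1.0) / (phi - 1.0)) ** (1.0 / 3.0)
        return radius if radius <= r_max else None
    root, _at_floor = _first_upward_root(
        lambda r: kinetics.sigma(n, r, alpha, phi),
        kinetics.floor(alpha),
        r_max,
        n_scan=300,
        xtol=1e-9,
    )
    return root


def destabilization_radius(
    n: int,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
    r_max: float = 1e6,
) -> float | None:
    """Smallest radius at which mode ``n`` has positive growth rate.

    Returns ``None`` (with a warning at the cap) when the mode is never
    destabilized below ``r_max``.  A mode already unstable at the
    low-activity validity floor is reported at the floor radius.
    """
    if isinstance(n, bool) or not isinstance(n, int) or n < 2:
        raise DomainError(f"destabilization is defined for integer modes n >= 2, got {n!r}")
    result = _destab_radius_cached(n, float(alpha), float(phi), kinetics.kind, float(r_max))
    if result is None and (
        kinetics.kind == "exponential" and (alpha > 0.0 or phi > 1.0)
    ):
        # distinguish "stable for ever" from "not found below the cap" cheaply:
        # only warn when sigma is still negative but rising at the cap.
        s_hi = kinetics.sigma(n, r_max, alpha, phi)
        s_lo = kinetics.sigma(n, 0.5 * r_max, alpha, phi)
        if s_hi > s_lo:
            warnings.warn(
                f"mode {n} not destabilized below the search cap r_max = {r_max}",
                stacklevel=2,
            )
    return result


def log_amplitude_gain(
    n: int,
    r0: float,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
    R_n: float | None = None,
) -> float:
    """``ln zeta_n(r0)``: aggregated growth integral of mode ``n``.

    Log form avoids overflow when comparing strongly amplified modes."""
    if R_n is None:
        R_n = destabilization_radius(n, alpha, phi, kinetics)
        if R_n is None:
            raise DomainError(
                f"mode {n} is never destabilized for alpha={alpha}, phi={phi} "
                f"({kinetics.kind} kinetics); zeta is undefined"
            )
    if r0 < R_n:
        raise DomainError(f"r0 = {r0} is below the destabilization radius R_{n} = {R_n}")
    if r0 == R_n:
        return 0.0

    def integrand(u: float) -> float:
        r = math.exp(u)
        return kinetics.sigma(n, r, alpha, phi) * kinetics.dt_dr(r) * r

    value, abserr = quad(
        integrand, math.log(R_n), math.log(r0), epsabs=1e-12, epsrel=1e-10, limit=200
    )
    if abserr > max(1e-8 * abs(value), 1e-7):
        raise ConvergenceError(
            f"quadrature for zeta_{n} did not converge (estimated error {abserr})"
        )
    return value


def amplitude_gain(
    n: int,
    r0: float,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
    R_n: float | None = None,
) -> float:
    """Aggregated amplitude gain ``zeta_n(r0) = exp int sigma dt`` (>= 1 at
    first destabilization; may fall below 1 again if the mode restabilizes)."""
    return math.exp(log_amplitude_gain(n, r0, alpha, phi, kinetics, R_n))


@dataclass(frozen=True)
class AmplitudeTrajectory:
    """Destabilization radius and gain history of one mode."""

    n: int
    R_n: float | None
    zeta: Callable[[float], float] | None

    def __post_init__(self):
        if self.R_n is not None and self.zeta is None:
            raise DomainError("a destabilized trajectory must carry its gain function")


def amplitude_trajectory(
    n: int,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
) -> AmplitudeTrajectory:
    R_n = destabilization_radius(n, alpha, phi, kinetics)
    if R_n is None:
        return AmplitudeTrajectory(n=n, R_n=None, zeta=None)
    return AmplitudeTrajectory(
        n=n,
        R_n=R_n,
        zeta=lambda r0: amplitude_gain(n, r0, alpha, phi, kinetics, R_n=R_n),
    )


@dataclass(frozen=True)
class DominantMode:
    """Mode with the largest aggregated gain at radius ``r0``."""

    r0: float
    n_d: int
    method: str  # "discrete-argmax"
    log_zeta: float


def solve_c() -> float:
    """Smaller positive root of ``3c = 3 + ln c`` (~0.0595).

    The equation also has the root c = 1 (ln 1 = 0), which is the larger
    solution and must not be returned."""
    root = brentq(lambda c: 3.0 * c - 3.0 - math.log(c), 1e-12, 0.9, xtol=1e-14)
    assert root < 0.9  # structurally below the larger root at c = 1
    return root


def _asymptotic_estimate(
    r0: float, alpha: float, phi: float, kinetics: KineticsSpec
) -> float | None:
    """Internal, never-raising variant of :func:`asymptotic_nd`."""
    c = solve_c()
    if kinetics.kind == "linear":
        u = alpha + phi - 1.0
        return math.sqrt(c * u) * r0 if u > 0 else None
    if phi > 1.0:
        return math.sqrt(c * (phi - 1.0)) * r0**1.5
    if phi == 1.0:
        half = alpha / 2.0
        return math.sqrt(half**2 + math.sqrt(half)) * math.sqrt(r0)
    return None


def asymptotic_nd(
    r0: float,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
    branch: str = "auto",
    form: str = "dimensionless",
    params=None,
    nu: float | None = None,
) -> float | None:
    """Closed-form large-radius estimate of the dominant finger number.

    ``branch`` selects the exponential-growth regime explicitly
    (``"viscosity"`` for phi > 1, ``"activity"`` for phi = 1); ``"auto"``
    picks from ``phi``.  Requesting a branch inconsistent with ``phi`` is a
    misuse error.  For exponential growth with ``phi < 1`` there is no
    asymptotic finger count (modes restabilize) and ``None`` is returned.

    With ``form="dimensional"``, ``r0`` is in metres and ``params`` (a
    :class:`~activedrop.params.TissueParameters`, plus ``nu`` for linear
    kinetics) supplies the dimensional inputs; the returned finger count is
    dimensionless either way.
    """
    if form not in ("dimensionless", "dimensional"):
        raise DomainError(f"form must be 'dimensionless' or 'dimensional', got {form!r}")
    if form == "dimensional":
        if params is None:
            raise DomainError("dimensional form requires TissueParameters")
        from .params import nondimensionalize

        dimless = nondimensionalize(params, r0, kinetics.kind, nu)
        return asymptotic_nd(
            dimless.r0, dimless.alpha, dimless.phi, kinetics, branch=branch
        )

    kinetics.check_activity(alpha)
    if kinetics.kind == "linear":
        if branch not in ("auto",):
            raise DomainError("branch selection applies to exponential kinetics only")
        return _asymptotic_estimate(r0, alpha, phi, kinetics)
    if branch == "viscosity" and not phi > 1.0:
        raise DomainError(f"the viscosity-mismatch law requires phi > 1, got phi = {phi}")
    if branch == "activity" and phi != 1.0:
        raise DomainError(f"the activity law requires phi = 1, got phi = {phi}")
    if branch not in ("auto", "viscosity", "activity"):
        raise DomainError(f"unknown branch {branch!r}")
    return _asymptotic_estimate(r0, alpha, phi, kinetics)


def _log_zeta_or_none(
    n: int, r0: float, alpha: float, phi: float, kinetics: KineticsSpec
) -> float | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R_n = destabilization_radius(n, alpha, phi, kinetics)
    if R_n is None or R_n > r0:
        return None
    return log_amplitude_gain(n, r0, alpha, phi, kinetics, R_n=R_n)


def dominant_mode(
    r0: float,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
    n_cap: int | None = None,
) -> DominantMode | None:
    """Mode with the largest aggregated gain ``zeta_n(r0)``; integer argmax.

    ``n_cap`` defaults to three times the applicable asymptotic estimate
    (minimum 64).  Hitting the cap raises :class:`ModeCapError` since the
    maximum may lie beyond it.  Ties break toward the smaller mode.  Returns
    ``None`` when no mode is destabilized at ``r0``.
    """
    if not r0 > 0:
        raise DomainError(f"r0 must be > 0, got {r0}")
    if n_cap is None:
        estimate = _asymptotic_estimate(r0, alpha, phi, kinetics)
        n_cap = max(64, math.ceil(3.0 * estimate)) if estimate else 64
    if n_cap < 2:
        raise DomainError(f"n_cap must be >= 2, got {n_cap}")

    def gain(n: int) -> float | None:
        return _log_zeta_or_none(n, r0, alpha, phi, kinetics)

    cache: dict[int, float | None] = {}

    def cached_gain(n: int) -> float | None:
        if n not in cache:
            cache[n] = gain(n)
        return cache[n]

    def best_of(ns) -> tuple[int | None, float | None]:
        top_n, top_val = None, None
        for n in ns:
            val = cached_gain(int(n))
            if val is not None and (top_val is None or val > top_val):
                top_n, top_val = int(n), val
        return top_n, top_val

    if n_cap <= 96:
        best_n, best_val = best_of(range(2, n_cap + 1))
    else:
        # iterative grid narrowing (the gain profile is smooth in n),
        # finishing with an exhaustive pass over the final window
        lo, hi = 2, n_cap
        while hi - lo > 48:
            grid = np.unique(np.geomspace(lo, hi, 16).astype(int))
            winner, _ = best_of(grid)
            if winner is None:
                # nothing destabilized on the coarse grid: only low modes can
                # be active (destabilization radii grow with n)
                hi = min(hi, 96)
                break
            i = int(np.searchsorted(grid, winner))
            lo = int(grid[max(i - 1, 0)])
            hi = int(grid[min(i + 1, len(grid) - 1)])
        best_n, best_val = best_of(range(lo, hi + 1))
    if best_n is None:
        return None
    if best_n >= n_cap:
        raise ModeCapError(
            f"dominant-mode search hit its cap n_cap = {n_cap}; "
            f"pass a larger n_cap"
        )
    return DominantMode(r0=r0, n_d=best_n, method="discrete-argmax", log_zeta=best_val)
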