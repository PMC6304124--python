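"""Linear-stability dispersion relation of the growing active droplet.

A circular droplet of dimensionless radius ``r0`` made of an active, uniformly
growing Darcy fluid displaces a passive fluid of relative friction ``phi``.
An ``n``-fold periodic perturbation of the interface grows at the
instantaneous dimensionless rate

    sigma_n(r0) = [ (phi-1)(n-1) - n(n^2-1)/r0^3 + Lambda_n(2*alpha/r0) ]
                  / ( 2 * (phi + 1 + Lambda_n(2*alpha/r0) - 2*n*alpha/r0) ),

valid in the low-activity regime ``alpha < r0/2``.  The three terms of the
numerator are the viscosity mismatch, surface tension, and activity.

``Lambda_n`` encodes the activity correction to the interior pressure
perturbation.  The perturbed interior pressure solves

    P'' + P'/rho - n^2 P / (rho (rho - 2*alpha)) = 0,

whose branch analytic at the origin is the polynomial
``P = sum_j a_j (2 alpha)^j rho^(n-j)`` with
``a_j = (-1)^j C(n,j)^2 / C(2n-1,j)``, and

    Lambda_n(x) = n x - 1 + n * S0(x) / S1(x),
    S0 = sum_j a_j x^j,      S1 = sum_j (n-j) a_j x^j,

with ``x = 2*alpha/r0 in [0, 1]``.  ``Lambda_n(0) = 0`` for every n,
``Lambda_1 == 0`` (a pure translation is neutral), ``Lambda_n(1) = n - 1``
(the interior polynomial vanishes at the turning circle ``rho = 2*alpha``),
and ``Lambda_2(x) = x(3x-4)/(2x-3)`` in closed form.

In the passive limit ``alpha -> 0`` the rate reduces to the radial
viscous-fingering result of Paterson (injection rate ``Q = pi r0^2``) plus the
growth correction ``1/(phi+1)`` from the fingers' own growth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from .errors import DomainError, RegimeError

__all__ = [
    "DispersionResult",
    "BaseFlowField",
    "lambda_mode",
    "lambda_mode_exact",
    "lambda2_closed_form",
    "sigma",
    "sigma_passive",
    "paterson_term",
    "base_flow",
    "pressure_condition",
    "regime_check",
]

# Relative cancellation loss (max term over sum) beyond which the float
# evaluation of the binomial sums is abandoned for exact rational arithmetic
# (keeps the float path accurate to ~1e-10 relative).
_CANCEL_LIMIT = 1e5


@lru_cache(maxsize=4096)
def _coeffs_exact(n: int) -> tuple[Fraction, ...]:
    """Exact polynomial coefficients a_j = (-1)^j C(n,j)^2 / C(2n-1,j)."""
    return tuple(
        Fraction((-1) ** j * math.comb(n, j) ** 2, math.comb(2 * n - 1, j))
        for j in range(n + 1)
    )


@lru_cache(maxsize=4096)
def _coeffs_float(n: int) -> tuple[float, ...] | None:
    """Float coefficients, or ``None`` when they overflow double range
    (possible for n of several hundred; the exact path still works there)."""
    try:
        return tuple(float(a) for a in _coeffs_exact(n))
    except OverflowError:
        return None


@lru_cache(maxsize=200_000)
def _lambda_exact_cached(n: int, x: Fraction) -> Fraction:
    a = _coeffs_exact(n)
    s0 = Fraction(0)
    s1 = Fraction(0)
    for j in range(n, -1, -1):
        s0 = s0 * x + a[j]
        s1 = s1 * x + (n - j) * a[j]
    if s1 == 0:
        raise DomainError(f"Lambda_{n} has a pole at x = {float(x)}")
    return n * x - 1 + Fraction(n) * s0 / s1


def _lambda_float(n: int, x: float) -> float | None:
    """Ascending-power float evaluation; ``None`` when cancellation is unsafe."""
    a = _coeffs_float(n)
    if a is None:
        return None
    s0 = 0.0
    s1 = 0.0
    mx0 = 0.0
    mx1 = 0.0
    t = 1.0
    for j in range(n + 1):
        term = a[j] * t
        s0 += term
        mx0 = max(mx0, abs(term))
        w = (n - j) * term
        s1 += w
        mx1 = max(mx1, abs(w))
        t *= x
    if s1 == 0.0 or mx1 > _CANCEL_LIMIT * abs(s1) or mx0 > _CANCEL_LIMIT * (abs(s0) + 1e-300):
        return None
    return n * x - 1.0 + n * s0 / s1


def _check_lambda_args(n: int, x: float) -> None:
    if not isinstance(n, (int,)) or isinstance(n, bool):
        raise DomainError(f"mode index n must be an integer, got {n!r}")
    if n < 0:
        raise DomainError(f"mode index n must be >= 0, got {n}")
    if not 0.0 <= x <= 1.0:
        raise RegimeError(
            f"Lambda_n argument x = 2*alpha/r0 must lie in [0, 1] "
            f"(low-activity regime, boundary included); got x = {x}"
        )


def lambda_mode(n: int, x: float, exact: bool | None = None) -> float:
    """Evaluate ``Lambda_n(x)`` for integer ``n >= 0`` and ``x in [0, 1]``.

    The alternating binomial sums lose precision for large ``n`` with ``x``
    near 1; by default the float path is used and automatically replaced by
    exact rational arithmetic when its estimated cancellation exceeds ~1e-10
    relative.  ``exact=True`` forces the rational path, ``exact=False`` forces
    the float path (raising on detected cancellation).
    """
    _check_lambda_args(n, x)
    if n == 0:
        # Neutral by convention, consistent with Lambda_n(0) = 0; the n = 0
        # (area) mode is rejected by sigma() anyway.
        return 0.0
    if x == 0.0:
        return 0.0
    if exact is not True:
        value = _lambda_float(n, x)
        if value is not None:
            return value
        if exact is False:
            raise ConvergenceWarningError(n, x)
    return float(_lambda_exact_cached(n, Fraction(x)))


class ConvergenceWarningError(DomainError):
    """Float evaluation of Lambda was requested but is numerically unsafe."""

    def __init__(self, n: int, x: float):
        super().__init__(
            f"float evaluation of Lambda_{n}({x}) suffers catastrophic "
            f"cancellation; use the exact path"
        )


def lambda_mode_exact(n: int, x: Fraction | int) -> Fraction:
    """Exact rational ``Lambda_n(x)`` for rational ``x`` (oracle-grade path)."""
    xq = Fraction(x)
    _check_lambda_args(n, float(xq))
    if n == 0:
        return Fraction(0)
    return _lambda_exact_cached(n, xq)


def lambda2_closed_form(x: float) -> float:
    """Closed form ``Lambda_2(x) = x(3x-4)/(2x-3)``; pole at ``x = 3/2``."""
    if x == 1.5:
        raise DomainError("Lambda_2 closed form has a pole at x = 3/2")
    return x * (3.0 * x - 4.0) / (2.0 * x - 3.0)


@dataclass(frozen=True)
class DispersionResult:
    """Growth rate of one interfacial mode with its regime diagnosis."""

    n: int
    sigma: float
    regime: str  # "low" or "high"
    valid: bool  # True iff the low-activity formula applies (alpha < r0/2)


def regime_check(alpha: float, r0: float) -> str:
    """Classify activity regime: ``"low"`` iff ``alpha < r0/2``.

    The boundary ``alpha = r0/2`` is classified high (the derivation of the
    dispersion relation assumes the strict inequality)."""
    if alpha < 0:
        raise DomainError(f"alpha must be >= 0, got {alpha}")
    if not r0 > 0:
        raise DomainError(f"r0 must be > 0, got {r0}")
    return "low" if alpha < r0 / 2.0 else "high"


def _sigma_value(n: int, r0: float, alpha: float, phi: float) -> float:
    x = 2.0 * alpha / r0
    lam = lambda_mode(n, x)
    numerator = (phi - 1.0) * (n - 1.0) - n * (n * n - 1.0) / r0**3 + lam
    denominator = 2.0 * (phi + 1.0 + lam - n * x)
    return numerator / denominator


def sigma(
    n: int,
    r0: float,
    alpha: float,
    phi: float,
    allow_invalid: bool = False,
) -> DispersionResult:
    """Growth rate ``sigma_n(r0)`` of interfacial mode ``n`` (exponential-growth units).

    Raises :class:`RegimeError` for high-activity input (``alpha >= r0/2``)
    unless ``allow_invalid`` is set, in which case a flagged result is
    returned (``sigma`` is NaN when the formula cannot be evaluated at all,
    i.e. for ``2*alpha/r0 > 1``).
    """
    if isinstance(n, bool) or not isinstance(n, int):
        raise DomainError(f"mode index n must be an integer, got {n!r}")
    if n < 1:
        raise DomainError(
            "mode index n must be >= 1 (the n = 0 area mode conflicts with the "
            "imposed growth and is outside the analysis)"
        )
    if not phi > 0:
        raise DomainError(f"phi must be > 0, got {phi}")
    regime = regime_check(alpha, r0)
    if regime == "high":
        if not allow_invalid:
            raise RegimeError(
                f"alpha = {alpha} >= r0/2 = {r0 / 2}: high-activity regime, "
                f"the interface-localized analysis does not apply "
                f"(pass allow_invalid=True for a flagged result)"
            )
        x = 2.0 * alpha / r0
        value = _sigma_value(n, r0, alpha, phi) if x <= 1.0 else math.nan
        return DispersionResult(n=n, sigma=value, regime=regime, valid=False)
    return DispersionResult(
        n=n, sigma=_sigma_value(n, r0, alpha, phi), regime=regime, valid=True
    )


def paterson_term(n: float, r0: float, phi: float) -> float:
    """Paterson's radial viscous-fingering growth rate, with the source
    strength set to the droplet's total growth ``Q = pi r0^2``.

    Accepts real ``n`` (the passive-limit rate is polynomial in ``n``)."""
    return 0.5 * (
        n * (phi - 1.0) / (phi + 1.0) - 1.0 - n * (n * n - 1.0) / (r0**3 * (phi + 1.0))
    )


def sigma_passive(n: float, r0: float, phi: float) -> float:
    """Passive limit ``alpha -> 0`` of the dispersion relation.

    Decomposes as Paterson's radial-geometry result plus the growth
    correction ``1/(phi+1)`` stemming from the invading fluid growing inside
    the fingers."""
    if not r0 > 0:
        raise DomainError(f"r0 must be > 0, got {r0}")
    if not phi > 0:
        raise DomainError(f"phi must be > 0, got {phi}")
    return paterson_term(n, r0, phi) + 1.0 / (phi + 1.0)


@dataclass(frozen=True)
class BaseFlowField:
    """Unperturbed axisymmetric flow at radius ``rho`` (dimensionless units).

    ``pressure`` is anchored to the interfacial pressure ``p_interface``;
    the azimuthal velocity vanishes identically."""

    region: str  # "droplet" or "exterior"
    rho: float
    v_rho: float
    v_theta: float
    pressure: float


def base_flow(
    rho: float,
    r0: float,
    alpha: float,
    phi: float,
    p_interface: float = 0.0,
) -> BaseFlowField:
    """Unperturbed base flow of the circular droplet (exponential-growth units).

    Inside (``rho <= r0``): ``v_rho = rho/2`` and
    ``p = alpha (rho - r0) - (rho^2 - r0^2)/4 + p_interface``.
    Outside: ``v_rho = r0^2/(2 rho)`` and
    ``p = -(phi r0^2 / 2) ln(rho/r0) - 1/(2 r0) + p_interface``
    (the ``1/(2 r0)`` is the dimensionless Laplace jump; the dimensionless
    surface tension in these units is 1/2).
    """
    if not rho > 0:
        raise DomainError(f"rho must be > 0, got {rho}")
    if not r0 > 0:
        raise DomainError(f"r0 must be > 0, got {r0}")
    if rho <= r0:
        return BaseFlowField(
            region="droplet",
            rho=rho,
            v_rho=rho / 2.0,
            v_theta=0.0,
            pressure=alpha * (rho - r0) - (rho**2 - r0**2) / 4.0 + p_interface,
        )
    return BaseFlowField(
        region="exterior",
        rho=rho,
        v_rho=r0**2 / (2.0 * rho),
        v_theta=0.0,
        pressure=-(phi * r0**2 / 2.0) * math.log(rho / r0)
        - 1.0 / (2.0 * r0)
        + p_interface,
    )


def pressure_condition(alpha: float, phi: float, r0: float) -> bool:
    """Necessary condition for fingering when surface tension is negligible:
    the interfacial pressure gradient is lower in the invading fluid, i.e.
    ``phi + 2*alpha/r0 > 1``."""
    if not r0 > 0:
        raise DomainError(f"r0 must be > 0, got {r0}")
    return phi + 2.0 * alpha / r0 > 1.0
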