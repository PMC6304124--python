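"""Critical radius for the onset of fingering.

Surface tension stabilizes small droplets; mode ``n = 2`` is the first to turn
unstable as the droplet grows.  The critical radius ``r_c(alpha, phi)`` is the
smallest radius satisfying ``sigma_2(r_c) = 0`` with a positive slope
``d sigma_2 / d r0 > 0``.  Increasing activity lowers ``r_c``; for ``phi < 1``
fingering requires a minimum activity (the more viscous invader is otherwise
stabilizing).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dispersion import _sigma_value, regime_check
from .errors import ConvergenceError, DomainError

__all__ = ["OnsetResult", "critical_radius", "min_activity_for_onset"]

logger = logging.getLogger(__name__)

#: Lower end of the radius bracket search (dimensionless).
_R_FLOOR = 1e-2
#: Relative offset keeping the search strictly inside the low-activity regime.
_VALIDITY_MARGIN = 1e-6


@dataclass(frozen=True)
class OnsetResult:
    """Outcome of the critical-radius search.

    ``r_c`` is ``None`` when mode 2 is never destabilized below the search
    cap.  ``regime_valid`` is False when the root violates (or sits at) the
    low-activity condition ``alpha < r_c/2``, i.e. the onset prediction lies
    outside the theory's domain of validity.
    """

    r_c: float | None
    exists: bool
    regime_valid: bool


def _search_floor(alpha: float) -> float:
    return max(_R_FLOOR, 2.0 * alpha * (1.0 + _VALIDITY_MARGIN))


def _first_upward_root(
    f, lo: float, hi: float, n_scan: int, xtol: float
) -> tuple[float | None, bool]:
    """Smallest root of ``f`` with positive slope on [lo, hi].

    Scans a geometric grid for a - -> + sign change (which automatically has
    non-negative slope) and polishes it with Brent's method.  Returns
    ``(root, at_floor)``; ``at_floor`` is True when f > 0 already at ``lo``.
    """
    grid = np.geomspace(lo, hi, n_scan)
    values = np.array([f(r) for r in grid])
    if values[0] > 0.0:
        return lo, True
    crossings = np.nonzero((values[:-1] <= 0.0) & (values[1:] > 0.0))[0]
    for i in crossings:
        try:
            root = brentq(f, grid[i], grid[i + 1], xtol=xtol)
        except ValueError as exc:  # bracket degenerated; genuine solver failure
            raise ConvergenceError(
                f"root bracketing failed on [{grid[i]}, {grid[i + 1]}]"
            ) from exc
        # keep only genuinely upward crossings (ignore tangencies)
        h = max(1e-7 * root, 1e-9)
        if f(root + h) - f(root - h) > 0.0:
            return root, False
    return None, False


def critical_radius(
    alpha: float,
    phi: float,
    r_max: float = 1e6,
    xtol: float = 1e-9,
) -> OnsetResult:
    """Critical radius ``r_c(alpha, phi)`` for the onset of fingering.

    Searches ``sigma_2(r0) = 0`` with positive slope on a geometric bracket
    from ``max(0.01, 2*alpha*(1+1e-6))`` (the low-activity validity floor) up
    to ``r_max``.  A droplet already unstable at the validity floor is
    reported with ``exists=True`` and ``regime_valid=False`` rather than
    silently dropped.
    """
    if alpha < 0:
        raise DomainError(f"alpha must be >= 0, got {alpha}")
    if not phi > 0:
        raise DomainError(f"phi must be > 0, got {phi}")
    lo = _search_floor(alpha)
    if lo >= r_max:
        raise DomainError(f"search floor {lo} exceeds r_max {r_max}")

    def f(r: float) -> float:
        return _sigma_value(2, r, alpha, phi)

    root, at_floor = _first_upward_root(f, lo, r_max, n_scan=400, xtol=xtol)
    if root is None:
        return OnsetResult(r_c=None, exists=False, regime_valid=False)
    valid = (not at_floor) and regime_check(alpha, root) == "low"
    scales_note = root * 27e-6  # metres for mid-range Table-1 parameters (l ~ 27 um)
    logger.info(
        "critical radius r_c = %.6g (dimensionless); ~%.3g m for l ~ 27 um",
        root,
        scales_note,
    )
    return OnsetResult(r_c=root, exists=True, regime_valid=valid)


def min_activity_for_onset(
    phi: float,
    alpha_cap: float = 50.0,
    tol: float = 1e-6,
) -> float | None:
    """Smallest activity for which a regime-valid onset radius exists, ``phi < 1``.

    For ``phi < 1`` the passive droplet is unconditionally stable; fingering
    requires the activity to exceed a threshold (the endpoint of the
    ``phi < 1`` onset curve).  Bisection on the existence predicate; returns
    ``None`` (with a warning) when no valid onset is found below ``alpha_cap``.
    """
    if not 0.0 < phi < 1.0:
        raise DomainError(f"min_activity_for_onset requires 0 < phi < 1, got {phi}")

    def onset_exists(alpha: float) -> bool:
        result = critical_radius(alpha, phi)
        return result.exists and result.regime_valid

    if onset_exists(0.0):
        return 0.0
    # The regime-valid existence region is a window in alpha: below it mode 2
    # never destabilizes, far above it the onset radius falls below the
    # low-activity validity floor.  Scan for any point inside the window,
    # then bisect its lower edge.
    lo = 0.0
    hi = None
    for alpha in np.geomspace(1e-3, alpha_cap, 80):
        if onset_exists(float(alpha)):
            hi = float(alpha)
            break
        lo = float(alpha)
    if hi is None:
        warnings.warn(
            f"no regime-valid onset below alpha = {alpha_cap} for phi = {phi}",
            stacklevel=2,
        )
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if onset_exists(mid):
            hi = mid
        else:
            lo = mid
    return hi
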