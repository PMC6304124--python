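"""Synthesis of perturbed droplet contours.

Each destabilized mode contributes a cosine perturbation whose amplitude is
the common initial amplitude (0.2 in units of the capillary length, about
2 um for mid-range tissue parameters) multiplied by its aggregated gain
``zeta_n(r0)``, with a random phase drawn once per mode:

    r(theta) = r0 + sum_n 0.2 * zeta_n(r0) * cos(n theta + phase_n).

This is the linear superposition only - no mode coupling, tip splitting or
finger competition.  Shapes whose perturbation exceeds 30% of the radius are
emitted with a "beyond linear validity" warning rather than refused.
"""
from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, RegimeError
from .modes import (
    EXPONENTIAL,
    KineticsSpec,
    _asymptotic_estimate,
    destabilization_radius,
    log_amplitude_gain,
)

__all__ = ["DropletShape", "synthesize_shape", "kinetics_matching"]


@dataclass(frozen=True)
class DropletShape:
    """Sampled contour ``r(theta)`` of a perturbed droplet.

    ``modes`` lists ``(n, amplitude, phase)`` triples; angles are measured
    counter-clockwise from the positive x axis."""

    r0: float
    modes: tuple[tuple[int, float, float], ...]
    theta: np.ndarray = field(repr=False)
    radius: np.ndarray = field(repr=False)
    seed: int = 0

    def save_csv(self, path: str | Path) -> None:
        """Write ``(theta_rad, r)`` rows with full (round-trippable) precision."""
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(["theta_rad", "r"])
            for t, r in zip(self.theta, self.radius):
                writer.writerow([format(t, ".17g"), format(r, ".17g")])

    @staticmethod
    def load_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return data[:, 0], data[:, 1]


def synthesize_shape(
    r0_final: float,
    alpha: float,
    phi: float,
    kinetics: KineticsSpec = EXPONENTIAL,
    initial_amplitude: float = 0.2,
    seed: int = 0,
    n_theta: int = 2048,
    n_max: int | None = None,
) -> DropletShape:
    """Superpose all modes destabilized by radius ``r0_final``.

    Phases are drawn uniformly on [0, 2 pi), one per included mode in
    ascending ``n``, from ``numpy.random.default_rng(seed)`` - so equal seeds
    give identical contours and different seeds differ only in phases.
    The whole growth history must lie in the low-activity regime.
    """
    if not r0_final > 0:
        raise DomainError(f"r0_final must be > 0, got {r0_final}")
    if n_theta < 4:
        raise DomainError(f"n_theta must be >= 4, got {n_theta}")
    kinetics.check_activity(alpha)
    if kinetics.kind == "exponential" and alpha >= r0_final / 2.0:
        raise RegimeError(
            f"high-activity regime over the radius interval "
            f"[{r0_final}, {2 * alpha}]: the droplet history up to r0 = "
            f"{r0_final} is not described by the low-activity analysis"
        )

    if n_max is None:
        estimate = _asymptotic_estimate(r0_final, alpha, phi, kinetics)
        n_max = max(64, math.ceil(3.0 * estimate)) if estimate else 64

    included: list[tuple[int, float, float]] = []
    rng = np.random.default_rng(seed)
    misses = 0
    for n in range(2, n_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R_n = destabilization_radius(n, alpha, phi, kinetics)
        if R_n is None or R_n > r0_final:
            misses += 1
            if misses >= 3:  # R_n grows with n; three misses in a row ends the scan
                break
            continue
        misses = 0
        gain = math.exp(log_amplitude_gain(n, r0_final, alpha, phi, kinetics, R_n=R_n))
        phase = rng.uniform(0.0, 2.0 * math.pi)
        included.append((n, initial_amplitude * gain, phase))

    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    radius = np.full_like(theta, float(r0_final))
    for n, amplitude, phase in included:
        radius = radius + amplitude * np.cos(n * theta + phase)

    if included:
        deviation = float(np.max(np.abs(radius - r0_final))) / r0_final
        if deviation > 0.3:
            warnings.warn(
                f"perturbation amplitude reaches {deviation:.0%} of the radius: "
                f"beyond linear validity",
                stacklevel=2,
            )
        if np.any(radius <= 0.0):
            warnings.warn(
                "contour radius is non-positive somewhere: linear superposition "
                "is not meaningful at this amplitude",
                stacklevel=2,
            )
    return DropletShape(
        r0=float(r0_final),
        modes=tuple(included),
        theta=theta,
        radius=radius,
        seed=seed,
    )


def kinetics_matching(
    beta: float, nu: float, gamma: float, k: float, rtol: float = 1e-9
) -> bool:
    """True iff the exponential and linear capillary lengths coincide:
    ``(2 gamma/(beta k))^(1/3) = (gamma/(beta nu))^(1/2)``, equivalently
    ``4 beta nu^3 = gamma k^2``.  Used to compare droplet morphologies across
    the two growth kinetics at equal characteristic scales."""
    for name, value in (("beta", beta), ("nu", nu), ("gamma", gamma), ("k", k)):
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")
    lhs = 4.0 * beta * nu**3
    rhs = gamma * k**2
    return abs(lhs - rhs) <= rtol * rhs
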