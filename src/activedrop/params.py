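"""Dimensional tissue parameters, characteristic scales and nondimensionalization.

The droplet model involves four mechanical parameters of the active tissue
(growth rate ``k``, substrate friction ``beta``, active traction ``alpha``,
surface tension ``gamma``) plus the friction ``beta_prime`` of the passive
surrounding tissue.  All analytic results are expressed in dimensionless
variables built from a characteristic capillary length at which growth (or
interface advance) balances surface tension:

* exponential growth (constant ``k``):  ``l = (2*gamma/(beta*k))**(1/3)``,
  time unit ``1/k``, velocity ``l*k``, pressure ``beta*l**2*k``, and the
  reference activity ``alpha* = beta*l*k``;
* linear radius growth (constant interface speed ``nu``):
  ``l = (gamma/(beta*nu))**(1/2)``, time unit ``l/nu``, velocity ``nu``,
  pressure ``beta*nu*l`` and reference activity ``alpha* = beta*nu`` (so the
  dimensionless interface speed is 1).

The dimensionless coordinates of every result in this package are the triple
``(alpha, phi, r0)`` with ``alpha = alpha_dim/alpha*``, ``phi = beta'/beta``
and ``r0 = r0_dim/l``.
"""
from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import DomainError

__all__ = [
    "TissueParameters",
    "CharacteristicScales",
    "DimensionlessParams",
    "DEFAULT_PARAMETERS",
    "characteristic_scales",
    "nondimensionalize",
    "dimensionalize",
    "load_config",
]

_KINETICS = ("exponential", "linear")


def _check_kinetics(kinetics: str) -> str:
    if kinetics not in _KINETICS:
        raise DomainError(f"kinetics must be one of {_KINETICS}, got {kinetics!r}")
    return kinetics


@dataclass(frozen=True)
class TissueParameters:
    """Dimensional mechanical parameters of the tissue pair.

    Attributes
    ----------
    k : float
        Net growth rate of the active droplet [1/s].
    beta : float
        Friction of the droplet against the substrate [Pa s m^-2].
    beta_prime : float
        Friction of the surrounding passive tissue [Pa s m^-2].
    alpha : float
        Magnitude of the active traction (volumic propulsion force) [Pa m^-1].
    gamma : float
        Effective interfacial tension between the two tissues [Pa m].
    """

    k: float = 1e-4
    beta: float = 1e15
    beta_prime: float = 1e15
    alpha: float = 0.0
    gamma: float = 1e-3

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise DomainError(f"growth rate k must be > 0, got {self.k}")
        if not self.beta > 0:
            raise DomainError(f"friction beta must be > 0, got {self.beta}")
        if not self.beta_prime > 0:
            raise DomainError(f"friction beta_prime must be > 0, got {self.beta_prime}")
        if self.alpha < 0:
            raise DomainError(f"active traction alpha must be >= 0, got {self.alpha}")
        if not self.gamma > 0:
            raise DomainError(f"surface tension gamma must be > 0, got {self.gamma}")

    @property
    def phi(self) -> float:
        """Viscosity (friction) ratio of displaced to invading tissue."""
        return self.beta_prime / self.beta


#: Low end of each estimated physical range; used by the CLI when no config is given.
DEFAULT_PARAMETERS = TissueParameters()


@dataclass(frozen=True)
class CharacteristicScales:
    """Characteristic scales of the chosen growth kinetics.

    ``length`` [m], ``time`` [s], ``activity`` [Pa m^-1], ``pressure`` [Pa],
    ``velocity`` [m/s].
    """

    length: float
    time: float
    activity: float
    pressure: float
    velocity: float
    kinetics: str = "exponential"

    def __post_init__(self) -> None:
        for name in ("length", "time", "activity", "pressure", "velocity"):
            if not getattr(self, name) > 0:
                raise DomainError(f"characteristic {name} must be positive")


@dataclass(frozen=True)
class DimensionlessParams:
    """The dimensionless coordinates (alpha, phi, r0) of the analytic results."""

    alpha: float
    phi: float
    r0: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise DomainError(f"dimensionless alpha must be >= 0, got {self.alpha}")
        if not self.phi > 0:
            raise DomainError(f"phi must be > 0, got {self.phi}")
        if not self.r0 > 0:
            raise DomainError(f"dimensionless r0 must be > 0, got {self.r0}")


def characteristic_scales(
    params: TissueParameters,
    kinetics: str = "exponential",
    nu: float | None = None,
) -> CharacteristicScales:
    """Build the characteristic scales for the given growth kinetics.

    Parameters
    ----------
    params : TissueParameters
    kinetics : {"exponential", "linear"}
    nu : float, optional
        Constant interface speed [m/s]; required iff ``kinetics == "linear"``.
    """
    _check_kinetics(kinetics)
    if kinetics == "exponential":
        ell = (2.0 * params.gamma / (params.beta * params.k)) ** (1.0 / 3.0)
        return CharacteristicScales(
            length=ell,
            time=1.0 / params.k,
            activity=params.beta * ell * params.k,
            pressure=params.beta * ell**2 * params.k,
            velocity=ell * params.k,
            kinetics=kinetics,
        )
    if nu is None:
        raise DomainError("linear kinetics requires the interface speed nu")
    if not nu > 0:
        raise DomainError(f"interface speed nu must be > 0, got {nu}")
    ell = math.sqrt(params.gamma / (params.beta * nu))
    return CharacteristicScales(
        length=ell,
        time=ell / nu,
        activity=params.beta * nu,
        pressure=params.beta * nu * ell,
        velocity=nu,
        kinetics=kinetics,
    )


def nondimensionalize(
    params: TissueParameters,
    r0_m: float,
    kinetics: str = "exponential",
    nu: float | None = None,
) -> DimensionlessParams:
    """Map dimensional parameters and a dimensional radius to (alpha, phi, r0)."""
    if not r0_m > 0:
        raise DomainError(f"radius must be > 0, got {r0_m}")
    scales = characteristic_scales(params, kinetics, nu)
    return DimensionlessParams(
        alpha=params.alpha / scales.activity,
        phi=params.beta_prime / params.beta,
        r0=r0_m / scales.length,
    )


def dimensionalize(
    dimless: DimensionlessParams,
    reference: TissueParameters,
    kinetics: str = "exponential",
    nu: float | None = None,
) -> tuple[TissueParameters, float]:
    """Inverse of :func:`nondimensionalize`.

    ``reference`` supplies the scales (k, beta, gamma and, for linear kinetics,
    nu); its ``alpha`` and ``beta_prime`` entries are replaced by the
    dimensional counterparts of ``dimless``.  Returns the reconstructed
    parameters and the dimensional radius in metres.
    """
    scales = characteristic_scales(reference, kinetics, nu)
    params = replace(
        reference,
        alpha=dimless.alpha * scales.activity,
        beta_prime=dimless.phi * reference.beta,
    )
    return params, dimless.r0 * scales.length


def load_config(path: str | Path) -> dict:
    """Read a flat TOML config with keys among
    ``k, beta, beta_prime, alpha, gamma, kinetics, nu``.

    Returns a dict with a ``TissueParameters`` under ``"params"`` plus the
    ``"kinetics"`` and ``"nu"`` entries (defaulting to exponential / None).
    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    raw = tomllib.loads(Path(path).read_text())
    known = {"k", "beta", "beta_prime", "alpha", "gamma", "kinetics", "nu"}
    unknown = set(raw) - known
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    kinetics = _check_kinetics(raw.pop("kinetics", "exponential"))
    nu = raw.pop("nu", None)
    defaults = {
        "k": DEFAULT_PARAMETERS.k,
        "beta": DEFAULT_PARAMETERS.beta,
        "beta_prime": DEFAULT_PARAMETERS.beta_prime,
        "alpha": DEFAULT_PARAMETERS.alpha,
        "gamma": DEFAULT_PARAMETERS.gamma,
    }
    defaults.update({key: float(value) for key, value in raw.items()})
    return {
        "params": TissueParameters(**defaults),
        "kinetics": kinetics,
        "nu": None if nu is None else float(nu),
    }
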