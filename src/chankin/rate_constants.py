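"""Decomposition of association/dissociation rate constants into microscopic
(intrinsic) and diffusional parts.

A macroscopic (observed) association rate constant ``a`` is the series
combination of the intrinsic rate ``k_a`` and the rate due to diffusion
``k_D`` (approximately ``4*pi*D*R`` for a reaction radius ``R``)::

    1/a = 1/k_a + 1/k_D

The *degree of diffusion control* ``gamma = k_a / k_D`` measures how
diffusion-limited the reaction is: ``gamma >> 1`` means ``a ~ k_D``
(diffusion limited), ``gamma << 1`` means ``a ~ k_a`` (reaction limited).
The corresponding macroscopic dissociation constant is ``d = k_d/(1+gamma)``.

Units are fixed throughout the kinetics modules: concentrations in nM,
time in s, so association constants are nM^-1 s^-1 and first-order
constants s^-1.  ``gamma = 0`` encodes the purely reaction-limited case
(``k_D = inf``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RateValidationError",
    "RateDecomposition",
    "macroscopic_from_micro",
    "micro_from_macroscopic",
    "michaelis_constant",
]


class RateValidationError(ValueError):
    """Raised when a rate constant or gamma is out of its physical range."""


@dataclass(frozen=True)
class RateDecomposition:
    """Full micro/diffusional/macroscopic decomposition of one binding step.

    Attributes
    ----------
    k_a : float
        Intrinsic (microscopic) association rate constant, nM^-1 s^-1.
    k_d : float
        Intrinsic dissociation rate constant, s^-1.
    k_D : float
        Rate due to diffusion, nM^-1 s^-1; ``math.inf`` when gamma = 0.
    gamma : float
        Degree of diffusion control, ``k_a / k_D`` (dimensionless).
    a : float
        Macroscopic association rate constant ``k_a/(1+gamma)``, nM^-1 s^-1.
    d : float
        Macroscopic dissociation rate constant ``k_d/(1+gamma)``, s^-1.
    """

    k_a: float
    k_d: float
    k_D: float
    gamma: float
    a: float
    d: float


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or math.isnan(value):
            raise RateValidationError(f"{name} must be strictly positive, got {value!r}")


def _check_gamma(gamma: float) -> None:
    if gamma < 0 or math.isnan(gamma):
        raise RateValidationError(f"gamma must be >= 0, got {gamma!r}")


def macroscopic_from_micro(k_a: float, k_d: float, gamma: float) -> RateDecomposition:
    """Macroscopic rate constants from intrinsic ones at a given gamma.

    Parameters
    ----------
    k_a, k_d : float
        Intrinsic association (nM^-1 s^-1) and dissociation (s^-1) constants.
    gamma : float
        Degree of diffusion control; ``0`` means no diffusion limitation.

    Returns
    -------
    RateDecomposition
        With ``a = k_a/(1+gamma)``, ``d = k_d/(1+gamma)`` and
        ``k_D = k_a/gamma`` (``inf`` at gamma = 0).
    """
    _check_positive(k_a=k_a, k_d=k_d)
    _check_gamma(gamma)
    k_D = math.inf if gamma == 0 else k_a / gamma
    return RateDecomposition(
        k_a=k_a,
        k_d=k_d,
        k_D=k_D,
        gamma=gamma,
        a=k_a / (1.0 + gamma),
        d=k_d / (1.0 + gamma),
    )


def micro_from_macroscopic(a: float, d: float, gamma: float) -> RateDecomposition:
    """Intrinsic rate constants from macroscopic ones: ``k_a = a(1+gamma)``,
    ``k_d = d(1+gamma)``.  Exact algebraic inverse of
    :func:`macroscopic_from_micro`.
    """
    _check_positive(a=a, d=d)
    _check_gamma(gamma)
    k_a = a * (1.0 + gamma)
    k_d = d * (1.0 + gamma)
    k_D = math.inf if gamma == 0 else k_a / gamma
    return RateDecomposition(k_a=k_a, k_d=k_d, k_D=k_D, gamma=gamma, a=a, d=d)


def michaelis_constant(a: float, d: float, k_cat: float) -> float:
    """Michaelis constant ``K_M = (k_cat + d)/a`` of a binding/turnover cycle, in nM."""
    if not (a > 0):
        raise RateValidationError(f"a must be strictly positive, got {a!r}")
    return (k_cat + d) / a
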