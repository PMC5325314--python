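"""Closed-form and semi-numeric steady states of the channeled and
non-channeled cascades.

The channeled velocity follows from the steady flux through the four
occupancy states of the complex (free, SE12, IE12, E12I)::

    v_ch = k1 k_ch k2 [S] [E12] / (k_ch k2 K_M^ch + [S](k_ch k2 + k1 k2 + k1 k_ch))

with K_M^ch = (k1 + d_ch)/a_ch.  The non-channeled velocity has two regimes
separated by the substrate threshold

    [S]_threshold = K_M^(1) k2 [E2] / (k1 [E1] - k2 [E2]),

below which the intermediate pool is finite and v_non follows the
Michaelis-Menten form of the first reaction; above it the first enzyme
outruns the second, [I] grows without bound and v_non saturates at k2 [E2].

All concentrations in nM, times in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .cascade import CascadeParams

__all__ = [
    "SteadyStateResult",
    "VMax",
    "v_channeled",
    "v_nonchanneled",
    "s_threshold",
    "v_max",
    "low_s_velocities",
    "iss_mixed",
    "solve_degradation",
    "solve_reversible",
]


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state production velocity and intermediate pool.

    ``regime`` is "first-limiting" (finite pool, Michaelis-Menten branch),
    "second-limiting"/"diverging" (saturated second enzyme, I_ss = inf), or
    "channeled" for the complex-only system (always bounded).
    """

    v: float          # nM/s
    I_ss: float       # nM, may be +inf
    regime: str


class VMax(NamedTuple):
    """Saturation (S -> inf) velocities of the three model variants, nM/s."""

    v_non_max: float
    v_ch_max: float
    v_ch_max_two_site: float


def v_channeled(params: CascadeParams, S: float) -> float:
    """Steady production velocity of the fully channeled system at substrate S.

    Occupancy-series form whose S -> inf limit is the harmonic-sum velocity
    ``(1/k1 + 1/k_ch + 1/k2)^-1 [E12]`` and whose S -> 0 slope is
    ``k1 [E12]/K_M^ch``.
    """
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S!r}")
    if params.E12_tot <= 0:
        raise ValueError("v_channeled requires E12_tot > 0")
    k1, kc, k2 = params.k1_ch, params.k_ch, params.k2_ch
    num = k1 * kc * k2 * S * params.E12_tot
    den = kc * k2 * params.KM_ch + S * (kc * k2 + k1 * k2 + k1 * kc)
    return num / den


def s_threshold(params: CascadeParams) -> float:
    """Substrate level above which the intermediate pool of the non-channeled
    system grows without bound; +inf when k1*E1 <= k2*E2 (the second enzyme
    can always keep up)."""
    excess = params.k1 * params.E1_tot - params.k2 * params.E2_tot
    if excess <= 0:
        return math.inf
    return params.KM1 * params.k2 * params.E2_tot / excess


def v_nonchanneled(params: CascadeParams, S: float) -> SteadyStateResult:
    """Steady state of the non-channeled cascade, branch chosen by the threshold.

    Below the threshold: v = k1 [E1] S/(K_M^(1) + S) with the finite pool
    I_ss = K_M^(2) v/(k2 [E2] - v).  At or above it: v = k2 [E2], I_ss = +inf.
    """
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S!r}")
    if params.E1_tot <= 0 or params.E2_tot <= 0:
        raise ValueError("v_nonchanneled requires E1_tot > 0 and E2_tot > 0")
    thr = s_threshold(params)
    if S >= thr:
        return SteadyStateResult(v=params.k2 * params.E2_tot, I_ss=math.inf,
                                 regime="diverging")
    v = params.k1 * params.E1_tot * S / (params.KM1 + S)
    cap = params.k2 * params.E2_tot
    I_ss = params.KM2 * v / (cap - v) if v < cap else math.inf
    return SteadyStateResult(v=v, I_ss=I_ss, regime="first-limiting")


def v_max(params: CascadeParams) -> VMax:
    """Saturation velocities: k1[E1]; harmonic(k1, k_ch, k2)[E12]; and the
    two-occupancy complex limit k2 k_ch [E12]/(k2 + k_ch)."""
    k1, kc, k2 = params.k1_ch, params.k_ch, params.k2_ch
    v_non = params.k1 * params.E1_tot
    v_ch = params.E12_tot / (1.0 / k1 + 1.0 / kc + 1.0 / k2)
    v_ts = k2 * kc * params.E12_tot / (k2 + kc)
    return VMax(v_non, v_ch, v_ts)


def low_s_velocities(params: CascadeParams, S: float) -> tuple[float, float]:
    """First-order (S << K_M) velocities (v_non, v_ch) = (k1 E1 S/K_M^(1),
    k1 E12 S/K_M^ch).  The caller is responsible for S being small."""
    return (params.k1 * params.E1_tot * S / params.KM1,
            params.k1_ch * params.E12_tot * S / params.KM_ch)


def iss_mixed(params: CascadeParams, S: float, x_ch: float) -> float:
    """Steady intermediate pool of the mixed system at degree of channeling x_ch.

    ``x_ch = [E12]/min([E1],[E2])`` converts the totals in ``params`` (which
    are interpreted here as the *overall* enzyme totals, complexed or not)
    into single-enzyme totals E_i0 = E_i - E12.  Returns +inf when S is at or
    above the threshold of the single-enzyme subsystem.
    """
    if not (0 <= x_ch < 1):
        raise ValueError(f"x_ch must lie in [0, 1), got {x_ch!r}")
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S!r}")
    E12 = x_ch * min(params.E1_tot, params.E2_tot)
    E10 = params.E1_tot - E12
    E20 = params.E2_tot - E12
    num = params.KM2 * params.k1 * E10 * S
    den = params.k2 * E20 * (params.KM1 + S) - params.k1 * E10 * S
    if den <= 0:
        return math.inf
    return num / den


def solve_degradation(params: CascadeParams, S: float,
                      k_deg: float) -> tuple[float, float]:
    """Steady state of the non-channeled cascade with intermediate degradation.

    Solves  v0 - k2 [E2] I/(K_M^(2) + I) - k_deg I = 0  (a quadratic in I)
    for the unique non-negative root, where v0 is the degradation-free
    velocity of the first reaction.  Returns ``(I_ss, v_non)`` with
    v_non = v0 - k_deg I_ss.
    """
    if k_deg < 0:
        raise ValueError(f"k_deg must be >= 0, got {k_deg!r}")
    v0 = params.k1 * params.E1_tot * S / (params.KM1 + S)
    cap = params.k2 * params.E2_tot
    KM2 = params.KM2
    if k_deg == 0:
        if v0 >= cap:
            return math.inf, cap
        return KM2 * v0 / (cap - v0), v0
    # k_deg I^2 + (cap + k_deg KM2 - v0) I - v0 KM2 = 0
    b = cap + k_deg * KM2 - v0
    c = -v0 * KM2
    disc = b * b - 4.0 * k_deg * c
    if disc < 0:  # pragma: no cover - impossible for valid inputs (c <= 0)
        raise RuntimeError("no non-negative root of the degradation quadratic")
    # stable evaluation of the positive root
    if b >= 0:
        I_ss = 2.0 * (-c) / (b + math.sqrt(disc))
    else:
        I_ss = (-b + math.sqrt(disc)) / (2.0 * k_deg)
    return I_ss, v0 - k_deg * I_ss


def solve_reversible(params: CascadeParams, S: float,
                     kbar1: float) -> tuple[float, float]:
    """Steady state of the non-channeled cascade with a reversible first step
    (E1 + I -> SE1 at rate kbar1).

    Simultaneously solves the consumption balance v = k2 [E2] I/(K_M^(2)+I)
    and the net first-reaction flux

        v = [E1] (k1 S/K_M^(1) - d1 I/Kbar_M^(1)) / (1 + S/K_M^(1) + I/Kbar_M^(1))

    with Kbar_M^(1) = (k1 + d1)/kbar1, by bracketed root finding on I >= 0.
    Returns ``(I_ss, v_non)``.
    """
    if kbar1 < 0:
        raise ValueError(f"kbar1 must be >= 0, got {kbar1!r}")
    KM1, KM2 = params.KM1, params.KM2
    cap = params.k2 * params.E2_tot
    if kbar1 == 0:
        res = v_nonchanneled(params, S)
        return res.I_ss, res.v
    KbM1 = (params.k1 + params.d1) / kbar1

    def v_forward(I: float) -> float:
        return (params.E1_tot * (params.k1 * S / KM1 - params.d1 * I / KbM1)
                / (1.0 + S / KM1 + I / KbM1))

    def v_consume(I: float) -> float:
        return cap * I / (KM2 + I)

    def f(I: float) -> float:
        return v_forward(I) - v_consume(I)

    if f(0.0) <= 0:  # no substrate or no first enzyme: trivial steady state
        return 0.0, 0.0
    # v_forward turns negative at I = k1 S KbM1/(d1 KM1) (or decays to 0 when
    # d1 = 0), while v_consume grows: expand the bracket geometrically.
    hi = max(KM2, S, 1.0)
    for _ in range(200):
        if f(hi) < 0:
            break
        hi *= 4.0
    else:
        raise RuntimeError(
            f"could not bracket the reversible steady state; residual at I={hi:g}: {f(hi):.3g}")
    I_ss = brentq(f, 0.0, hi, xtol=1e-30, rtol=1e-15)
    return I_ss, v_consume(I_ss)
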