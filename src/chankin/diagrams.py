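"""Channeling phase diagrams and parameter sweeps.

Demarcation curves separate the (S, gamma_ch) regions in which channeling
accelerates vs. decelerates the cascade: in steady state the curve is the
gamma_ch at which the channeled and non-channeled velocities are equal; in a
batch reactor it is the gamma_ch at which both systems need equal time to
convert a fraction alpha of the initial substrate.  Also provided: the
ceiling substrate level S_max above which channeling cannot accelerate the
reaction for any gamma_ch, the pool-size curve I_ss(x_ch), and the
degradation/reversibility sweeps.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cascade import CascadeParams, time_to_product_fraction
from .scenarios import Scenario, build_params, scenario_to_config
from . import steady_state as ss

__all__ = [
    "DemarcationCurve",
    "steady_demarcation",
    "s_max",
    "batch_demarcation",
    "pool_size_curve",
    "degradation_sweep",
    "reversibility_sweep",
]

logger = logging.getLogger(__name__)

#: no-crossing searches run in log10(gamma_ch) over this window
LOG_GAMMA_WINDOW = (-6.0, 6.0)

#: flag values used in DemarcationCurve.flags
OK, NO_CROSSING_SLOWER, NO_CROSSING_FASTER, DIVERGING = (
    "ok", "no-crossing-slower", "no-crossing-faster", "diverging")


@dataclass
class DemarcationCurve:
    """A computed curve plus the fixed parameters that produced it.

    ``flags[i]`` qualifies point i: "ok" for a located value,
    "no-crossing-slower"/"-faster" when the channeled system is slower/faster
    over the whole gamma window (ordinate is NaN there), "diverging" for an
    unbounded pool.
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    flags: list[str]
    abscissa_name: str
    ordinate_name: str
    metadata: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # named secondary columns

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "abscissa": self.abscissa,
            "ordinate": self.ordinate,
            "flag": self.flags,
        })
        for name, col in self.extra.items():
            df[name] = col
        return df

    def write_csv(self, path: str | Path) -> None:
        """CSV of the curve plus a JSON sidecar with the fixed parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {"abscissa": self.abscissa_name, "ordinate": self.ordinate_name,
                **self.metadata}
        sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")


def _channeled_params(base: Scenario, gamma_ch: float) -> CascadeParams:
    """Rebuild the scenario's parameters with a different gamma_ch (shared
    microscopic constants)."""
    p = base.params
    k_a = p.a1 * (1.0 + base.gamma_1)
    k_d = p.d1 * (1.0 + base.gamma_1)
    k_a2 = p.a2 * (1.0 + base.gamma_2)
    k_d2 = p.d2 * (1.0 + base.gamma_2)
    return build_params(k_a, k_d, p.k1, p.k2, p.k_ch,
                        base.gamma_1, base.gamma_2, gamma_ch,
                        E1_tot=p.E1_tot, E2_tot=p.E2_tot, E12_tot=p.E12_tot,
                        k_a2=k_a2, k_d2=k_d2)


def steady_demarcation(base: Scenario, S_grid: np.ndarray) -> DemarcationCurve:
    """gamma_ch*(S): the degree of diffusion control of the complex at which
    the channeled and non-channeled steady velocities are equal.

    The channeled and non-channeled binding steps share microscopic
    constants; v_ch is strictly decreasing in gamma_ch, so the root (when it
    exists inside the log-gamma window) is unique.
    """
    S_grid = np.asarray(S_grid, dtype=float)
    lo, hi = LOG_GAMMA_WINDOW
    ords, flags = [], []
    for S in S_grid:
        v_non = ss.v_nonchanneled(base.params, S).v

        def g(lg: float) -> float:
            return ss.v_channeled(_channeled_params(base, 10.0 ** lg), S) - v_non

        g_lo, g_hi = g(lo), g(hi)
        if g_lo < 0:  # channeled slower even at the most favourable gamma_ch
            ords.append(math.nan)
            flags.append(NO_CROSSING_SLOWER)
        elif g_hi > 0:
            ords.append(math.nan)
            flags.append(NO_CROSSING_FASTER)
        else:
            lg = brentq(g, lo, hi, xtol=1e-13, rtol=1e-14)
            ords.append(10.0 ** lg)
            flags.append(OK)
    return DemarcationCurve(S_grid, np.array(ords), flags, "S_nM", "gamma_ch",
                            metadata=scenario_to_config(base))


def s_max(base: Scenario, gamma_1: float | None = None,
          s_hi: float | None = None) -> float:
    """Substrate level above which channeling decelerates the reaction for
    every gamma_ch, i.e. where even the gamma_ch -> 0 (purely
    reaction-limited) channeled velocity equals the non-channeled one.

    Returns 0 when gamma_1 = 0 (with equal microscopic constants the
    channeled system is then slower at every S > 0).
    """
    if gamma_1 is None:
        gamma_1 = base.gamma_1
    if gamma_1 == 0:
        return 0.0
    sc = Scenario(name=base.name, params=base.params, feed=base.feed, S0=base.S0,
                  gamma_1=gamma_1, gamma_2=base.gamma_2, gamma_ch=base.gamma_ch)
    if gamma_1 != base.gamma_1:
        # rebuild the first-step macroscopic constants at the requested gamma_1
        p = base.params
        k_a = p.a1 * (1.0 + base.gamma_1)
        k_d = p.d1 * (1.0 + base.gamma_1)
        params = build_params(k_a, k_d, p.k1, p.k2, p.k_ch, gamma_1, base.gamma_2,
                              base.gamma_ch,
                              E1_tot=p.E1_tot, E2_tot=p.E2_tot, E12_tot=p.E12_tot,
                              k_a2=p.a2 * (1.0 + base.gamma_2),
                              k_d2=p.d2 * (1.0 + base.gamma_2))
        sc = Scenario(name=base.name, params=params, feed=base.feed, S0=base.S0,
                      gamma_1=gamma_1, gamma_2=base.gamma_2, gamma_ch=base.gamma_ch)
    ch0 = _channeled_params(sc, 0.0)

    def h(S: float) -> float:
        return ss.v_channeled(ch0, S) - ss.v_nonchanneled(sc.params, S).v

    thr = ss.s_threshold(sc.params)
    if s_hi is None:
        s_hi = min(thr * (1.0 - 1e-9), 1e12) if math.isfinite(thr) else 1e12
    s_lo = 1e-9
    if h(s_lo) <= 0:
        return 0.0
    if h(s_hi) > 0:  # pragma: no cover - favourable channeling up to the threshold
        return s_hi
    return brentq(h, s_lo, s_hi, xtol=1e-12, rtol=1e-14)


def batch_demarcation(base: Scenario, alpha: float, S0_grid: np.ndarray,
                      rtol: float = 1e-10, xtol: float = 1e-4) -> DemarcationCurve:
    """(gamma_ch/gamma_1)*(S0): equal-time demarcation of the batch reactor.

    For each initial substrate dose the channeled-only system (totals E12)
    is compared against the non-channeled-only system (totals E1, E2); the
    ordinate is the gamma_ch/gamma_1 ratio at which the times to reach
    [P] = alpha*S0 coincide.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    S0_grid = np.asarray(S0_grid, dtype=float)
    p = base.params
    non_params = p.with_totals(E12_tot=0.0)
    lo, hi = LOG_GAMMA_WINDOW
    ords, flags = [], []
    for S0 in S0_grid:
        t_non = time_to_product_fraction(non_params, S0, alpha, rtol=rtol)

        def g(lg: float) -> float:
            ch = _channeled_params(base, 10.0 ** lg).with_totals(E1_tot=0.0, E2_tot=0.0)
            return time_to_product_fraction(ch, S0, alpha, rtol=rtol) - t_non

        if g(lo) > 0:  # channeled slower even at the smallest gamma_ch
            ords.append(math.nan)
            flags.append(NO_CROSSING_SLOWER)
        elif g(hi) < 0:
            ords.append(math.nan)
            flags.append(NO_CROSSING_FASTER)
        else:
            lg = brentq(g, lo, hi, xtol=xtol)
            ords.append(10.0 ** lg / base.gamma_1)
            flags.append(OK)
    meta = scenario_to_config(base)
    meta["alpha"] = alpha
    return DemarcationCurve(S0_grid, np.array(ords), flags, "S0_nM",
                            "gamma_ch_over_gamma_1", metadata=meta)


def pool_size_curve(base: Scenario, x_ch_grid: np.ndarray,
                    S: float | None = None) -> DemarcationCurve:
    """Steady intermediate pool I_ss along the degree of channeling x_ch."""
    x_ch_grid = np.asarray(x_ch_grid, dtype=float)
    if S is None:
        S = base.S0
    vals, flags = [], []
    for x in x_ch_grid:
        I = ss.iss_mixed(base.params, S, x)
        if math.isinf(I):
            vals.append(math.nan)
            flags.append(DIVERGING)
        else:
            vals.append(I)
            flags.append(OK)
    meta = scenario_to_config(base)
    meta["S"] = S
    return DemarcationCurve(x_ch_grid, np.array(vals), flags, "x_ch", "I_ss_nM",
                            metadata=meta)


def _sweep(base: Scenario, S: float | None, grid: np.ndarray, solver,
           abscissa_name: str) -> DemarcationCurve:
    grid = np.asarray(grid, dtype=float)
    if S is None:
        S = base.S0
    v_ch = ss.v_channeled(base.params, S)
    pairs = [solver(base.params, S, g) for g in grid]
    v_non = np.array([p[1] for p in pairs])
    I_ss = np.array([p[0] for p in pairs])
    flags = [OK] * len(grid)
    # locate the crossing v_non = v_ch, when bracketed by the grid
    crossing = math.nan
    d = v_non - v_ch
    idx = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if idx.size:
        i = int(idx[0])
        crossing = brentq(lambda g: solver(base.params, S, g)[1] - v_ch,
                          grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)
    meta = scenario_to_config(base)
    meta.update({"S": S, "v_ch": v_ch, "crossing": crossing})
    return DemarcationCurve(grid, v_non, flags, abscissa_name, "v_non_nM_per_s",
                            metadata=meta, extra={"I_ss": I_ss,
                                                  "v_ch": np.full(len(grid), v_ch)})


def degradation_sweep(base: Scenario, k_deg_grid: np.ndarray,
                      S: float | None = None) -> DemarcationCurve:
    """v_non(k_deg) (with the channeled velocity, unaffected by degradation,
    as a reference column); the v_non = v_ch crossing is stored in metadata."""
    return _sweep(base, S, k_deg_grid, ss.solve_degradation, "k_deg_per_s")


def reversibility_sweep(base: Scenario, kbar1_grid: np.ndarray,
                        S: float | None = None) -> DemarcationCurve:
    """v_non(kbar_1) for the reversible first step; abscissa in nM^-1 s^-1
    (divide by a1 for the dimensionless degree of reversibility)."""
    return _sweep(base, S, kbar1_grid, ss.solve_reversible, "kbar1_nM-1s-1")
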