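"""Mass-action ODE model of a two-enzyme cascade with an optional channeling
complex.

The mixed system contains free enzymes E1 and E2 (Michaelis-Menten cascade
S -> I -> P) plus enzyme-enzyme complexes E12 that channel the intermediate
directly between their two active sites:

    S + E1  <->(a1, d1)  SE1  ->(k1)  E1 + I
    I + E2  <->(a2, d2)  IE2  ->(k2)  E2 + P
    S + E12 <->(a_ch, d_ch) SE12 ->(k1_ch) IE12 ->(k_ch) E12I ->(k2_ch) E12 + P

Free-enzyme concentrations are eliminated through the conservation laws
(E1_free = E1_tot - SE1, etc.), so enzyme conservation holds exactly at
every time point.  Optional extensions: first-order degradation of the
intermediate (k_deg), a reversible first step E1 + I -> SE1 (kbar1), and a
two-occupancy complex (S can bind E12I, giving the extra species SE12I).

Units: nM for concentrations, s for time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .rate_constants import RateValidationError

__all__ = [
    "CascadeParams",
    "FeedMode",
    "Trajectory",
    "SteadyStateOutcome",
    "IntegrationError",
    "InconclusiveSteadyState",
    "build_rhs",
    "build_jacobian",
    "initial_state",
    "species_names",
    "integrate",
    "steady_state_numeric",
    "time_to_product_fraction",
]

logger = logging.getLogger(__name__)

#: State-vector layout of the base model (two-occupancy adds "SE12I" before "P").
_BASE_SPECIES = ("S", "SE1", "I", "IE2", "SE12", "IE12", "E12I", "P")


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid state, if any."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


class InconclusiveSteadyState(RuntimeError):
    """Neither convergence nor divergence detected within the time budget."""


@dataclass(frozen=True)
class CascadeParams:
    """Macroscopic rate constants and total concentrations of the mixed system.

    ``k1_ch``/``k2_ch`` default to ``k1``/``k2`` (the fairness assumption that
    complex formation does not alter intrinsic turnover).  ``two_site=True``
    enables the two-occupancy complex extension with binding constants
    ``a_ts``/``d_ts`` and turnover ``k_ts`` (defaulting to a_ch, d_ch, k2_ch).
    """

    a1: float  # nM^-1 s^-1
    d1: float  # s^-1
    k1: float  # s^-1
    a2: float
    d2: float
    k2: float
    a_ch: float
    d_ch: float
    k_ch: float  # channeling (intramolecular transfer) rate, s^-1
    E1_tot: float = 0.0  # nM, single (non-complexed) enzyme 1
    E2_tot: float = 0.0
    E12_tot: float = 0.0
    k1_ch: float | None = None
    k2_ch: float | None = None
    k_deg: float = 0.0  # s^-1, degradation of free intermediate
    kbar1: float = 0.0  # nM^-1 s^-1, reverse rate of E1 + I -> SE1
    two_site: bool = False
    a_ts: float | None = None
    d_ts: float | None = None
    k_ts: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "k1_ch", self.k1 if self.k1_ch is None else self.k1_ch)
        object.__setattr__(self, "k2_ch", self.k2 if self.k2_ch is None else self.k2_ch)
        object.__setattr__(self, "a_ts", self.a_ch if self.a_ts is None else self.a_ts)
        object.__setattr__(self, "d_ts", self.d_ch if self.d_ts is None else self.d_ts)
        object.__setattr__(self, "k_ts", self.k2_ch if self.k_ts is None else self.k_ts)
        for name in ("a1", "d1", "k1", "a2", "d2", "k2", "a_ch", "d_ch", "k_ch",
                     "k1_ch", "k2_ch", "k_deg", "kbar1", "a_ts", "d_ts", "k_ts",
                     "E1_tot", "E2_tot", "E12_tot"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise RateValidationError(f"{name} must be >= 0, got {v!r}")

    def with_totals(self, E1_tot=None, E2_tot=None, E12_tot=None) -> "CascadeParams":
        kw = {}
        if E1_tot is not None:
            kw["E1_tot"] = E1_tot
        if E2_tot is not None:
            kw["E2_tot"] = E2_tot
        if E12_tot is not None:
            kw["E12_tot"] = E12_tot
        return replace(self, **kw)

    @property
    def KM1(self) -> float:
        """Michaelis constant of the first free-enzyme reaction, nM."""
        return (self.k1 + self.d1) / self.a1

    @property
    def KM2(self) -> float:
        """Michaelis constant of the second free-enzyme reaction, nM."""
        return (self.k2 + self.d2) / self.a2

    @property
    def KM_ch(self) -> float:
        """Michaelis constant of the channeled complex, (k1_ch + d_ch)/a_ch, nM."""
        return (self.k1_ch + self.d_ch) / self.a_ch


@dataclass(frozen=True)
class FeedMode:
    """Substrate feeding condition.

    mode:
        "batch"              - closed system, v_S = 0;
        "constant_substrate" - [S] clamped at S_fixed (cell-like conditions);
        "constant_feed"      - constant supply velocity v_S (fed-batch).
    """

    mode: str = "batch"
    v_S: float = 0.0  # nM/s, used by constant_feed
    S_fixed: float | None = None  # nM, used by constant_substrate

    def __post_init__(self):
        if self.mode not in ("batch", "constant_substrate", "constant_feed"):
            raise ValueError(f"unknown feed mode {self.mode!r}")
        if self.mode == "batch" and self.v_S != 0.0:
            raise ValueError("batch mode requires v_S = 0")
        if self.mode == "constant_substrate" and self.S_fixed is None:
            raise ValueError("constant_substrate mode requires S_fixed")


def species_names(params: CascadeParams) -> tuple[str, ...]:
    """Names of the integrated state-vector components, in order."""
    if params.two_site:
        return _BASE_SPECIES[:-1] + ("SE12I", "P")
    return _BASE_SPECIES


def initial_state(params: CascadeParams, S0: float, I0: float = 0.0,
                  P0: float = 0.0) -> np.ndarray:
    """Default initial condition: all enzymes free and unbound at t = 0."""
    n = 9 if params.two_site else 8
    y0 = np.zeros(n)
    y0[0] = S0
    y0[2] = I0
    y0[-1] = P0
    return y0


def build_rhs(params: CascadeParams,
              feed: FeedMode) -> Callable[[float, np.ndarray], np.ndarray]:
    """Mass-action right-hand side d[y]/dt for the mixed system.

    The state vector is ``(S, SE1, I, IE2, SE12, IE12, E12I[, SE12I], P)``;
    free enzymes are recovered from the conservation laws.  In
    ``constant_substrate`` mode d[S]/dt is clamped to zero (the implied
    supply velocity can be recovered post hoc from the substrate-consuming
    terms).
    """
    p = params
    clamp_S = feed.mode == "constant_substrate"
    v_S = feed.v_S if feed.mode == "constant_feed" else 0.0
    two_site = p.two_site

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if two_site:
            S, SE1, I, IE2, SE12, IE12, E12I, SE12I, _P = y
        else:
            S, SE1, I, IE2, SE12, IE12, E12I = y[:7]
            SE12I = 0.0
        E1 = p.E1_tot - SE1
        E2 = p.E2_tot - IE2
        E12 = p.E12_tot - SE12 - IE12 - E12I - SE12I

        bind1 = p.a1 * E1 * S
        bind2 = p.a2 * E2 * I
        bindc = p.a_ch * E12 * S
        rebind = p.kbar1 * E1 * I

        dS = -bind1 + p.d1 * SE1 - bindc + p.d_ch * SE12 + v_S
        dSE1 = bind1 - (p.d1 + p.k1) * SE1 + rebind
        dI = p.k1 * SE1 - bind2 + p.d2 * IE2 - p.k_deg * I - rebind
        dIE2 = bind2 - (p.d2 + p.k2) * IE2
        dSE12 = bindc - (p.d_ch + p.k1_ch) * SE12
        dIE12 = p.k1_ch * SE12 - p.k_ch * IE12
        dE12I = p.k_ch * IE12 - p.k2_ch * E12I
        dP = p.k2 * IE2 + p.k2_ch * E12I

        if two_site:
            bind_ts = p.a_ts * E12I * S
            dS += -bind_ts + p.d_ts * SE12I
            dE12I += -bind_ts + p.d_ts * SE12I
            dSE12I = bind_ts - (p.d_ts + p.k_ts) * SE12I
            dIE12 += p.k_ts * SE12I
            dP += p.k_ts * SE12I
            if clamp_S:
                dS = 0.0
            return np.array([dS, dSE1, dI, dIE2, dSE12, dIE12, dE12I, dSE12I, dP])

        if clamp_S:
            dS = 0.0
        return np.array([dS, dSE1, dI, dIE2, dSE12, dIE12, dE12I, dP])

    return rhs


def build_jacobian(params: CascadeParams,
                   feed: FeedMode) -> Callable[[float, np.ndarray], np.ndarray]:
    """Analytic Jacobian of :func:`build_rhs` (mass action is bilinear, so the
    entries are affine in the state)."""
    p = params
    clamp_S = feed.mode == "constant_substrate"
    two_site = p.two_site
    n = 9 if two_site else 8

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        if two_site:
            S, SE1, I, IE2, SE12, IE12, E12I, SE12I, _P = y
        else:
            S, SE1, I, IE2, SE12, IE12, E12I = y[:7]
            SE12I = 0.0
        E1 = p.E1_tot - SE1
        E2 = p.E2_tot - IE2
        E12 = p.E12_tot - SE12 - IE12 - E12I - SE12I
        J = np.zeros((n, n))
        iP = n - 1
        # dS row
        J[0, 0] = -p.a1 * E1 - p.a_ch * E12
        J[0, 1] = p.a1 * S + p.d1
        J[0, 4] = p.a_ch * S + p.d_ch
        J[0, 5] = p.a_ch * S
        J[0, 6] = p.a_ch * S
        # dSE1 row
        J[1, 0] = p.a1 * E1
        J[1, 1] = -p.a1 * S - (p.d1 + p.k1) - p.kbar1 * I
        J[1, 2] = p.kbar1 * E1
        # dI row
        J[2, 1] = p.k1 + p.kbar1 * I
        J[2, 2] = -p.a2 * E2 - p.k_deg - p.kbar1 * E1
        J[2, 3] = p.a2 * I + p.d2
        # dIE2 row
        J[3, 2] = p.a2 * E2
        J[3, 3] = -p.a2 * I - (p.d2 + p.k2)
        # dSE12 row
        J[4, 0] = p.a_ch * E12
        J[4, 4] = -p.a_ch * S - (p.d_ch + p.k1_ch)
        J[4, 5] = -p.a_ch * S
        J[4, 6] = -p.a_ch * S
        # dIE12 row
        J[5, 4] = p.k1_ch
        J[5, 5] = -p.k_ch
        # dE12I row
        J[6, 5] = p.k_ch
        J[6, 6] = -p.k2_ch
        # dP row
        J[iP, 3] = p.k2
        J[iP, 6] = p.k2_ch
        if two_site:
            J[0, 7] = p.a_ch * S  # SE12I occupies the complex too
            J[4, 7] = -p.a_ch * S
            J[0, 0] += -p.a_ts * E12I
            J[0, 6] += -p.a_ts * S
            J[0, 7] += p.d_ts
            J[5, 7] = p.k_ts
            J[6, 0] = -p.a_ts * E12I
            J[6, 6] += -p.a_ts * S
            J[6, 7] = p.d_ts
            J[7, 0] = p.a_ts * E12I
            J[7, 6] = p.a_ts * S
            J[7, 7] = -(p.d_ts + p.k_ts)
            J[iP, 7] = p.k_ts
        if clamp_S:
            J[0, :] = 0.0
        return J

    return jac


def production_velocity(params: CascadeParams, y: np.ndarray) -> np.ndarray:
    """Product formation velocity v_P = dP/dt evaluated on state(s) ``y``.

    ``y`` may be a single state vector or an array of shape (n_times, n_species).
    """
    y = np.asarray(y)
    IE2 = y[..., 3]
    E12I = y[..., 6]
    v = params.k2 * IE2 + params.k2_ch * E12I
    if params.two_site:
        v = v + params.k_ts * y[..., 7]
    return v


@dataclass
class Trajectory:
    """Integrated time course of the mixed system.

    ``states[i]`` is the state vector at ``t[i]``; derived free-enzyme and
    v_P columns are available through :meth:`to_frame`.
    """

    t: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    params: CascadeParams
    feed: FeedMode

    @property
    def species(self) -> tuple[str, ...]:
        return species_names(self.params)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    @property
    def v_P(self) -> np.ndarray:
        """Production velocity nM/s at every stored time point."""
        return production_velocity(self.params, self.states)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with free-enzyme and vP columns."""
        p = self.params
        df = pd.DataFrame({"t": self.t})
        cols = dict(zip(self.species, self.states.T))
        df["S"] = cols["S"]
        df["I"] = cols["I"]
        df["P"] = cols["P"]
        df["E1"] = p.E1_tot - cols["SE1"]
        df["SE1"] = cols["SE1"]
        df["E2"] = p.E2_tot - cols["IE2"]
        df["IE2"] = cols["IE2"]
        E12_free = p.E12_tot - cols["SE12"] - cols["IE12"] - cols["E12I"]
        if p.two_site:
            E12_free = E12_free - cols["SE12I"]
        df["E12"] = E12_free
        df["SE12"] = cols["SE12"]
        df["IE12"] = cols["IE12"]
        df["E12I"] = cols["E12I"]
        if p.two_site:
            df["SE12I"] = cols["SE12I"]
        df["vP"] = self.v_P
        return df

    def conservation_errors(self) -> dict[str, float]:
        """Max relative violation of the enzyme/metabolite conservation laws."""
        p = self.params
        cols = dict(zip(self.species, self.states.T))
        out = {}
        # free enzymes are eliminated via the conservation laws, so the law is
        # violated only if a bound pool leaves [0, total]
        if p.E1_tot > 0:
            SE1 = cols["SE1"]
            out["E1"] = float(max(np.max(SE1 - p.E1_tot), np.max(-SE1), 0.0) / p.E1_tot)
        if p.E2_tot > 0:
            IE2 = cols["IE2"]
            out["E2"] = float(max(np.max(IE2 - p.E2_tot), np.max(-IE2), 0.0) / p.E2_tot)
        if p.E12_tot > 0:
            bound = cols["SE12"] + cols["IE12"] + cols["E12I"]
            if p.two_site:
                bound = bound + cols["SE12I"]
            out["E12"] = float(max(np.max(bound - p.E12_tot), -np.min(bound), 0.0) / p.E12_tot)
        if self.feed.mode == "batch" and p.k_deg == 0 and p.kbar1 >= 0:
            total = (cols["S"] + cols["I"] + cols["P"] + cols["SE1"] + cols["IE2"]
                     + cols["SE12"] + cols["IE12"] + cols["E12I"])
            if p.two_site:
                total = total + 2.0 * cols["SE12I"]  # SE12I carries two metabolites
            ref = total[0]
            if ref > 0:
                out["metabolite"] = float(np.max(np.abs(total - ref)) / ref)
        return out


def integrate(params: CascadeParams, feed: FeedMode, state0: np.ndarray | Sequence[float],
              t_end: float, rtol: float = 1e-10, atol: float = 1e-12,
              t_eval: np.ndarray | None = None, events=None,
              method: str = "BDF", t_start: float = 0.0) -> Trajectory:
    """Integrate the cascade ODEs with a stiff-capable implicit solver and
    the analytic mass-action Jacobian.

    Raises
    ------
    IntegrationError
        If the solver fails; the exception carries the last valid state.
    """
    y0 = np.asarray(state0, dtype=float)
    if feed.mode == "constant_substrate" and feed.S_fixed is not None:
        y0 = y0.copy()
        y0[0] = feed.S_fixed
    rhs = build_rhs(params, feed)
    jac = build_jacobian(params, feed) if method in ("BDF", "Radau", "LSODA") else None
    sol = solve_ivp(rhs, (t_start, t_end), y0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, events=events, dense_output=False, jac=jac)
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else None
        raise IntegrationError(f"ODE integration failed: {sol.message}", last_state=last)
    traj = Trajectory(t=sol.t, states=sol.y.T, params=params, feed=feed)
    traj._sol = sol  # keep events accessible to callers
    return traj


@dataclass
class SteadyStateOutcome:
    """Result of the numerical steady-state search.

    ``verdict`` is "converged" (a true steady state, RHS norm below tolerance)
    or "diverging" (the intermediate -- or substrate under constant feed --
    grows without bound).
    """

    verdict: str
    state: np.ndarray
    t: float
    rhs_norm: float
    v_P: float


def steady_state_numeric(params: CascadeParams, feed: FeedMode,
                         state0: np.ndarray | None = None,
                         ss_tol: float = 1e-10,
                         conc_tol: float = 1e-9,
                         t_max: float = 1e12,
                         rtol: float = 1e-10, atol: float = 1e-12,
                         ceiling_factor: float = 1e5) -> SteadyStateOutcome:
    """Drive the system to steady state (or detect unbounded growth).

    Integrates on a doubling time grid.  Convergence requires, per species i
    (excluding the product), either an RHS component below ``ss_tol`` (nM/s)
    or an estimated remaining concentration error ``|dy_i/dt| / |J_ii|``
    below ``conc_tol * (1 + |y_i|)`` nM -- the Jacobian diagonal supplies
    each species' own relaxation rate, which keeps the criterion meaningful
    for arbitrarily stiff parameter sets.  Divergence of the intermediate
    pool (or of the substrate under constant feed) is detected
    behaviourally, by the concentration crossing a ceiling of
    ``ceiling_factor * max(KM2, concentration scale)`` while still
    growing.

    Raises
    ------
    ValueError
        If called in batch mode (the batch system trivially runs to complete
        conversion, not to a steady state with finite substrate).
    InconclusiveSteadyState
        If neither outcome is established within ``t_max``.
    """
    if feed.mode == "batch":
        raise ValueError("steady_state_numeric requires constant_substrate or constant_feed mode")
    if state0 is None:
        S0 = feed.S_fixed if feed.mode == "constant_substrate" else 0.0
        state0 = initial_state(params, S0=S0 or 0.0)
    y = np.asarray(state0, dtype=float)
    if feed.mode == "constant_substrate":
        y = y.copy()
        y[0] = feed.S_fixed

    rhs = build_rhs(params, feed)
    scale = max(params.KM2, float(y[0]), float(y[2]), 1.0)
    ceiling = ceiling_factor * scale

    def hit_ceiling_I(t, yy):
        return yy[2] - ceiling

    hit_ceiling_I.terminal = True
    hit_ceiling_I.direction = 1

    def hit_ceiling_S(t, yy):
        return yy[0] - ceiling

    hit_ceiling_S.terminal = True
    hit_ceiling_S.direction = 1

    events = [hit_ceiling_I]
    if feed.mode == "constant_feed":
        events.append(hit_ceiling_S)

    mask = np.ones(y.size, dtype=bool)
    mask[-1] = False  # exclude d[P]/dt
    if feed.mode == "constant_substrate":
        mask[0] = False  # d[S]/dt clamped to zero anyway

    jac = build_jacobian(params, feed)

    def is_converged(t: float, yy: np.ndarray, g: np.ndarray) -> bool:
        lam = np.abs(np.diag(jac(t, yy)))
        ok = np.abs(g) <= ss_tol + conc_tol * (1.0 + np.abs(yy)) * lam
        return bool(np.all(ok[mask]))

    t_now = 0.0
    t_next = 1.0
    best_norm = math.inf
    stagnant = 0
    while t_now < t_max:
        t_next = min(t_next, t_max)
        traj = integrate(params, feed, y, t_next, rtol=rtol, atol=atol,
                         events=events, t_start=t_now)
        y = traj.final_state
        t_now = traj.t[-1]
        sol = traj._sol
        if sol.status == 1:  # a ceiling event fired
            f = rhs(t_now, y)
            if f[2] > 0 or (feed.mode == "constant_feed" and f[0] > 0):
                logger.info("diverging pool detected at t=%.3g s (concentration ceiling %.3g nM)",
                            t_now, ceiling)
                return SteadyStateOutcome("diverging", y, t_now, float(np.max(np.abs(f[mask]))),
                                          float(production_velocity(params, y)))
        f = rhs(t_now, y)
        norm = float(np.max(np.abs(f[mask])))
        if norm < ss_tol or is_converged(t_now, y, f):
            return SteadyStateOutcome("converged", y, t_now, norm,
                                      float(production_velocity(params, y)))
        if norm < best_norm / 2.0:
            best_norm = min(best_norm, norm)
            stagnant = 0
        else:
            stagnant += 1
            best_norm = min(best_norm, norm)
            # integrator error floor: norm no longer decreasing but already tiny
            if stagnant >= 3 and norm < 1e-6:
                logger.info("steady-state norm stagnated at %.3g nM/s (error floor); accepting", norm)
                return SteadyStateOutcome("converged", y, t_now, norm,
                                          float(production_velocity(params, y)))
        t_next = t_now * 2.0 if t_now > 0 else 2.0
    raise InconclusiveSteadyState(
        f"no steady state or divergence within t_max={t_max:g} s (last RHS norm {norm:.3g} nM/s)")


def time_to_product_fraction(params: CascadeParams, S0: float, alpha: float,
                             rtol: float = 1e-10, atol: float = 1e-12,
                             t_max: float = 1e12) -> float:
    """Time for the batch system to reach [P] = alpha*[S]0.

    Located by terminal event detection on the integrated trajectory; the
    time horizon is grown geometrically until the event fires.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie strictly between 0 and 1 "
                         "(batch product asymptotes to S0)")
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    if params.E1_tot <= 0 and params.E12_tot <= 0:
        raise ValueError("no catalyst: at least one enzyme total must be positive")
    target = alpha * S0
    feed = FeedMode(mode="batch")

    def hit(t, y):
        return y[-1] - target

    hit.terminal = True
    hit.direction = 1

    # crude horizon guess from the slowest first-stage velocity scale
    v_guess = max(params.k1 * params.E1_tot, params.k1_ch * params.E12_tot, 1e-12)
    t_end = max(10.0 * target / v_guess, 1.0)
    y = initial_state(params, S0=S0)
    t_start = 0.0
    while t_end <= t_max * 2:
        traj = integrate(params, feed, y, t_end, rtol=rtol, atol=atol,
                         events=hit, t_start=t_start)
        sol = traj._sol
        if sol.status == 1 and sol.t_events[0].size:
            return float(sol.t_events[0][0])
        y = traj.final_state
        t_start = traj.t[-1]
        t_end = t_start * 8.0
    raise IntegrationError(f"[P] did not reach {alpha}*S0 within t={t_max:g} s", last_state=y)
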