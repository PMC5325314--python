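"""Scenario construction: reference parameter sets, randomized ensembles, and
flat-config (TOML/JSON) serialization.

The reference microscopic constants are those of the first two reactions of
the MAPK pathway: k_a = 0.027 nM^-1 s^-1, k_d = 1.35 s^-1, turnover
k_i = 1.5 s^-1 for both enzymes, and a channeling rate k_ch = 1 s^-1.
Macroscopic constants follow from the chosen degrees of diffusion control
via :mod:`chankin.rate_constants`.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cascade import CascadeParams, FeedMode
from .rate_constants import macroscopic_from_micro
from .steady_state import s_threshold

__all__ = [
    "MAPK_KA", "MAPK_KD", "MAPK_KCAT", "MAPK_KCH",
    "Scenario", "build_params", "mapk_scenario", "random_ensemble",
    "scenario_to_config", "scenario_from_config", "load_config", "dump_config",
    "list_named_scenarios", "named_scenario",
]

#: Microscopic association rate of the reference (MAPK) parameter set, nM^-1 s^-1.
MAPK_KA = 0.027
#: Microscopic dissociation rate, s^-1.
MAPK_KD = 1.35
#: Turnover number of both enzymes, s^-1.
MAPK_KCAT = 1.5
#: Channeling (intramolecular transfer) rate, s^-1.
MAPK_KCH = 1.0


def build_params(k_a: float, k_d: float, k1: float, k2: float, k_ch: float,
                 gamma_1: float, gamma_2: float, gamma_ch: float,
                 E1_tot: float = 0.0, E2_tot: float = 0.0, E12_tot: float = 0.0,
                 k_a2: float | None = None, k_d2: float | None = None,
                 **extensions) -> CascadeParams:
    """CascadeParams from microscopic constants and per-step gammas.

    The channeled and non-channeled first steps share the same microscopic
    constants (k_a, k_d); only the degrees of diffusion control differ.  The
    second enzyme may get its own microscopic pair via ``k_a2``/``k_d2``.
    """
    r1 = macroscopic_from_micro(k_a, k_d, gamma_1)
    r2 = macroscopic_from_micro(k_a2 if k_a2 is not None else k_a,
                                k_d2 if k_d2 is not None else k_d, gamma_2)
    rc = macroscopic_from_micro(k_a, k_d, gamma_ch)
    return CascadeParams(a1=r1.a, d1=r1.d, k1=k1, a2=r2.a, d2=r2.d, k2=k2,
                         a_ch=rc.a, d_ch=rc.d, k_ch=k_ch,
                         E1_tot=E1_tot, E2_tot=E2_tot, E12_tot=E12_tot,
                         **extensions)


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation setup (parameters + feeding + initials)."""

    name: str
    params: CascadeParams
    feed: FeedMode
    S0: float = 0.0        # initial substrate, nM (batch) / clamp level otherwise
    gamma_1: float = math.nan   # provenance: gammas used to build params
    gamma_2: float = math.nan
    gamma_ch: float = math.nan
    seed: int | None = None

    def describe(self) -> dict:
        d = scenario_to_config(self)
        return d


def mapk_scenario(gamma_1: float = 1.0, gamma_2: float = 1.0, gamma_ch: float = 1.0,
                  S: float = 90.0, E1_tot: float = 50.0, E2_tot: float = 50.0,
                  E12_tot: float = 50.0, k2: float = MAPK_KCAT,
                  mode: str = "constant_substrate", v_S: float = 0.0,
                  name: str = "mapk", **extensions) -> Scenario:
    """The reference scenario built on the MAPK-derived rate constants.

    Defaults (all gammas 1, S = 90 nM, all totals 50 nM, constant substrate)
    give the base case used throughout the steady-state and pool-size
    analyses.  ``k2``/``E2_tot`` can be varied jointly (k1 E1 = k2 E2) for the
    pool-size variants.
    """
    params = build_params(MAPK_KA, MAPK_KD, MAPK_KCAT, k2, MAPK_KCH,
                          gamma_1, gamma_2, gamma_ch,
                          E1_tot=E1_tot, E2_tot=E2_tot, E12_tot=E12_tot,
                          **extensions)
    feed = FeedMode(mode=mode, v_S=v_S,
                    S_fixed=S if mode == "constant_substrate" else None)
    return Scenario(name=name, params=params, feed=feed, S0=S,
                    gamma_1=gamma_1, gamma_2=gamma_2, gamma_ch=gamma_ch)


_NAMED = {
    "fig-base": dict(),
    "fig-pool-equal": dict(k2=1.5, E2_tot=50.0),
    "fig-pool-e2-abundant": dict(k2=1.0, E2_tot=75.0),
    "fig-pool-e1-abundant": dict(k2=2.0, E2_tot=37.5),
    "fig-batch": dict(mode="batch"),
}


def list_named_scenarios() -> list[str]:
    return sorted(_NAMED)


def named_scenario(name: str) -> Scenario:
    try:
        kw = _NAMED[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: {', '.join(sorted(_NAMED))}") from None
    return mapk_scenario(name=name, **kw)


def random_ensemble(n: int, seed: int,
                    rate_range: tuple[float, float] = (1e-3, 1e1),
                    gamma_range: tuple[float, float] = (1e-1, 1e1),
                    s_range: tuple[float, float] = (1.0, 1e4),
                    totals: tuple[float, float, float] = (50.0, 50.0, 50.0),
                    require_convergent: bool = True,
                    max_tries: int = 100000) -> list[Scenario]:
    """Reproducible log-uniform ensemble of scenarios around the reference set.

    Each microscopic rate (k_a, k_d, k1, k2, k_ch) is drawn log-uniformly
    within ``rate_range`` times its reference value, gammas within
    ``gamma_range``, and the clamped substrate level within ``s_range`` nM.
    With ``require_convergent`` the draws are filtered to S < [S]_threshold
    so the non-channeled steady state exists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = rate_range
    out: list[Scenario] = []
    tries = 0
    while len(out) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"only {len(out)}/{n} draws accepted after {max_tries} tries; "
                "widen the ranges or drop require_convergent")
        tries += 1
        mult = lambda: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        g = lambda: float(np.exp(rng.uniform(*np.log(gamma_range))))
        k_a = MAPK_KA * mult()
        k_d = MAPK_KD * mult()
        k1 = MAPK_KCAT * mult()
        k2 = MAPK_KCAT * mult()
        k_ch = MAPK_KCH * mult()
        gamma_1, gamma_2, gamma_ch = g(), g(), g()
        S = float(np.exp(rng.uniform(*np.log(s_range))))
        params = build_params(k_a, k_d, k1, k2, k_ch, gamma_1, gamma_2, gamma_ch,
                              E1_tot=totals[0], E2_tot=totals[1], E12_tot=totals[2])
        if require_convergent and S >= 0.95 * s_threshold(params):
            continue
        out.append(Scenario(name=f"draw-{len(out)}", params=params,
                            feed=FeedMode("constant_substrate", S_fixed=S),
                            S0=S, gamma_1=gamma_1, gamma_2=gamma_2,
                            gamma_ch=gamma_ch, seed=seed))
    return out


# ---------------------------------------------------------------------------
# flat key-value config I/O (TOML primary, JSON accepted)

def _enc(v):
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    if isinstance(v, float) and math.isnan(v):
        return "nan"
    return v


def _dec(v):
    if v == "inf":
        return math.inf
    if v == "nan":
        return math.nan
    return v


def scenario_to_config(sc: Scenario) -> dict:
    """Flat key-value dict (units fixed: nM, s) describing the scenario."""
    p = sc.params
    cfg = {
        "name": sc.name,
        "a_1": p.a1, "d_1": p.d1, "k_1": p.k1,
        "a_2": p.a2, "d_2": p.d2, "k_2": p.k2,
        "a_ch": p.a_ch, "d_ch": p.d_ch, "k1_ch": p.k1_ch, "k_ch": p.k_ch,
        "k2_ch": p.k2_ch,
        "gamma_1": sc.gamma_1, "gamma_2": sc.gamma_2, "gamma_ch": sc.gamma_ch,
        "E1_tot": p.E1_tot, "E2_tot": p.E2_tot, "E12_tot": p.E12_tot,
        "k_deg": p.k_deg, "kbar_1": p.kbar1, "two_site": p.two_site,
        "mode": sc.feed.mode, "v_S": sc.feed.v_S, "S0": sc.S0,
    }
    if sc.feed.S_fixed is not None:
        cfg["S_fixed"] = sc.feed.S_fixed
    if sc.seed is not None:
        cfg["seed"] = sc.seed
    return {k: _enc(v) for k, v in cfg.items()}


def scenario_from_config(cfg: dict) -> Scenario:
    """Inverse of :func:`scenario_to_config`.

    Raises
    ------
    KeyError
        Naming the offending key when a required entry is missing.
    """
    cfg = {k: _dec(v) for k, v in cfg.items()}
    try:
        params = CascadeParams(
            a1=cfg["a_1"], d1=cfg["d_1"], k1=cfg["k_1"],
            a2=cfg["a_2"], d2=cfg["d_2"], k2=cfg["k_2"],
            a_ch=cfg["a_ch"], d_ch=cfg["d_ch"], k_ch=cfg["k_ch"],
            k1_ch=cfg.get("k1_ch"), k2_ch=cfg.get("k2_ch"),
            E1_tot=cfg.get("E1_tot", 0.0), E2_tot=cfg.get("E2_tot", 0.0),
            E12_tot=cfg.get("E12_tot", 0.0),
            k_deg=cfg.get("k_deg", 0.0), kbar1=cfg.get("kbar_1", 0.0),
            two_site=bool(cfg.get("two_site", False)),
        )
        mode = cfg.get("mode", "batch")
        feed = FeedMode(mode=mode, v_S=cfg.get("v_S", 0.0),
                        S_fixed=cfg.get("S_fixed") if mode == "constant_substrate" else None)
        return Scenario(name=str(cfg.get("name", "scenario")), params=params,
                        feed=feed, S0=cfg.get("S0", cfg.get("S_fixed", 0.0)),
                        gamma_1=cfg.get("gamma_1", math.nan),
                        gamma_2=cfg.get("gamma_2", math.nan),
                        gamma_ch=cfg.get("gamma_ch", math.nan),
                        seed=cfg.get("seed"))
    except KeyError as e:
        raise KeyError(f"config is missing required key {e.args[0]!r}") from None


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, float):
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        if math.isnan(v):
            return "nan"
        return repr(v)
    return repr(v)


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write a flat config as TOML (``.toml``) or JSON (anything else)."""
    path = Path(path)
    if path.suffix == ".toml":
        lines = [f"{k} = {_toml_scalar(v)}" for k, v in cfg.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(cfg, indent=2) + "\n")


def load_config(path: str | Path) -> dict:
    """Read a flat TOML or JSON config."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    return json.loads(path.read_text())
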