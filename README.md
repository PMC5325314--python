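# chankin

Does metabolite channeling accelerate enzyme-catalyzed cascade reactions?
`chankin` is a Python toolkit for answering that question quantitatively in
the simplest setting where it can be posed cleanly: a two-enzyme
Michaelis–Menten cascade

    S + E1 <=> SE1 -> E1 + I,      I + E2 <=> IE2 -> E2 + P,

compared against its channeled counterpart, in which an enzyme–enzyme
complex E12 hands the intermediate directly from one active site to the
other:

    S + E12 <=> SE12 -> IE12 -> E12I -> E12 + P,

with a channeling rate k_ch for the internal transfer step. The package is
aimed at modellers in enzymology, synthetic biology and biocatalysis who
want reproducible numbers — not just the folklore that "channeling speeds
things up".

## What it computes

* **Mass-action ODE kinetics** (`chankin.cascade`) of the mixed system
  (free enzymes + complexes) under batch, constant-substrate, or
  constant-feed conditions, with optional intermediate degradation
  (k_deg), a reversible first step, and a two-occupancy complex. Stiff
  integration (BDF with the analytic Jacobian), steady-state search with a
  behavioural divergence verdict, and event-located batch conversion
  times.
* **Closed-form steady states** (`chankin.steady_state`):

  v_ch = k1 k_ch k2 [S][E12] / (k_ch k2 K_M^ch + [S](k_ch k2 + k1 k2 + k1 k_ch)),

  the non-channeled branches v_non = k1[E1][S]/(K_M + [S]) (below the
  threshold [S]_th = K_M k2[E2]/(k1[E1] − k2[E2])) and v_non = k2[E2]
  (above it, where the intermediate pool grows without bound), the
  saturation limits (1/k1 + 1/k_ch + 1/k2)^-1 [E12] vs k1[E1], and the
  mixed-system pool size [I]_ss as a function of the degree of channeling
  x_ch = [E12]/min([E1],[E2]).
* **Rate-constant decomposition** (`chankin.rate_constants`): microscopic
  vs diffusional parts, 1/a = 1/k_a + 1/k_D, degree of diffusion control
  γ = k_a/k_D.
* **Channeling diagrams** (`chankin.diagrams`): the γ_ch(S) demarcation
  between acceleration and deceleration, the ceiling substrate level
  S_max(γ1), batch-reactor equal-time diagrams, pool-size curves, and
  degradation/reversibility sweeps.
* **Brownian-dynamics association rates** (`chankin.brownian`): icosphere
  bead-model enzymes and enzyme–enzyme complexes, Lennard-Jones (or
  purely repulsive WCA) substrate interactions, and Northrup–Allison–
  McCammon estimation of diffusion-limited rates,
  k = k_D(b) β / (1 − (1−β) k_D(b)/k_D(q)), with Brownian-bridge
  corrections for missed boundary crossings.

Units are fixed throughout: nM, s for kinetics; nm, ns, k_BT for the
bead model.

## Worked example

```python
import chankin as ck
from chankin import scenarios as sn, steady_state as ss
from chankin.cascade import FeedMode, steady_state_numeric

sc = sn.mapk_scenario()          # MAPK-derived constants, gammas = 1,
p = sc.params                    # S = 90 nM, all totals 50 nM

print(ss.v_channeled(p, 90.0))         # 14.177362893815637
print(ss.v_nonchanneled(p, 90.0).v)    # 26.88053097345133
print(ss.v_max(p))                     # VMax(v_non_max=75.0,
                                       #      v_ch_max=21.42857142857143,
                                       #      v_ch_max_two_site=30.0)

out = steady_state_numeric(p.with_totals(E1_tot=0.0, E2_tot=0.0),
                           FeedMode("constant_substrate", S_fixed=90.0))
print(out.v_P)                         # 14.177362893815623
```

At the reference conditions the channeled system produces product at
14.18 nM/s in steady state while the plain cascade manages 26.88 nM/s —
channeling *slows down* this cascade, and the saturation limits (21.4 vs
75 nM/s) show the gap only widens at high substrate. The last call
cross-checks the closed form against a long-time ODE integration; the two
agree to ~1e-9 relative. Where channeling does pay off is protection of
the intermediate: `ss.solve_degradation(p, 90.0, k_deg)` shows the
non-channeled velocity dropping below the (degradation-immune) channeled
one once k_deg exceeds ≈ 0.34 s^-1.

A command-line interface mirrors the library:

```sh
chankin scenarios emit fig-base --out params.toml
chankin simulate --config params.toml --mode batch --t-end 1e3 --out traj.csv
chankin steady   --config params.toml --s-grid 1:1000:200log --out ss.csv
chankin diagram pool --config params.toml --out pool.csv
chankin bd-rate --geometry complex --eps 0.1 --ntraj 10000 --seed 42 --out rate.json
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the numerical
choices (integration, steady-state and divergence detection, the NAM
propagator), and known limitations.
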