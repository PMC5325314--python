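# Methods

## Model

We compare a two-step Michaelis–Menten cascade with its channeled
counterpart. The non-channeled system is

    S + E1 <=>[a1,d1] SE1 ->[k1] E1 + I,
    I + E2 <=>[a2,d2] IE2 ->[k2] E2 + P,

and the channeled system replaces the free enzymes by an enzyme–enzyme
complex that hands the intermediate from the first active site to the
second without release:

    S + E12 <=>[a_ch,d_ch] SE12 ->[k1_ch] IE12 ->[k_ch] E12I ->[k2_ch] E12 + P.

k_ch is the inverse of the internal transfer time. Both systems are
assumed well mixed; all reactions and the transfer step are irreversible
(extensions below). The *fairness assumptions* baked into the default
parameter construction are that complex formation alters neither the
turnover numbers (k1_ch = k1, k2_ch = k2) nor the microscopic
association/dissociation constants — only the diffusional encounter rate
may change. To express that, every association constant is split into a
microscopic and a diffusional part, 1/a = 1/k_a + 1/k_D, with
d = k_d/(1+γ) and the degree of diffusion control γ = k_a/k_D. Channeling
can then only act through γ_ch ≠ γ1.

The base complex carries one metabolite at a time; this is what makes its
saturation velocity a harmonic sum, (1/k1 + 1/k_ch + 1/k2)^-1 [E12],
necessarily below the non-channeled k1[E1] at equal enzyme investment —
the complex processes metabolites in series while free enzymes work in
parallel. The optional two-occupancy extension (`two_site=True`) adds
S + E12I <=> SE12I -> IE12 + P with binding constants defaulting to
(a_ch, d_ch) and turnover k2_ch (all three independently overridable),
which raises the ceiling to k2 k_ch [E12]/(k2 + k_ch) but not above
k1[E1].

### Closed-form steady states

The channeled velocity follows from the steady flux around the four
occupancy states of the complex:

    v_ch = k1 k_ch k2 [S][E12] / (k_ch k2 K_M^ch + [S](k_ch k2 + k1 k2 + k1 k_ch)),

with K_M^ch = (k1_ch + d_ch)/a_ch. (We re-derived this denominator from
the occupancy cycle; it reproduces the harmonic-sum limit at S → ∞ and
the slope k1[E12]/K_M^ch at S → 0.)

The non-channeled system has two regimes separated by

    [S]_threshold = K_M^(1) k2 [E2] / (k1 [E1] − k2 [E2])

(infinite when k1[E1] ≤ k2[E2]). Below it the intermediate pool is finite,
I_ss = K_M^(2) v/(k2[E2] − v), and v = k1[E1][S]/(K_M^(1)+[S]); above it
the first enzyme outruns the second, [I] grows linearly without bound and
the production velocity saturates at k2[E2].

For the mixed system (single enzymes at E_i0 = [E_i] − [E12] plus
complexes) the pool is

    I_ss = K_M^(2) k1 E10 [S] / (k2 E20 (K_M^(1) + [S]) − k1 E10 [S]),

which is algebraically identical to the threshold-factored form when the
threshold is finite and remains valid when it is not. Under the
capacity-matched constraint k1[E1] = k2[E2] the sign of dI_ss/dx_ch is
the sign of [E1] − [E2]: channeling *raises* the pool when the first
enzyme is abundant, is neutral at [E1] = [E2], and lowers it otherwise.

### Competing-reaction extensions

Intermediate degradation adds −k_deg[I] to the pool balance; the steady
state solves v0 − k2[E2] I/(K_M^(2)+I) − k_deg I = 0, a quadratic in I
whose unique non-negative root we evaluate in closed form (stable
quadratic formula; the residual is checked to < 1e-10 nM/s in the test
suite), with v_non = v0 − k_deg I_ss. The reversible first step
(E1 + I → SE1 at rate kbar1) couples the consumption law to the net
forward flux

    v = [E1](k1 S/K_M^(1) − d1 I/K̄_M^(1)) / (1 + S/K_M^(1) + I/K̄_M^(1)),

K̄_M^(1) = (k1+d1)/kbar1; the pair is solved by bracketed Brent root
finding on I ≥ 0 (bracket grown geometrically until the sign flips,
xtol 1e-30/rtol 1e-15). A useful corollary, verified in the tests: the
ratio v_non/v_ch in the reversible case is independent of the common
enzyme scale.

## Numerical choices

* **Integration.** `scipy.integrate.solve_ivp` with BDF and the analytic
  mass-action Jacobian; default rtol 1e-10, atol 1e-12 nM. (LSODA was
  observed to stall — millions of micro-steps — on near-threshold chunks
  of this system; BDF with the exact Jacobian does not.) Free-enzyme
  coordinates are eliminated through the conservation laws, so enzyme
  totals are conserved exactly; batch metabolite conservation then holds
  to integrator accuracy (asserted ≤ 1e-8 relative).
* **Constant-substrate mode** clamps d[S]/dt = 0 (the substrate entry of
  the RHS and Jacobian row are zeroed) rather than solving for a supply
  velocity; the implied v_S(t) is available post hoc from the
  substrate-consuming terms.
* **Steady-state search** integrates on a doubling time grid (t_max
  1e12 s). Convergence requires, per species (excluding product), either
  an RHS component below 1e-10 nM/s or an estimated remaining
  concentration error |dy_i/dt|/|J_ii| below 1e-9 (1+|y_i|) nM — the
  Jacobian diagonal supplies each species' own relaxation rate, which
  keeps the criterion attainable for stiff parameter sets whose absolute
  residual floor scales with the fastest rate. A stagnation fallback
  accepts states whose residual has plateaued below 1e-6 nM/s at the
  integrator's error floor.
* **Divergence verdict.** Whether the intermediate pool diverges is
  decided behaviourally, not from the threshold formula (the ODE verdict
  serves as an independent check *of* that formula): a terminal event
  fires when [I] (or [S] under constant feed) crosses a ceiling of
  1e5 × max(K_M^(2), concentration scale) while still growing. Finite
  near-threshold pools reach only ~1e2–1e5 × K_M^(2) at the ±2%
  threshold resolution probed by the tests, so the ceiling separates the
  outcomes cleanly.
* **Batch conversion times** are located by a terminal integration event
  on [P] = α[S]0, with the horizon grown geometrically until the event
  fires.
* **Demarcation curves** bracket their roots in log10 γ_ch over [−6, 6]
  (outside this window the point is flagged no-crossing rather than
  erroring); batch-diagram bisection uses xtol 1e-4 in log γ, and every
  located point re-evaluates to |v_ch − v_non|/v_non < 1e-6 (steady) or
  equal times to 1e-3 (batch).

### A note on the short-time transient

At t → 0 both systems produce product like t^3, with ratio
v_ch/v_non → (k_ch/(a2[E2])) (a_ch/a1) ([E12]/[E1]). With the reference
constants this exceeds 1 — the much-cited short-time advantage of
channeling, caused by the non-channeled cascade having to fill its
intermediate pool first — only while γ_ch ≲ 2 γ1. For strongly
diffusion-hindered complexes (γ_ch/γ1 ≳ 3 at these constants) the
channeled system is slower at *every* time, not just in steady state;
full integrations confirm the window closes there.

## Reference parameters and the scenario generator

The reference microscopic constants are those of the first two MAPK
pathway reactions: k_a = 0.027 nM⁻¹s⁻¹, k_d = 1.35 s⁻¹, k1 = k2 =
1.5 s⁻¹, with channeling rate k_ch = 1 s⁻¹; defaults γ1 = γ2 = γ_ch = 1,
[S] = 90 nM, and all enzyme totals 50 nM. Pool-size variants adjust
(k2, [E2]) to (1, 75) and (2, 37.5) nM, preserving k1[E1] = k2[E2].

`random_ensemble` draws each microscopic rate log-uniformly within
[1e-3, 10] × its reference value, γ's within [0.1, 10], and the clamped
substrate within [1, 1e4] nM, filtering to S < 0.95 [S]_threshold so the
non-channeled steady state exists and converges in bounded time (the 5%
margin excludes arbitrarily slow near-threshold relaxations). Ensembles
are reproducible from their seed. The generator emulates parameter
*uncertainty* around one biological operating point; it does not emulate
correlated rate constants, enzyme inactivation, crowding, or spatial
effects, so agreement on the ensemble demonstrates the internal
consistency of the theory across rate scales, not fidelity to any
particular real pathway.

## Brownian-dynamics rate estimation

Enzymes are bead shells: 10·4^level + 2 beads (default level 1, 42
beads, radius 0.37 nm) at the vertices of a subdivided icosahedron
projected onto a 1.5 nm core sphere, rotated so the active-site bead sits
exactly on +z. A complex merges two shells 1.4 nm apart with the
second enzyme behind the first one's active site; beads falling inside
the other core are removed. The substrate is a single sphere of radius
0.4 nm; per bead, σ = bead radius + substrate radius and the 12-6
Lennard-Jones potential 4ε[(σ/r)¹² − (σ/r)⁶] is truncated and shifted at
a configurable cutoff (default 3σ).

For the soft-enzyme rate-vs-ε trend we use the cutoff 2^(1/6)σ (the WCA
choice: truncation at the minimum leaves a purely repulsive softened
sphere). The reason is physical: the capture surface sits 0.82 nm from
the active bead centre, where the full 12-6 potential of the active bead
and its ~6 neighbours is a net well of ≈ −2.9ε, so with an attractive
tail the association rate *rises* with ε (we verified this numerically);
a repulsion-dominated interaction is what makes the enzyme "harder" with
growing ε and the rate fall, which is the regime of interest for
diffusion-limited association of an uncharged enzyme whose van der Waals
attraction is negligible. Both variants are exposed and tested.

Rates come from the Northrup–Allison–McCammon estimator: trajectories
start uniformly on a b-sphere (5 nm) outside all interactions, and the
rate is k = k_D(b) β / (1 − (1−β) k_D(b)/k_D(q)), k_D(x) = 4πDx, where β
is the capture probability (within a 0.82 nm reaction distance of the
active-site bead centre) and the denominator corrects analytically for
returns from beyond the escape sphere q. Defaults not fixed by the
geometry: q = 25 nm (the correction makes k insensitive to q — tested at
15/25/50 nm), substrate diffusivity D = 1 nm²/ns (a small aqueous
metabolite; enzymes held fixed), dt = 2e-4 ns so the rms free step
(≈ 0.035 nm) is well under a quarter bead radius (validated, and a
half-step convergence test is in the suite). Rates are reported in
nm³/ns and in nM⁻¹s⁻¹ (1 nm³/ns = 10⁻²⁴ L × 10⁹ s⁻¹ × N_A / 10⁹ nM/M ≈
0.602 nM⁻¹s⁻¹).

The propagator is free-draining Brownian dynamics (displacement
D Δt F/k_BT plus Gaussian noise of variance 2D Δt per coordinate) with
two purely numerical accelerations: (i) in the force-free far field the
step rms grows as one quarter of the distance to the nearest of the
force region, the capture sphere and the q-sphere (floored at the
user dt); (ii) every step applies Brownian-bridge crossing corrections,
capturing (or discarding) trajectories whose continuous path would have
crossed the capture (or escape) sphere between samples with probability
exp(−2 d_before d_after / 2DΔt). The bridge correction removes the
~1% capture-miss bias a discrete propagator otherwise shows against the
Smoluchowski closed form. A drift cap of σ/2 per step guards against the
(never observed in tests; counted and reported) case of a step landing
deep inside a bead. Estimates are bit-reproducible for a fixed seed:
each trajectory re-seeds the generator from seed + trajectory index.

Monte-Carlo uncertainty: β carries its binomial standard error,
propagated to k by the delta method; the complex/single rate ratio is run
with a shared seed (common random numbers) and quotes the conservative
independent-error combination.

Validation anchors (all recomputed in the test suite): on a bare
absorbing sphere the estimator reproduces 4πDR and the concentric-sphere
first-passage probability (1/b − 1/q)/(1/R − 1/q) within 3 Monte-Carlo σ,
with the error halving from 10⁴ to 4×10⁴ trajectories; on the bead
geometries the rate falls monotonically with ε_LJ and the complex's rate
matches the single enzyme's within the confidence interval at weak
coupling — placing the second enzyme behind the active site is only a
minor diffusive obstruction, i.e. γ_ch ≈ γ1 for uncharged enzymes.

## Problem sizes

The shipped tests and the acceptance script choose sizes that make the
statistical checks decisive while staying lightweight: 50-draw ensembles
for the analytic↔numeric equivalence (agreement ~1e-8, asserted at
1e-4), 10⁴ Brownian trajectories per estimate in the test suite
(σ_k/k ≈ 4–7%) and 2–4×10³ in the acceptance script. All are parameters,
so heavier runs are one argument away.

## Known limitations

* Spatially homogeneous, deterministic mass action: no stochastic
  (Gillespie) kinetics, no compartments, no crowding or anomalous
  diffusion.
* Proximity channeling (diffusive transfer along a shortened path) is
  outside the model; only direct transfer through the complex is treated.
* The second reaction and the transfer step are irreversible; only the
  one-complex reversible first step is implemented.
* The bead model is uncharged and rigid, with the substrate the only
  mobile species; electrostatic steering and hydrodynamic interactions
  are not included, so absolute rates are illustrative — the supported
  claims are the validated limits and trends above.
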