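"""Bead-model Brownian dynamics and Northrup-Allison-McCammon (NAM)
estimation of diffusion-limited substrate-enzyme association rates.

An enzyme is a shell of small Lennard-Jones beads on the vertices of a
subdivided icosahedron projected onto a core sphere; one bead is the active
site.  An enzyme-enzyme complex is two such shells merged along the z axis,
with the first enzyme's active site on the far side from the second enzyme.

The NAM method launches substrates uniformly on a sphere of radius b
(outside all interactions), propagates free-draining Brownian dynamics, and
scores a trajectory as captured when the substrate centre comes within the
reaction distance of the active-site bead, or escaped on crossing the
q-sphere.  The rate is

    k = k_D(b) * beta / (1 - (1 - beta) * k_D(b)/k_D(q)),   k_D(x) = 4 pi D x,

where the denominator analytically corrects for re-entries from beyond q.

Units: nm for lengths, ns for time, k_B T for energies; rates in nm^3/ns
(and converted to nM^-1 s^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "AVOGADRO",
    "NM3_PER_NS_TO_PER_NM_PER_S",
    "EnzymeGeometry",
    "NAMEstimate",
    "build_enzyme",
    "build_complex",
    "bare_sphere",
    "lj_energy_force",
    "nam_rate",
    "rate_ratio_complex",
    "smoluchowski_rate",
    "capture_probability_analytic",
]

AVOGADRO = 6.02214076e23
#: 1 nm^3/ns = 1e-24 L * 1e9 /s * N_A / (1e9 nM/M) = 0.602... nM^-1 s^-1
NM3_PER_NS_TO_PER_NM_PER_S = 1e-24 * AVOGADRO * 1e9 * 1e-9


@dataclass(frozen=True)
class EnzymeGeometry:
    """Bead-shell geometry of an enzyme or enzyme-enzyme complex.

    ``centers`` has shape (n_beads, 3) in nm; ``eps_lj`` and ``bead_radii``
    are per-bead (k_B T and nm).  ``core_centers`` lists the core-sphere
    centres (one per enzyme in the assembly).
    """

    centers: np.ndarray
    bead_radii: np.ndarray
    eps_lj: np.ndarray
    active_index: int
    core_radius: float
    core_centers: np.ndarray  # (n_enzymes, 3)

    def __post_init__(self):
        object.__setattr__(self, "centers", np.ascontiguousarray(self.centers, dtype=float))
        object.__setattr__(self, "bead_radii", np.ascontiguousarray(self.bead_radii, dtype=float))
        object.__setattr__(self, "eps_lj", np.ascontiguousarray(self.eps_lj, dtype=float))
        object.__setattr__(self, "core_centers", np.atleast_2d(np.asarray(self.core_centers, dtype=float)))
        n = len(self.centers)
        if not (0 <= self.active_index < n):
            raise ValueError(f"active_index {self.active_index} out of range for {n} beads")
        if self.bead_radii.shape != (n,) or self.eps_lj.shape != (n,):
            raise ValueError("per-bead arrays must match the number of beads")

    @property
    def n_beads(self) -> int:
        return len(self.centers)

    @property
    def active_site(self) -> np.ndarray:
        return self.centers[self.active_index]

    def with_eps(self, eps_lj: float) -> "EnzymeGeometry":
        """Same geometry with a uniform Lennard-Jones well depth (k_B T)."""
        return replace(self, eps_lj=np.full(self.n_beads, float(eps_lj)))

    def extent(self) -> float:
        """Largest bead-centre distance from the origin, nm."""
        return float(np.max(np.linalg.norm(self.centers, axis=1)))

    def to_xyz(self, comment: str = "") -> str:
        """XYZ export; the active-site bead is tagged 'A', others 'B'."""
        lines = [str(self.n_beads), comment]
        for i, c in enumerate(self.centers):
            tag = "A" if i == self.active_index else "B"
            lines.append(f"{tag} {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class NAMEstimate:
    """NAM rate estimate with Monte-Carlo uncertainty (delta-method on beta)."""

    beta: float
    beta_stderr: float
    k: float                 # nm^3/ns
    k_stderr: float          # nm^3/ns
    b: float
    q: float
    r_react: float
    D: float
    dt: float
    n_traj: int
    n_captured: int
    n_truncated: int
    seed: int
    min_sep_over_sigma: float  # closest substrate-bead approach, units of sigma

    @property
    def k_per_nM_per_s(self) -> float:
        return self.k * NM3_PER_NS_TO_PER_NM_PER_S

    @property
    def k_D_b(self) -> float:
        return 4.0 * math.pi * self.D * self.b

    def ci(self, n_sigma: float = 3.0) -> tuple[float, float]:
        return self.k - n_sigma * self.k_stderr, self.k + n_sigma * self.k_stderr


def smoluchowski_rate(D: float, R: float) -> float:
    """Diffusion-limited rate onto a perfectly absorbing sphere, 4 pi D R (nm^3/ns)."""
    return 4.0 * math.pi * D * R


def capture_probability_analytic(R: float, b: float, q: float) -> float:
    """First-passage probability to hit an absorbing sphere of radius R before
    an absorbing q-sphere, starting from radius b (concentric spheres):
    (1/b - 1/q)/(1/R - 1/q)."""
    return (1.0 / b - 1.0 / q) / (1.0 / R - 1.0 / q)


# ---------------------------------------------------------------------------
# geometry construction

_PHI = (1.0 + math.sqrt(5.0)) / 2.0


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    verts = []
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            verts += [(0.0, s1, s2 * _PHI), (s1, s2 * _PHI, 0.0), (s2 * _PHI, 0.0, s1)]
    v = np.array(verts)
    v /= np.linalg.norm(v[0])
    # faces: triples of mutually nearest vertices (edge length 2/|v0|)
    edge = 2.0 / math.sqrt(1.0 + _PHI ** 2)
    n = len(v)
    faces = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(np.linalg.norm(v[i] - v[j]) - edge) > 1e-9:
                continue
            for k in range(j + 1, n):
                if (abs(np.linalg.norm(v[i] - v[k]) - edge) < 1e-9
                        and abs(np.linalg.norm(v[j] - v[k]) - edge) < 1e-9):
                    faces.append((i, j, k))
    return v, np.array(faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    verts = list(map(tuple, verts))
    index = {np.round(v, 12).tobytes(): i for i, v in enumerate(np.asarray(verts))}

    def midpoint(i, j, verts_list):
        m = (np.array(verts_list[i]) + np.array(verts_list[j])) / 2.0
        m /= np.linalg.norm(m)
        key = np.round(m, 12).tobytes()
        if key not in index:
            index[key] = len(verts_list)
            verts_list.append(tuple(m))
        return index[key]

    new_faces = []
    for (i, j, k) in faces:
        a = midpoint(i, j, verts)
        b = midpoint(j, k, verts)
        c = midpoint(k, i, verts)
        new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
    return np.array(verts), np.array(new_faces)


def _rotation_to_pole(v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector v to +z."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def build_enzyme(core_radius: float = 1.5, subdivision_level: int = 1,
                 bead_radius: float = 0.37, eps_lj: float = 1.0) -> EnzymeGeometry:
    """Icosphere bead shell: 10*4^level + 2 beads on the core sphere, with the
    active-site bead rotated exactly onto the +z pole.

    Emits a warning (via logging) when neighbouring beads overlap by more
    than 90% of their diameter at the chosen level.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(subdivision_level):
        verts, faces = _subdivide(verts, faces)
    rot = _rotation_to_pole(verts[0])
    verts = verts @ rot.T
    centers = verts * core_radius
    active = int(np.argmax(centers[:, 2]))
    n = len(centers)
    # nearest-neighbour spacing check
    if n > 1:
        d2 = np.sum((centers[None] - centers[:, None]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if math.sqrt(d2.min()) < 0.1 * (2.0 * bead_radius):
            import logging
            logging.getLogger(__name__).warning(
                "bead overlap beyond 90%% of diameter at subdivision level %d",
                subdivision_level)
    return EnzymeGeometry(centers=centers,
                          bead_radii=np.full(n, float(bead_radius)),
                          eps_lj=np.full(n, float(eps_lj)),
                          active_index=active, core_radius=core_radius,
                          core_centers=np.zeros((1, 3)))


def build_complex(geom: EnzymeGeometry, separation: float = 1.4) -> EnzymeGeometry:
    """Merge two copies of ``geom`` into an enzyme-enzyme complex.

    The second enzyme's core centre is placed at (0, 0, -separation), i.e.
    behind the first enzyme relative to its active site at (0, 0, +core);
    beads of either shell whose centres fall inside the other core sphere
    are removed.
    """
    shift = np.array([0.0, 0.0, -float(separation)])
    c1, c2 = geom.centers, geom.centers + shift
    r = geom.core_radius
    keep1 = np.linalg.norm(c1 - shift, axis=1) >= r  # outside E2's core
    keep2 = np.linalg.norm(c2, axis=1) >= r          # outside E1's core
    keep1[geom.active_index] = True                  # active site always kept
    centers = np.vstack([c1[keep1], c2[keep2]])
    radii = np.concatenate([geom.bead_radii[keep1], geom.bead_radii[keep2]])
    eps = np.concatenate([geom.eps_lj[keep1], geom.eps_lj[keep2]])
    active = int(np.sum(keep1[:geom.active_index]))
    return EnzymeGeometry(centers=centers, bead_radii=radii, eps_lj=eps,
                          active_index=active, core_radius=r,
                          core_centers=np.vstack([np.zeros(3), shift]))


def bare_sphere(R: float, bead_radius: float = 0.37) -> EnzymeGeometry:
    """A single non-interacting bead at the origin: with reaction distance R
    this is the perfectly absorbing Smoluchowski sphere (validation geometry)."""
    return EnzymeGeometry(centers=np.zeros((1, 3)),
                          bead_radii=np.array([bead_radius]),
                          eps_lj=np.array([0.0]), active_index=0,
                          core_radius=R, core_centers=np.zeros((1, 3)))


# ---------------------------------------------------------------------------
# Lennard-Jones interaction

def lj_energy_force(pos: np.ndarray, geom: EnzymeGeometry,
                    substrate_radius: float = 0.4,
                    cutoff_factor: float = 3.0) -> tuple[float, np.ndarray]:
    """Truncated-shifted 12-6 Lennard-Jones energy (k_B T) and force (k_B T/nm)
    on a substrate at ``pos``.

    Per bead, sigma = bead_radius + substrate_radius and the potential
    4 eps [(sigma/r)^12 - (sigma/r)^6] is truncated and shifted to zero at
    ``cutoff_factor * sigma``.  ``cutoff_factor = 2**(1/6)`` yields the
    purely repulsive (WCA) variant used for the soft-enzyme rate trend.
    """
    pos = np.asarray(pos, dtype=float)
    dr = pos - geom.centers
    r2 = np.sum(dr * dr, axis=1)
    if np.any(r2 == 0.0):
        raise ValueError("substrate centre coincides with a bead centre (overlap)")
    sigma = geom.bead_radii + substrate_radius
    cut2 = (cutoff_factor * sigma) ** 2
    mask = (r2 < cut2) & (geom.eps_lj > 0)
    U = 0.0
    F = np.zeros(3)
    if np.any(mask):
        eps = geom.eps_lj[mask]
        s2 = sigma[mask] ** 2 / r2[mask]
        s6 = s2 ** 3
        s12 = s6 ** 2
        cf6 = cutoff_factor ** -6
        shift = 4.0 * eps * (cf6 * cf6 - cf6)  # U at the cutoff
        U = float(np.sum(4.0 * eps * (s12 - s6) - shift))
        fmag = 24.0 * eps * (2.0 * s12 - s6) / r2[mask]
        F = np.sum(fmag[:, None] * dr[mask], axis=0)
    return U, F


# ---------------------------------------------------------------------------
# NAM Brownian-dynamics kernel

@njit(cache=True)
def _nam_kernel(centers, eps4, sig2, cut2, active_pos, r_react, b, q, D,
                dt0, r_force, n_traj, seed0, max_steps, drift_cap):
    """Sequential per-trajectory BD propagation; returns
    (n_captured, n_truncated, min separation^2 / sigma^2 observed)."""
    n_beads = centers.shape[0]
    sqrt_2D = math.sqrt(2.0 * D)
    s0 = math.sqrt(6.0 * D * dt0)
    captured = 0
    truncated = 0
    min_ratio2 = 1e30
    r_react2 = r_react * r_react
    for itraj in range(n_traj):
        # decorrelate runs with different base seeds (a plain seed0+itraj
        # would share almost all trajectory streams between nearby seeds)
        np.random.seed((seed0 * 2654435761 + itraj * 7919) % 2147483647)
        # uniform point on the b-sphere
        while True:
            x = np.random.standard_normal()
            y = np.random.standard_normal()
            z = np.random.standard_normal()
            nrm = math.sqrt(x * x + y * y + z * z)
            if nrm > 1e-12:
                break
        px = b * x / nrm
        py = b * y / nrm
        pz = b * z / nrm
        steps = 0
        da_prev = b  # distance to the active site before the step
        r_prev = b
        dt_prev = -1.0
        while True:
            steps += 1
            if steps > max_steps:
                truncated += 1
                break
            r = math.sqrt(px * px + py * py + pz * pz)
            dax = px - active_pos[0]
            day = py - active_pos[1]
            daz = pz - active_pos[2]
            da2 = dax * dax + day * day + daz * daz
            da = math.sqrt(da2)
            if da <= r_react:
                captured += 1
                break
            if r >= q:
                break  # escaped
            if dt_prev > 0.0:
                # Brownian-bridge corrections for boundary crossings missed
                # between discrete samples (capture sphere, then q-sphere)
                var = 2.0 * D * dt_prev
                ex = 2.0 * (da_prev - r_react) * (da - r_react) / var
                if ex < 30.0 and np.random.random_sample() < math.exp(-ex):
                    captured += 1
                    break
                ex = 2.0 * (q - r_prev) * (q - r) / var
                if ex < 30.0 and np.random.random_sample() < math.exp(-ex):
                    break  # escaped across q and back
            if r <= r_force:
                # full-resolution step with forces
                dt = dt0
                fx = 0.0
                fy = 0.0
                fz = 0.0
                for ib in range(n_beads):
                    dx = px - centers[ib, 0]
                    dy = py - centers[ib, 1]
                    dz = pz - centers[ib, 2]
                    rr2 = dx * dx + dy * dy + dz * dz
                    if rr2 < cut2[ib] and eps4[ib] > 0.0:
                        ratio2 = rr2 / sig2[ib]
                        if ratio2 < min_ratio2:
                            min_ratio2 = ratio2
                        inv = sig2[ib] / rr2
                        s6 = inv * inv * inv
                        s12 = s6 * s6
                        fmag = 6.0 * eps4[ib] * (2.0 * s12 - s6) / rr2
                        fx += fmag * dx
                        fy += fmag * dy
                        fz += fmag * dz
                ddt = D * dt
                mx = ddt * fx
                my = ddt * fy
                mz = ddt * fz
                mlen = math.sqrt(mx * mx + my * my + mz * mz)
                if mlen > drift_cap:  # guard against rare deep-overlap kicks
                    scale = drift_cap / mlen
                    mx *= scale
                    my *= scale
                    mz *= scale
                sd = sqrt_2D * math.sqrt(dt)
                px += mx + sd * np.random.standard_normal()
                py += my + sd * np.random.standard_normal()
                pz += mz + sd * np.random.standard_normal()
            else:
                # force-free region: grow the step with distance to the force
                # region, the capture sphere and the escape sphere
                gap = r - r_force
                dgap = da - r_react
                if dgap < gap:
                    gap = dgap
                dq = q - r
                if dq < gap:
                    gap = dq
                s = gap / 4.0
                if s < s0:
                    s = s0
                dt = s * s / (6.0 * D)
                sd = sqrt_2D * math.sqrt(dt)
                px += sd * np.random.standard_normal()
                py += sd * np.random.standard_normal()
                pz += sd * np.random.standard_normal()
            da_prev = da
            r_prev = r
            dt_prev = dt
    return captured, truncated, min_ratio2


def nam_rate(geom: EnzymeGeometry, b: float = 5.0, q: float = 25.0,
             r_react: float = 0.82, D: float = 1.0, dt: float = 2e-4,
             n_traj: int = 10000, seed: int = 0,
             substrate_radius: float = 0.4, cutoff_factor: float = 3.0,
             max_steps: int = 20_000_000) -> NAMEstimate:
    """NAM estimate of the diffusion-limited association rate.

    Substrates start uniformly on the b-sphere, are propagated by
    free-draining Brownian dynamics (displacement D dt F/k_BT plus Gaussian
    noise of variance 2 D dt per coordinate) and are scored captured when
    their centre comes within ``r_react`` of the active-site bead centre.
    The time step is ``dt`` wherever forces act and grows adaptively in the
    force-free far field.  Bit-reproducible for fixed seed and dt.
    """
    if not (r_react < b < q):
        raise ValueError("need r_react < b < q")
    sigma = geom.bead_radii + substrate_radius
    bead_r = float(np.min(geom.bead_radii))
    if math.sqrt(6.0 * D * dt) > bead_r / 4.0:
        raise ValueError(
            f"dt={dt} too coarse: rms free step {math.sqrt(6*D*dt):.3g} nm exceeds "
            f"a quarter bead radius {bead_r/4:.3g} nm")
    interacting = geom.eps_lj > 0
    if np.any(interacting):
        r_force = float(np.max(np.linalg.norm(geom.centers[interacting], axis=1)
                               + cutoff_factor * sigma[interacting])) + 0.1
    else:
        r_force = 0.0
    if geom.extent() + float(np.max(sigma)) >= b:
        raise ValueError("geometry (plus contact distance) must fit inside the b-sphere")

    eps4 = 4.0 * geom.eps_lj
    sig2 = sigma ** 2
    cut2 = (cutoff_factor * sigma) ** 2
    captured, truncated, min_ratio2 = _nam_kernel(
        geom.centers, eps4, sig2, cut2, geom.active_site.astype(float),
        float(r_react), float(b), float(q), float(D), float(dt), r_force,
        int(n_traj), int(seed), int(max_steps), drift_cap=0.5 * float(np.min(sigma)))

    beta = captured / n_traj
    if captured == 0:
        beta_se = 3.0 / n_traj  # one-sided: rate consistent with zero
    else:
        beta_se = math.sqrt(beta * (1.0 - beta) / n_traj)
    kD_b = 4.0 * math.pi * D * b
    c = b / q
    denom = 1.0 - (1.0 - beta) * c
    k = kD_b * beta / denom
    k_se = kD_b * (1.0 - c) / denom ** 2 * beta_se
    return NAMEstimate(beta=beta, beta_stderr=beta_se, k=k, k_stderr=k_se,
                       b=b, q=q, r_react=r_react, D=D, dt=dt, n_traj=n_traj,
                       n_captured=captured, n_truncated=truncated, seed=seed,
                       min_sep_over_sigma=math.sqrt(min_ratio2) if min_ratio2 < 1e30 else math.inf)


def rate_ratio_complex(geom_single: EnzymeGeometry, geom_complex: EnzymeGeometry,
                       **protocol) -> tuple[float, float, NAMEstimate, NAMEstimate]:
    """k(E12)/k(E1) under an identical protocol and shared seed for both runs.

    Returns ``(ratio, ratio_stderr, est_single, est_complex)``; the standard
    error combines the two Monte-Carlo errors as if independent (conservative
    under common random numbers).
    """
    est1 = nam_rate(geom_single, **protocol)
    est12 = nam_rate(geom_complex, **protocol)
    ratio = est12.k / est1.k
    rel = math.sqrt((est1.k_stderr / est1.k) ** 2 + (est12.k_stderr / est12.k) ** 2)
    return ratio, ratio * rel, est1, est12
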