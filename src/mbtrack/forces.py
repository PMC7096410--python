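"""Per-particle force models: drag, Saffman lift, Brownian, gravity/buoyancy,
and Lennard-Jones MB-MB interaction.

All forces are vectorized over particles; every function accepts either a
single particle (1-D arrays) or ``n`` particles (2-D arrays, one row each).

Drag uses a piecewise standard-sphere correlation for the drag coefficient
C_D(Re_r).  Because C_D alone diverges as Re_r -> 0, the dynamics always
evaluate the *product* C_D * Re_r, which tends to the Stokes value 24; the
relaxation time is

    tau_p = 4 rho_p d_p^2 / (3 eta C_D Re_r)  ->  rho_p d_p^2 / (18 eta).

The Saffman lift is implemented in the printed form
F_L = -20.3 d_p^2 L_v sqrt(eta rho |u - v| / |L_v|) with
L_v = (u - v) x [curl(u - v)]; the prefactor and sign follow the source
correlation verbatim (see docs/methods.md for a note on the sign convention
relative to the classical Saffman result).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

TABLE_RE_MAX = 260.0  # upper validity limit of the drag correlation


def relative_reynolds(u_fluid, v_particle, d_p, rho_fluid, eta_app):
    """Particle relative Reynolds number rho |u - v| d_p / eta."""
    du = np.asarray(u_fluid, dtype=float) - np.asarray(v_particle, dtype=float)
    slip = np.linalg.norm(np.atleast_2d(du), axis=1)
    re = rho_fluid * slip * np.asarray(d_p, dtype=float) / np.asarray(
        eta_app, dtype=float)
    return float(re[0]) if np.asarray(u_fluid).ndim == 1 else re


def drag_cd_re(re_r):
    """The product C_D * Re_r from the piecewise standard-drag correlation.

    Finite everywhere, with the Stokes limit C_D*Re_r -> 24 at Re_r = 0.
    The middle branch uses w = log10(Re_r).  Values above Re_r = 260
    extrapolate the top branch with a warning.
    """
    re = np.asarray(re_r, dtype=float)
    if np.any(re < 0.0):
        raise ValueError("Re_r must be non-negative")
    if np.any(re > TABLE_RE_MAX):
        warnings.warn(
            f"Re_r above {TABLE_RE_MAX}: outside drag-correlation validity, "
            "extrapolating top branch", stacklevel=2)
    out = np.empty_like(re, dtype=float)
    lo = re <= 0.01
    hi = re >= 20.0
    mid = ~lo & ~hi
    out[lo] = 24.0 * (1.0 + (3.0 / 16.0) * re[lo])
    if np.any(mid):
        w = np.log10(re[mid])
        out[mid] = 24.0 * (1.0 + 0.1315 * re[mid] ** (0.82 - 0.05 * w))
    out[hi] = 24.0 * (1.0 + 0.1935 * re[hi] ** 0.6305)
    return float(out) if out.ndim == 0 else out


def drag_coefficient(re_r):
    """Drag coefficient C_D(Re_r); infinite at Re_r = 0 (Stokes limit is
    handled through the product C_D * Re_r, see :func:`drag_cd_re`)."""
    re = np.asarray(re_r, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(re > 0.0, drag_cd_re(np.maximum(re, 1e-300)) / re,
                       np.inf)
    return float(out) if out.ndim == 0 else out


def relaxation_time(d_p, rho_particle, eta_app, re_r=0.0):
    """Drag relaxation time tau_p = 4 rho_p d_p^2 / (3 eta C_D Re_r), s."""
    cdre = drag_cd_re(re_r)
    return 4.0 * np.asarray(rho_particle, dtype=float) * np.asarray(
        d_p, dtype=float) ** 2 / (3.0 * np.asarray(eta_app, dtype=float) * cdre)


def drag_force(u_fluid, v_particle, d_p, rho_fluid, rho_particle, eta_app):
    """Drag force F_D = (m_p / tau_p)(u - v), N; returns (force, tau_p).

    In the Stokes limit this reduces to 3 pi eta d_p (u - v).
    """
    u = np.asarray(u_fluid, dtype=float)
    v = np.asarray(v_particle, dtype=float)
    re = relative_reynolds(u, v, d_p, rho_fluid, eta_app)
    tau = relaxation_time(d_p, rho_particle, eta_app, re)
    d = np.asarray(d_p, dtype=float)
    m_p = np.asarray(rho_particle, dtype=float) * np.pi * d**3 / 6.0
    if u.ndim == 1:
        return (m_p / tau) * (u - v), float(tau)
    return (m_p / tau)[:, None] * (u - v), tau


def saffman_lift(u_fluid, v_particle, velocity_gradient, d_p, rho_fluid,
                 eta_app):
    """Shear-induced (Saffman-type) lift force, N.

    L_v = (u - v) x [curl(u - v)]; the particle velocity is spatially uniform
    so curl(u - v) = curl(u), taken from the fluid velocity gradient.  Zero
    whenever the slip or the curl vanishes.
    """
    u = np.asarray(u_fluid, dtype=float)
    single = u.ndim == 1
    u2 = np.atleast_2d(u)
    v2 = np.atleast_2d(np.asarray(v_particle, dtype=float))
    grad = np.asarray(velocity_gradient, dtype=float).reshape(-1, 3, 3)
    w = u2 - v2
    curl = np.empty_like(w)
    curl[:, 0] = grad[:, 2, 1] - grad[:, 1, 2]
    curl[:, 1] = grad[:, 0, 2] - grad[:, 2, 0]
    curl[:, 2] = grad[:, 1, 0] - grad[:, 0, 1]
    lv = np.cross(w, curl)
    lv_mag = np.linalg.norm(lv, axis=1)
    slip = np.linalg.norm(w, axis=1)
    d = np.broadcast_to(np.asarray(d_p, dtype=float), (len(u2),))
    eta = np.broadcast_to(np.asarray(eta_app, dtype=float), (len(u2),))
    ok = lv_mag > 0.0
    amp = np.zeros(len(u2))
    amp[ok] = -20.3 * d[ok] ** 2 * np.sqrt(
        eta[ok] * rho_fluid * slip[ok] / lv_mag[ok])
    force = amp[:, None] * lv
    return force[0] if single else force


def brownian_force(d_p, eta_app, temperature, dt, rng, kB=1.3806e-23, n=None):
    """Brownian force sampled as Gaussian noise, N.

    Each component is zeta_i * sqrt(6 pi k_B eta T d_p / dt) with independent
    standard-normal zeta_i from the supplied generator.  With the exponential
    drag integrator this amplitude reproduces Stokes-Einstein positional
    diffusion D = k_B T / (3 pi eta d_p) in the overdamped limit.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    d = np.asarray(d_p, dtype=float)
    eta = np.asarray(eta_app, dtype=float)
    amp = np.sqrt(6.0 * np.pi * kB * eta * temperature * d / dt)
    if n is None and d.ndim == 0:
        return amp * rng.standard_normal(3)
    count = n if n is not None else len(d)
    return np.broadcast_to(amp, (count,))[:, None] * rng.standard_normal(
        (count, 3))


def gravity_force(m_p, rho_particle, rho_fluid, g_vector):
    """Buoyancy-corrected weight F_G = m_p g (rho_p - rho) / rho_p, N.

    For MBs (rho_p < rho) the force opposes g: bubbles rise.
    """
    if np.any(np.asarray(rho_particle) <= 0.0):
        raise ValueError("rho_particle must be positive")
    g = np.asarray(g_vector, dtype=float)
    m = np.asarray(m_p, dtype=float)
    factor = m * (np.asarray(rho_particle, dtype=float) - rho_fluid) / \
        np.asarray(rho_particle, dtype=float)
    if m.ndim == 0:
        return factor * g
    return factor[:, None] * g


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones MB-MB interaction parameters.

    ``sigma`` per particle is ``sigma_factor * d_p`` (0.89 d_p places the
    potential minimum r_m = 2^(1/6) sigma at contact, r_m = d_p for
    rigid-surface MBs); pair sigma is the mean of the two particles' values.
    """

    epsilon: float = 8.20e-22      # J
    sigma_factor: float = 0.89     # sigma = sigma_factor * d_p
    cutoff_sigma: float = 5.0      # cutoff = cutoff_sigma * sigma_pair
    softening: float = 1e-3        # force capped below r = softening * sigma

    def __post_init__(self) -> None:
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        if self.cutoff_sigma < 1.0:
            raise ValueError("cutoff must be at least sigma")


def _lj_accumulate(positions, sigmas, pairs, params):
    n = len(positions)
    forces = np.zeros((n, 3))
    if len(pairs) == 0:
        return forces
    i = pairs[:, 0]
    j = pairs[:, 1]
    sig = 0.5 * (sigmas[i] + sigmas[j])
    rij = positions[i] - positions[j]
    r = np.linalg.norm(rij, axis=1)
    keep = r <= params.cutoff_sigma * sig
    if not np.all(r > 0.0):
        raise ValueError("coincident particle positions in LJ interaction")
    floor = params.softening * sig
    capped = r < floor
    if np.any(capped):
        warnings.warn("overlapping MBs: LJ force capped at softening floor",
                      stacklevel=2)
        r = np.maximum(r, floor)
    i, j, sig, rij, r = i[keep], j[keep], sig[keep], rij[keep], r[keep]
    sr = sig / r
    mag = (24.0 * params.epsilon / sig) * (2.0 * sr**13 - sr**7)
    f = (mag / r)[:, None] * rij   # on particle i, along r_i - r_j
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def lj_pair_forces(positions, diameters, params: LJParams = LJParams()):
    """Pairwise Lennard-Jones forces with a KD-tree neighbor search, N.

    F_i = (24 eps / sigma) sum_j [2 (sigma/r)^13 - (sigma/r)^7] rhat_ij over
    neighbors within the cutoff; exactly antisymmetric per pair so total
    momentum is conserved.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d = np.broadcast_to(np.asarray(diameters, dtype=float), (len(pos),))
    sigmas = params.sigma_factor * d
    if len(pos) < 2:
        return np.zeros_like(pos)
    rmax = params.cutoff_sigma * sigmas.max()
    pairs = cKDTree(pos).query_pairs(rmax, output_type="ndarray")
    return _lj_accumulate(pos, sigmas, pairs, params)


def lj_pair_forces_allpairs(positions, diameters,
                            params: LJParams = LJParams()):
    """All-pairs reference implementation (test oracle for the tree search)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d = np.broadcast_to(np.asarray(diameters, dtype=float), (len(pos),))
    sigmas = params.sigma_factor * d
    n = len(pos)
    if n < 2:
        return np.zeros_like(pos)
    ii, jj = np.triu_indices(n, k=1)
    pairs = np.column_stack([ii, jj])
    return _lj_accumulate(pos, sigmas, pairs, params)
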