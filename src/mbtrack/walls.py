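"""Wall-crossing detection and the mixed specular / diffuse reflection model.

When a microbubble's straight sub-step segment exits through the lateral
wall, the first surface intersection is located and the particle either
adheres (see :mod:`mbtrack.adhesion`) or is reflected.  Reflection is
specular with probability ``gamma`` (default 0.5) and otherwise diffuse
according to Knudsen's cosine law: the polar angle from the wall normal is
theta = asin(sqrt(Gamma)) with Gamma ~ U(0, 1), the azimuth is uniform, and
the speed is preserved.  The cosine-law normal component is
|v| cos(theta) along the inward normal (the printed sin(theta) form would
not preserve speed; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass
class WallHit:
    """A particle-wall collision event."""

    particle_id: int
    point: np.ndarray          # hit point on the surface, m
    element_id: int            # boundary-mesh element
    normal: np.ndarray         # outward unit normal
    velocity: np.ndarray       # incident particle velocity, m/s
    time: float                # s


def detect_wall_crossing(x_prev, x_new, geometry, mesh=None,
                         particle_id: int = -1, time: float = 0.0,
                         velocity=None):
    """First lateral-wall intersection of the segment x_prev -> x_new.

    Returns a :class:`WallHit` or ``None`` when the segment stays interior
    (exits through the inlet/outlet planes are classified by the engine, not
    here).  ``x_prev`` must be inside the domain.
    """
    x0 = np.asarray(x_prev, dtype=float)
    x1 = np.asarray(x_new, dtype=float)

    def f(s):
        p = x0 + s * (x1 - x0)
        return float(np.hypot(p[0], p[1]) - geometry.radius(p[2]))

    f0 = f(0.0)
    if f0 > 0.0:
        raise ValueError("segment start is outside the lateral wall")
    if f(1.0) <= 0.0:
        return None   # fully interior (radially)
    s_hit = brentq(f, 0.0, 1.0, xtol=1e-15)
    point = x0 + s_hit * (x1 - x0)
    normal = surface_normal(point, geometry)
    elem = mesh.locate_lateral(point) if mesh is not None else -1
    vel = (x1 - x0) if velocity is None else np.asarray(velocity, dtype=float)
    return WallHit(particle_id=particle_id, point=point, element_id=elem,
                   normal=normal, velocity=vel, time=time)


def surface_normal(point, geometry) -> np.ndarray:
    """Outward unit normal of the surface of revolution at a surface point."""
    x, y, z = (float(v) for v in point)
    r = np.hypot(x, y)
    if r == 0.0:
        raise ValueError("surface normal undefined on the axis")
    dr = geometry.radius_deriv(z)
    n = np.array([x / r, y / r, -dr])
    return n / np.linalg.norm(n)


def specular_reflect(v, n) -> np.ndarray:
    """Mirror reflection v' = v - 2 (n . v) n; position unchanged."""
    v = np.asarray(v, dtype=float)
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("normal must be unit length")
    return v - 2.0 * np.dot(n, v) * n


def tangent_basis(n) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair (t1, t2) completing the unit normal n.

    Gram-Schmidt against the coordinate axis with the smallest |n| component;
    azimuthal uniformity of the diffuse draw makes the choice immaterial, but
    determinism matters for seeded reproducibility.
    """
    n = np.asarray(n, dtype=float)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(n)))] = 1.0
    t1 = e - np.dot(e, n) * n
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def diffuse_reflect(v_c, n, rng) -> np.ndarray:
    """Knudsen cosine-law re-emission; ``n`` is the unit normal pointing into
    the fluid.  Speed is preserved exactly."""
    v_c = np.asarray(v_c, dtype=float)
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("normal must be unit length")
    speed = np.linalg.norm(v_c)
    gamma = rng.uniform()
    theta = np.arcsin(np.sqrt(gamma))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    t1, t2 = tangent_basis(n)
    return speed * (
        np.cos(theta) * n
        + np.sin(theta) * (np.sin(phi) * t1 + np.cos(phi) * t2)
    )


def mixed_reflect(hit: WallHit, gamma_specular: float, rng) -> np.ndarray:
    """Reflect a wall hit: specular with probability ``gamma_specular``,
    else diffuse off the inward normal.  Returns the outgoing velocity."""
    if not (0.0 <= gamma_specular <= 1.0):
        raise ValueError("gamma_specular must lie in [0, 1]")
    if rng.uniform() < gamma_specular:
        return specular_reflect(hit.velocity, hit.normal)
    return diffuse_reflect(hit.velocity, -hit.normal, rng)
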