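"""Synthetic idealized abdominal-aortic-aneurysm (AAA) domain.

This module stands in for a patient-specific fluid-structure-interaction
solve.  It provides:

* an axisymmetric geometry whose radius profile is a Gaussian bulge on a
  straight tube, dimensioned from a measured inlet lumen area (377.4 mm^2)
  and a maximum aneurysm diameter (40 mm);
* a periodic physiological inlet waveform with a systolic peak, and either a
  late-systolic retrograde (negative) lobe or a clamped non-negative variant;
* an analytic, exactly divergence-free lubrication-theory flow field with
  no-slip walls, queryable for velocity, velocity gradient and wall shear
  stress at any point and time;
* a triangulated boundary surface mesh with per-element areas, centroids,
  outward normals and region tags (aaa / non_aaa / inlet / outlet), on which
  adhered microbubbles are accumulated.

The lubrication field is a smooth laminar approximation: it conserves flux
exactly through every cross-section and satisfies no-slip, but it does not
reproduce the recirculating vortices of a real aneurysm (see docs/methods.md).
Externally computed fields can replace it via :mod:`mbtrack.external_field`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .rheology import RheologyParams, apparent_viscosity

# Truncated sum-of-Gaussians template for the physiological pulse:
# (center fraction of the period, width fraction, amplitude).  The first lobe
# is the systolic ejection peak, the second the retrograde (negative) lobe at
# end systole, the third a weak diastolic forward hump.
WAVEFORM_LOBES: tuple[tuple[float, float, float], ...] = (
    (0.20, 0.055, 1.00),
    (0.47, 0.060, -0.40),
    (0.78, 0.120, 0.12),
)


@dataclass(frozen=True)
class GeometryModel:
    """Axisymmetric tube-with-bulge geometry.

    The radius profile is R(z) = R0 + (R_a - R0) exp(-((z - z_c)/w_b)^2).
    The z axis runs from the inlet plane (z = 0) to the outlet plane
    (z = z_out); gravity acts along -y (supine patient).
    """

    inlet_radius_R0: float          # m
    bulge_max_radius_Ra: float      # m
    bulge_center_zc: float          # m
    bulge_width_wb: float           # m
    domain_length: float            # m
    carina_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)
    aaa_tag_threshold: float = 0.05  # aaa region where R > R0*(1+threshold)

    @property
    def outlet_plane_zout(self) -> float:
        return self.domain_length

    def radius(self, z):
        z = np.asarray(z, dtype=float)
        arg = (z - self.bulge_center_zc) / self.bulge_width_wb
        r = self.inlet_radius_R0 + (
            self.bulge_max_radius_Ra - self.inlet_radius_R0
        ) * np.exp(-arg * arg)
        return float(r) if r.ndim == 0 else r

    def radius_deriv(self, z):
        z = np.asarray(z, dtype=float)
        arg = (z - self.bulge_center_zc) / self.bulge_width_wb
        dr = (
            (self.bulge_max_radius_Ra - self.inlet_radius_R0)
            * np.exp(-arg * arg)
            * (-2.0 * arg / self.bulge_width_wb)
        )
        return float(dr) if dr.ndim == 0 else dr

    def radius_second_deriv(self, z):
        z = np.asarray(z, dtype=float)
        w = self.bulge_width_wb
        arg = (z - self.bulge_center_zc) / w
        d2 = (
            (self.bulge_max_radius_Ra - self.inlet_radius_R0)
            * np.exp(-arg * arg)
            * (4.0 * arg * arg - 2.0) / (w * w)
        )
        return float(d2) if d2.ndim == 0 else d2

    @property
    def aaa_interval(self) -> tuple[float, float]:
        """Axial interval [z_lo, z_hi] tagged as aneurysm lumen."""
        r_thresh = self.inlet_radius_R0 * (1.0 + self.aaa_tag_threshold)
        amp = self.bulge_max_radius_Ra - self.inlet_radius_R0
        excess = r_thresh - self.inlet_radius_R0
        if excess >= amp:
            return (self.bulge_center_zc, self.bulge_center_zc)
        half = self.bulge_width_wb * np.sqrt(np.log(amp / excess))
        return (self.bulge_center_zc - half, self.bulge_center_zc + half)

    def inside(self, x, tol: float = 0.0):
        """Containment predicate; x is (3,) or (n, 3)."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        r = np.hypot(pts[:, 0], pts[:, 1])
        z = pts[:, 2]
        ok = (z >= -tol) & (z <= self.domain_length + tol) & (
            r <= self.radius(z) + tol
        )
        return bool(ok[0]) if np.asarray(x).ndim == 1 else ok


@dataclass(frozen=True)
class InletWaveform:
    """Periodic inlet centerline-mean velocity v_in(t), m/s.

    ``kind`` is ``"negative"`` (the waveform dips below zero late in systole)
    or ``"non_negative"`` (the same template clamped at zero, rescaled to its
    own peak).
    """

    kind: str
    peak: float     # m/s
    period: float   # s
    _scale: float = field(repr=False, default=1.0)

    def _base(self, tau):
        b = np.zeros_like(tau)
        for center, width, amp in WAVEFORM_LOBES:
            # wrapped Gaussian for exact periodicity
            for k in (-1.0, 0.0, 1.0):
                b += amp * np.exp(-(((tau - center + k) / width) ** 2))
        return b

    def __call__(self, t):
        tau = np.asarray(t, dtype=float) / self.period % 1.0
        v = self._base(tau) * self._scale
        if self.kind == "non_negative":
            v = np.clip(v, 0.0, None)
        out = v
        return float(out) if out.ndim == 0 else out

    @property
    def min_over_period(self) -> float:
        tt = np.linspace(0.0, self.period, 4096, endpoint=False)
        return float(np.min(self(tt)))

    @property
    def mean_over_period(self) -> float:
        tt = np.linspace(0.0, self.period, 4096, endpoint=False)
        return float(np.mean(self(tt)))


def make_waveform(kind: str, peak: float, period: float = 1.0) -> InletWaveform:
    """Build a one-period inlet waveform with ``max == peak`` exactly.

    ``kind="negative"`` keeps the retrograde lobe (min < 0);
    ``kind="non_negative"`` clamps the template at zero.
    """
    if kind not in ("negative", "non_negative"):
        raise ValueError(f"unknown waveform kind {kind!r}")
    if peak <= 0.0:
        raise ValueError("peak must be positive")
    if period <= 0.0:
        raise ValueError("period must be positive")
    from scipy.optimize import minimize_scalar

    probe = InletWaveform(kind="negative", peak=1.0, period=1.0, _scale=1.0)
    tau = np.linspace(0.0, 1.0, 8192, endpoint=False)
    base = probe._base(tau)
    tau_star = tau[int(np.argmax(base))]
    res = minimize_scalar(
        lambda s: -probe._base(np.asarray(s)),
        bounds=(tau_star - 0.01, tau_star + 0.01), method="bounded",
        options={"xatol": 1e-14},
    )
    # clamping does not move the maximum (the template max is positive)
    scale = peak / float(-res.fun)
    return InletWaveform(kind=kind, peak=peak, period=period, _scale=scale)


@dataclass
class BoundaryMesh:
    """Triangulated boundary surface with per-element attributes.

    The lateral wall is a structured (z, theta) grid, each quad split into two
    triangles; inlet/outlet caps are triangle fans.  ``tags`` holds one of
    ``aaa``, ``non_aaa``, ``inlet``, ``outlet`` per element.
    """

    vertices: np.ndarray        # (nv, 3)
    triangles: np.ndarray       # (ne, 3) int
    areas: np.ndarray           # (ne,)
    centroids: np.ndarray       # (ne, 3)
    normals: np.ndarray         # (ne, 3) outward unit
    tags: np.ndarray            # (ne,) str
    # lateral-wall structured indexing for O(1) hit->element lookup
    n_z: int = 0
    n_theta: int = 0
    z_edges: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def region_area(self, tag: str) -> float:
        return float(self.areas[self.tags == tag].sum())

    def locate_lateral(self, point) -> int:
        """Map a point on (or near) the lateral wall to its triangle id.

        Lateral elements are stored first, ordered (iz, itheta, upper/lower).
        """
        x, y, z = (float(v) for v in point)
        iz = int(np.clip(np.searchsorted(self.z_edges, z) - 1, 0, self.n_z - 1))
        theta = np.arctan2(y, x) % (2.0 * np.pi)
        dtheta = 2.0 * np.pi / self.n_theta
        it = int(np.clip(theta // dtheta, 0, self.n_theta - 1))
        # local coordinates in the quad decide the triangle half
        u = (z - self.z_edges[iz]) / (self.z_edges[iz + 1] - self.z_edges[iz])
        v = theta / dtheta - it
        half = 0 if (u + v) <= 1.0 else 1
        return 2 * (iz * self.n_theta + it) + half


def _triangle_attrs(vertices: np.ndarray, tris: np.ndarray):
    p0 = vertices[tris[:, 0]]
    p1 = vertices[tris[:, 1]]
    p2 = vertices[tris[:, 2]]
    cross = np.cross(p1 - p0, p2 - p0)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    centroids = (p0 + p1 + p2) / 3.0
    normals = cross / (2.0 * areas)[:, None]
    return areas, centroids, normals


def build_idealized_aaa(
    inlet_area: float = 377.4e-6,
    max_aneurysm_diameter: float = 40e-3,
    bulge_center_fraction: float = 0.5,
    bulge_width: float = 0.02,
    length: float = 0.12,
    n_z: int = 80,
    n_theta: int = 48,
    carina_normal: tuple[float, float, float] = (1.0, 0.0, 0.0),
    aaa_tag_threshold: float = 0.05,
) -> tuple[GeometryModel, BoundaryMesh]:
    """Construct the idealized AAA geometry and its boundary surface mesh.

    Defaults reproduce the study dimensions: inlet lumen area 377.4 mm^2
    (R0 ~ 10.96 mm) and 40 mm maximum aneurysm diameter.
    """
    if inlet_area <= 0.0 or length <= 0.0 or bulge_width <= 0.0:
        raise ValueError("inlet_area, length and bulge_width must be positive")
    r0 = float(np.sqrt(inlet_area / np.pi))
    ra = max_aneurysm_diameter / 2.0
    if ra <= r0:
        raise ValueError(
            f"max_aneurysm_diameter ({max_aneurysm_diameter}) must exceed the "
            f"inlet diameter ({2 * r0:.4g}); degenerate bulge rejected"
        )
    geom = GeometryModel(
        inlet_radius_R0=r0,
        bulge_max_radius_Ra=ra,
        bulge_center_zc=bulge_center_fraction * length,
        bulge_width_wb=bulge_width,
        domain_length=length,
        carina_normal=carina_normal,
        aaa_tag_threshold=aaa_tag_threshold,
    )

    # lateral wall: structured grid of vertices on the surface of revolution
    z_edges = np.linspace(0.0, length, n_z + 1)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rr = geom.radius(z_edges)
    zz, tt = np.meshgrid(z_edges, thetas, indexing="ij")
    rr2 = np.repeat(rr[:, None], n_theta, axis=1)
    verts = np.column_stack(
        [(rr2 * np.cos(tt)).ravel(), (rr2 * np.sin(tt)).ravel(), zz.ravel()]
    )

    def vid(iz, it):
        return iz * n_theta + (it % n_theta)

    tris = []
    for iz in range(n_z):
        for it in range(n_theta):
            a = vid(iz, it)
            b = vid(iz, it + 1)
            c = vid(iz + 1, it)
            d = vid(iz + 1, it + 1)
            # winding chosen so cross products point outward (away from axis)
            tris.append((a, b, c))   # "lower" half (u + v <= 1)
            tris.append((b, d, c))   # "upper" half
    n_lateral = len(tris)

    # cap fans: inlet at z=0, outlet at z=length
    verts = np.vstack([verts, [[0.0, 0.0, 0.0]], [[0.0, 0.0, length]]])
    c_in = len(verts) - 2
    c_out = len(verts) - 1
    for it in range(n_theta):
        tris.append((c_in, vid(0, it + 1), vid(0, it)))         # normal -z
        tris.append((c_out, vid(n_z, it), vid(n_z, it + 1)))    # normal +z
    tris = np.asarray(tris, dtype=np.int64)

    areas, centroids, normals = _triangle_attrs(verts, tris)

    tags = np.empty(len(tris), dtype=object)
    z_lo, z_hi = geom.aaa_interval
    cz = centroids[:n_lateral, 2]
    tags[:n_lateral] = np.where((cz >= z_lo) & (cz <= z_hi), "aaa", "non_aaa")
    cap = tags[n_lateral:]
    cap_cz = centroids[n_lateral:, 2]
    tags[n_lateral:] = np.where(cap_cz < length / 2.0, "inlet", "outlet")

    mesh = BoundaryMesh(
        vertices=verts, triangles=tris, areas=areas, centroids=centroids,
        normals=normals, tags=tags.astype(str),
        n_z=n_z, n_theta=n_theta, z_edges=z_edges,
    )
    return geom, mesh


def revolution_surface_area(geom: GeometryModel, n: int = 20000) -> float:
    """Analytic lateral area of revolution, 2*pi Int R sqrt(1 + R'^2) dz."""
    z = np.linspace(0.0, geom.domain_length, n)
    r = geom.radius(z)
    dr = geom.radius_deriv(z)
    return float(np.trapezoid(2.0 * np.pi * r * np.sqrt(1.0 + dr * dr), z))


class LubricationFlowField:
    """Analytic divergence-free pulsatile flow in the idealized AAA.

    Axial velocity is a locally parabolic (Poiseuille-like) profile rescaled
    by continuity,

        u_z(r, z, t) = 2 v_in(t) (R0 / R(z))^2 (1 - (r / R(z))^2),

    and the radial component follows from exact integration of the
    incompressibility constraint, so div(u) = 0 analytically and the wall is
    exactly no-slip.  Pressure is identically zero (traction with pressure is
    exercised on imported fields or explicit inputs).
    """

    def __init__(self, geometry: GeometryModel, waveform: InletWaveform,
                 rheology: RheologyParams):
        self.geometry = geometry
        self.waveform = waveform
        self.rheology = rheology

    # -- cylindrical-component helpers -------------------------------------
    def _components(self, r, z, t):
        g = self.geometry
        v = self.waveform(t)
        r0sq = g.inlet_radius_R0 ** 2
        R = g.radius(z)
        dR = g.radius_deriv(z)
        uz = 2.0 * v * r0sq * (1.0 / R**2 - r**2 / R**4)
        ur = 2.0 * v * r0sq * dR * (r / R**3 - r**3 / R**5)
        return uz, ur

    def velocity(self, x, t):
        """Velocity (m/s) at point(s) x, time t; x is (3,) or (n, 3)."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        r = np.hypot(pts[:, 0], pts[:, 1])
        z = pts[:, 2]
        uz, ur = self._components(r, z, t)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = np.where(r > 0.0, pts[:, 0] / r, 1.0)
            sin_t = np.where(r > 0.0, pts[:, 1] / r, 0.0)
        out = np.column_stack([ur * cos_t, ur * sin_t, uz])
        return out[0] if np.asarray(x).ndim == 1 else out

    def velocity_gradient(self, x, t):
        """Cartesian velocity-gradient tensor(s) G[i,j] = du_i/dx_j, 1/s."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        g = self.geometry
        v = self.waveform(t)
        r0sq = g.inlet_radius_R0 ** 2
        xc, yc, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r = np.hypot(xc, yc)
        R = g.radius(z)
        dR = g.radius_deriv(z)
        d2R = g.radius_second_deriv(z)

        duz_dr = -4.0 * v * r0sq * r / R**4
        duz_dz = 2.0 * v * r0sq * dR * (-2.0 / R**3 + 4.0 * r**2 / R**5)
        dur_dr = 2.0 * v * r0sq * dR * (1.0 / R**3 - 3.0 * r**2 / R**5)
        dur_dz = 2.0 * v * r0sq * (
            d2R * (r / R**3 - r**3 / R**5)
            + dR * dR * (-3.0 * r / R**4 + 5.0 * r**3 / R**6)
        )
        # u_r / r, finite as r -> 0 (u_r ~ C r)
        ur_over_r = 2.0 * v * r0sq * dR * (1.0 / R**3 - r**2 / R**5)

        with np.errstate(invalid="ignore", divide="ignore"):
            ct = np.where(r > 0.0, xc / r, 1.0)
            st = np.where(r > 0.0, yc / r, 0.0)

        n = len(pts)
        grad = np.zeros((n, 3, 3))
        grad[:, 0, 0] = dur_dr * ct * ct + ur_over_r * st * st
        grad[:, 0, 1] = (dur_dr - ur_over_r) * ct * st
        grad[:, 0, 2] = dur_dz * ct
        grad[:, 1, 0] = grad[:, 0, 1]
        grad[:, 1, 1] = dur_dr * st * st + ur_over_r * ct * ct
        grad[:, 1, 2] = dur_dz * st
        grad[:, 2, 0] = duz_dr * ct
        grad[:, 2, 1] = duz_dr * st
        grad[:, 2, 2] = duz_dz
        return grad[0] if np.asarray(x).ndim == 1 else grad

    def pressure(self, x, t):
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.zeros(len(pts))
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    def wall_shear_rate(self, z, t):
        """Wall shear rate magnitude 4 |v_in(t)| R0^2 / R(z)^3, 1/s."""
        g = self.geometry
        R = g.radius(z)
        val = 4.0 * abs(self.waveform(t)) * g.inlet_radius_R0**2 / R**3
        return val

    def wall_shear_stress(self, point, t):
        """Wall shear stress magnitude eta_app(gdot_w) * gdot_w at a surface
        point (uses only the axial coordinate of the point), Pa."""
        z = np.asarray(point, dtype=float)[..., 2] if np.ndim(point) else point
        gdot = self.wall_shear_rate(z, t)
        return apparent_viscosity(gdot, self.rheology) * gdot

    def inside(self, x, tol: float = 0.0):
        return self.geometry.inside(x, tol=tol)

    def flux(self, z, t) -> float:
        """Volumetric flux through the cross-section at z; equals
        pi R0^2 v_in(t) independent of z (mass conservation built in)."""
        g = self.geometry
        return float(np.pi * g.inlet_radius_R0**2 * self.waveform(t))


def lubrication_flow(geometry: GeometryModel, waveform: InletWaveform,
                     rheology: RheologyParams) -> LubricationFlowField:
    """Build the analytic pulsatile flow field for a geometry + waveform."""
    return LubricationFlowField(geometry, waveform, rheology)


def vorticity(flow, x, t):
    """Vorticity curl(u) at x, from the field's gradient operator, 1/s."""
    if hasattr(flow, "inside") and not np.all(flow.inside(x)):
        raise ValueError("point outside the flow domain")
    grad = flow.velocity_gradient(x, t)
    grad = np.asarray(grad)
    w = np.empty(grad.shape[:-2] + (3,))
    w[..., 0] = grad[..., 2, 1] - grad[..., 1, 2]
    w[..., 1] = grad[..., 0, 2] - grad[..., 2, 0]
    w[..., 2] = grad[..., 1, 0] - grad[..., 0, 1]
    return w
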