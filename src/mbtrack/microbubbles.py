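"""Commercial microbubble (MB) formulations and particle cohort construction.

Four clinically approved ultrasound contrast agents are encoded with their
shell material, core gas, manufacturable diameter range and shell mechanics.
Shell surface tension / viscosity / elasticity are metadata only: they govern
acoustic response, which is outside the transport model; the quantities that
enter the dynamics are diameter and density (1000 kg/m^3 for all agents).

A cohort is a set of monodisperse MBs released at the inlet cross-section at
scheduled times (the study protocol is 500 MBs at t = 0, 1, 2, 3 s), seeded
uniformly over the inlet disc area with initial velocity equal to the local
fluid velocity at release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Particle status codes.
PENDING, ACTIVE, ADHERED, EXITED_OUTLET1, EXITED_OUTLET2, EXITED_INLET = range(6)

STATUS_NAMES = {
    PENDING: "pending",
    ACTIVE: "active",
    ADHERED: "adhered",
    EXITED_OUTLET1: "exited_outlet1",
    EXITED_OUTLET2: "exited_outlet2",
    EXITED_INLET: "exited_inlet",
}


@dataclass(frozen=True)
class MicrobubbleSpec:
    """A commercial MB formulation."""

    name: str
    shell: str
    core_gas: str
    diameter_range_um: tuple[float, float]   # [min, max], micrometres
    surface_tension: float                    # N/m
    shell_viscosity: float                    # Pa*s
    shell_elasticity: float                   # N/m
    density: float = 1000.0                   # kg/m^3

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_um
        if not (0.0 < lo <= hi):
            raise ValueError("diameter range must satisfy 0 < min <= max")
        if self.density <= 0.0:
            raise ValueError("density must be positive")

    @property
    def mid_diameter_um(self) -> float:
        lo, hi = self.diameter_range_um
        return 0.5 * (lo + hi)


def builtin_specs() -> dict[str, MicrobubbleSpec]:
    """The four built-in commercial MB formulations."""
    specs = [
        MicrobubbleSpec("definity", "lipid", "C3F8", (1.1, 3.3),
                        0.051, 0.00415, 0.855),
        MicrobubbleSpec("micromarker", "phospholipid", "C4F10", (2.0, 5.0),
                        0.051, 0.00952, 5.150),
        MicrobubbleSpec("optison", "albumin", "C3F8", (3.0, 4.5),
                        0.072, 0.001, 0.230),
        MicrobubbleSpec("sonovue", "phospholipid", "SF6", (1.5, 2.5),
                        0.073, 0.001, 0.55),
    ]
    return {s.name: s for s in specs}


def particle_mass(diameter: float, density: float = 1000.0) -> float:
    """Mass of a spherical particle, kg: rho * pi * d^3 / 6."""
    if diameter <= 0.0:
        raise ValueError("diameter must be positive")
    return density * np.pi * diameter**3 / 6.0


@dataclass(frozen=True)
class InjectionSchedule:
    """When and how many MBs enter the domain.

    ``r_min_frac``/``r_max_frac`` restrict seeding to an annulus of the inlet
    disc (fractions of the inlet radius); the default covers the whole disc.
    """

    count_per_injection: int = 500
    injection_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    r_min_frac: float = 0.0
    r_max_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.count_per_injection <= 0:
            raise ValueError("count_per_injection must be positive")
        if len(self.injection_times) == 0:
            raise ValueError("injection schedule is empty")
        if any(b < a for a, b in zip(self.injection_times,
                                     self.injection_times[1:])):
            raise ValueError("injection_times must be non-decreasing")
        if not (0.0 <= self.r_min_frac < self.r_max_frac <= 1.0):
            raise ValueError("require 0 <= r_min_frac < r_max_frac <= 1")

    @property
    def total(self) -> int:
        return self.count_per_injection * len(self.injection_times)


@dataclass
class Cohort:
    """Structure-of-arrays particle state for one run."""

    position: np.ndarray    # (n, 3) m
    velocity: np.ndarray    # (n, 3) m/s
    diameter: np.ndarray    # (n,) m
    mass: np.ndarray        # (n,) kg
    status: np.ndarray      # (n,) int codes
    t_inject: np.ndarray    # (n,) s
    t_final: np.ndarray     # (n,) s (nan until exit/adhesion/run end)
    aaa_time: np.ndarray    # (n,) s accumulated residence in the AAA region

    @property
    def n(self) -> int:
        return len(self.diameter)

    def status_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.status == code))
                for code, name in STATUS_NAMES.items()}


def make_cohort(spec: MicrobubbleSpec, diameter: float,
                schedule: InjectionSchedule, geometry, field,
                seed: int | np.random.Generator) -> Cohort:
    """Seed a monodisperse cohort on the inlet disc.

    Positions are uniform over the seeding annulus area; initial velocity is
    the local fluid velocity at each particle's release time.  Deterministic
    given the seed.

    Parameters
    ----------
    spec : MicrobubbleSpec
        Formulation; a diameter outside its range triggers a warning only.
    diameter : float
        Particle diameter, m.
    geometry : GeometryModel
    field : flow field with a ``velocity(x, t)`` method
    seed : int or numpy Generator
    """
    lo, hi = spec.diameter_range_um
    if not (lo * 1e-6 <= diameter <= hi * 1e-6):
        warnings.warn(
            f"diameter {diameter * 1e6:.3g} um outside {spec.name} range "
            f"[{lo}, {hi}] um", stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n = schedule.total
    z_seed = 1e-6 * geometry.domain_length  # just inside the inlet plane
    # fractions are relative to the local lumen radius at the seeding plane
    # (== R0 up to the far tail of the bulge), so r_max_frac -> 1 seeds
    # genuinely wall-adjacent particles
    r0 = geometry.radius(z_seed)
    pos = np.empty((n, 3))
    vel = np.empty((n, 3))
    t_inj = np.empty(n)
    k = schedule.count_per_injection
    a2 = schedule.r_min_frac**2
    b2 = schedule.r_max_frac**2
    for i, t0 in enumerate(schedule.injection_times):
        sl = slice(i * k, (i + 1) * k)
        u = rng.uniform(size=k)
        r = r0 * np.sqrt(a2 + u * (b2 - a2))
        th = rng.uniform(0.0, 2.0 * np.pi, size=k)
        pos[sl, 0] = r * np.cos(th)
        pos[sl, 1] = r * np.sin(th)
        pos[sl, 2] = z_seed
        vel[sl] = field.velocity(pos[sl], t0)
        t_inj[sl] = t0

    m = particle_mass(diameter, spec.density)
    return Cohort(
        position=pos,
        velocity=vel,
        diameter=np.full(n, float(diameter)),
        mass=np.full(n, m),
        status=np.full(n, PENDING, dtype=np.int64),
        t_inject=t_inj,
        t_final=np.full(n, np.nan),
        aaa_time=np.zeros(n),
    )
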