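"""Ligand-receptor adhesion probability (Decuzzi-Ferrari model) and the
surface-density-of-microbubbles (SDM) accumulator.

The MB surface carries P-selectin aptamer ligands; the endothelium carries
receptors at surface density ``m_r``.  At a wall collision the probability of
having formed at least one bond is

    P_a = pi r0^2 m_r m_l Ka0
          * exp[ - beta d_p (eta S) / (kB T r0^2 m_r)
                 * ( 3 (d_p/2 + delta_eq) F_s + (d_p^2 / r0) T_s ) ]

capped at 1, where ``eta S`` is the local wall shear stress, ``r0`` the
radius of the contact annulus within bonding reach h0,

    r0^2 = d_p^2 [ 1/4 - (1/2 - (h0 - delta_eq)/d_p)^2 ],

and F_s = 1.668, T_s = 0.944 are the Goldman wall-correction factors for a
sphere.  Hydrodynamic load (shear) strains the bonds and suppresses P_a
exponentially -- high-shear regions capture fewer MBs.

The printed parameter set gives only the kinetic rates k_f0, k_r0 (1/s),
while P_a needs an area-dimensioned association constant; here
Ka0 = (k_f0 / k_r0) * A_bond with a configurable bond-patch area A_bond, a
declared free parameter recorded in every run's metadata (see
docs/methods.md).  The ligand density m_l is likewise configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .microbubbles import ADHERED
from .rheology import BOLTZMANN_KB


@dataclass(frozen=True)
class AdhesionParams:
    """Kinetic and geometric constants of the adhesive-dynamics model.

    Defaults are the P-selectin aptamer (PSA : P-selectin) set; ``beta`` is
    stored in metres (0.21 Angstrom), ``delta_eq`` and ``h_0`` in metres.
    """

    k_f0: float = 2.33e5            # 1/s intrinsic forward rate
    k_r0: float = 3.4e-5            # 1/s intrinsic reverse rate
    bond_patch_area: float = 8.822e-29  # m^2; Ka0 = (k_f0/k_r0) * this
    beta: float = 0.21e-10          # m, reactive compliance
    delta_eq: float = 50e-9         # m, equilibrium bond length
    m_r: float = 2.7e15             # 1/m^2, receptor surface density
    m_l: float = 1.0e15             # 1/m^2, ligand surface density
    h_0: float = 100e-9             # m, max bond-formation distance
    F_s: float = 1.668              # Goldman force factor (sphere)
    T_s: float = 0.944              # Goldman torque factor (sphere)
    temperature: float = 310.15     # K
    boltzmann_kB: float = BOLTZMANN_KB

    def __post_init__(self) -> None:
        for name in ("k_f0", "k_r0", "bond_patch_area", "beta", "delta_eq",
                     "m_r", "m_l", "h_0", "F_s", "T_s", "temperature"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.h_0 <= self.delta_eq:
            raise ValueError("h_0 must exceed delta_eq")

    @property
    def K_a0(self) -> float:
        """Association constant at zero load, m^2."""
        return (self.k_f0 / self.k_r0) * self.bond_patch_area


def bond_radius_squared(d_p: float, h_0: float, delta_eq: float) -> float:
    """Squared radius of the contact annulus within bonding reach, m^2.

    Clipped at zero when the reach h_0 - delta_eq is non-positive (warning)
    or exceeds geometric contact.
    """
    if h_0 <= delta_eq:
        warnings.warn("h_0 <= delta_eq: no geometric contact annulus",
                      stacklevel=2)
        return 0.0
    frac = (h_0 - delta_eq) / d_p
    val = d_p**2 * (0.25 - (0.5 - frac) ** 2)
    return max(val, 0.0)


def adhesion_probability(d_p, wall_shear_stress,
                         params: AdhesionParams = AdhesionParams()):
    """Probability of at least one ligand-receptor bond at a wall collision.

    ``wall_shear_stress`` is the local eta_app * S in Pa (>= 0); scalar or
    array.  Always in [0, 1]; strictly decreasing in shear stress.
    """
    s = np.asarray(wall_shear_stress, dtype=float)
    if np.any(s < 0.0):
        raise ValueError("wall shear stress must be non-negative")
    r0sq = bond_radius_squared(d_p, params.h_0, params.delta_eq)
    if r0sq == 0.0:
        out = np.zeros_like(s)
        return float(out) if out.ndim == 0 else out
    r0 = np.sqrt(r0sq)
    prefactor = np.pi * r0sq * params.m_r * params.m_l * params.K_a0
    load = (params.beta * d_p * s
            / (params.boltzmann_kB * params.temperature * r0sq * params.m_r))
    geom = 3.0 * (d_p / 2.0 + params.delta_eq) * params.F_s \
        + (d_p**2 / r0) * params.T_s
    p = np.minimum(prefactor * np.exp(-load * geom), 1.0)
    return float(p) if p.ndim == 0 else p


def try_adhere(hit, flow, params: AdhesionParams, rng,
               cohort=None) -> bool:
    """Bernoulli adhesion decision at a wall hit.

    Draws against :func:`adhesion_probability` evaluated with the wall shear
    stress at the hit point and time.  On success and when a cohort is given,
    the particle is frozen at the hit point with status ``adhered``.
    """
    if cohort is None:
        raise ValueError("try_adhere requires the cohort for the diameter")
    d_p = float(cohort.diameter[hit.particle_id])
    s = float(flow.wall_shear_stress(hit.point, hit.time))
    p = adhesion_probability(d_p, s, params)
    if rng.uniform() < p:
        i = hit.particle_id
        cohort.status[i] = ADHERED
        cohort.position[i] = hit.point
        cohort.velocity[i] = 0.0
        cohort.t_final[i] = hit.time
        return True
    return False


@dataclass
class SDMField:
    """Per-boundary-element adhered-count accumulator.

    ``sdm`` per element is count / area (1/m^2); the scalar study outcome is
    the region summary over the aneurysm lumen:
    total adhered count in region / total region area.
    """

    mesh: "object"                       # BoundaryMesh
    counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(self.mesh.n_elements, dtype=np.int64)

    @property
    def sdm(self) -> np.ndarray:
        return self.counts / self.mesh.areas

    def accumulate(self, element_id: int) -> None:
        if not (0 <= element_id < self.mesh.n_elements):
            raise KeyError(f"unknown boundary element {element_id}")
        self.counts[element_id] += 1

    def summary(self, region: str = "aaa") -> float:
        mask = self.mesh.tags == region
        area = float(self.mesh.areas[mask].sum())
        if area == 0.0:
            raise ValueError(f"region {region!r} has zero area")
        return float(self.counts[mask].sum()) / area

    def total_count(self, region: str | None = None) -> int:
        if region is None:
            return int(self.counts.sum())
        return int(self.counts[self.mesh.tags == region].sum())


def sdm_accumulate(sdm_field: SDMField, element_id: int) -> SDMField:
    """Increment one element's adhered count (functional-style wrapper)."""
    sdm_field.accumulate(element_id)
    return sdm_field


def sdm_summary(sdm_field: SDMField, region: str = "aaa") -> float:
    """Region-level SDM: adhered count per unit region area, 1/m^2."""
    return sdm_field.summary(region)
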