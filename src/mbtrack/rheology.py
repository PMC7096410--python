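"""Constitutive models: Carreau-Yasuda blood rheology, generalized-Newtonian
stress and wall traction, and a hyperelastic strain-energy evaluator for the
aneurysmal wall.

Blood is shear-thinning: its apparent viscosity falls from a zero-shear
plateau ``eta_zero`` to an infinite-shear plateau ``eta_inf`` as the local
shear rate grows.  The Carreau-Yasuda interpolation

    eta(gdot) = eta_inf + (eta_zero - eta_inf) * [1 + (lambda*gdot)^2]^((a-1)/2)

is parameterized per hematocrit level (volume fraction of red blood cells);
three presets are shipped for 25% (anemic), 45% (healthy) and 65% (e.g.
dehydration/polycythemia) hematocrit.

The wall model is a two-parameter Yeoh-type (Raghavan) strain-energy density
used here purely as a pointwise evaluator -- no finite-element solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann's constant, m^2 kg / (s^2 K)
BOLTZMANN_KB = 1.3806e-23


@dataclass(frozen=True)
class RheologyParams:
    """One Carreau-Yasuda parameter set.

    Attributes
    ----------
    hct_label : str
        Hematocrit tag, e.g. ``"45%"``.
    eta_zero : float
        Zero-shear viscosity, Pa*s.
    eta_inf : float
        Infinite-shear viscosity, Pa*s.
    lambda_time : float
        Relaxation time constant, s.
    power_index_a : float
        Dimensionless power-law index (< 1 for shear thinning).
    """

    hct_label: str
    eta_zero: float
    eta_inf: float
    lambda_time: float
    power_index_a: float

    def __post_init__(self) -> None:
        if not (self.eta_zero > self.eta_inf > 0.0):
            raise ValueError(
                f"require eta_zero > eta_inf > 0, got {self.eta_zero}, {self.eta_inf}"
            )
        if self.lambda_time <= 0.0:
            raise ValueError("lambda_time must be positive")


#: Carreau-Yasuda presets keyed by hematocrit percentage.
HCT_PRESETS: dict[int, RheologyParams] = {
    25: RheologyParams("25%", eta_zero=0.0178, eta_inf=0.00257,
                       lambda_time=12.448, power_index_a=0.330),
    45: RheologyParams("45%", eta_zero=0.1613, eta_inf=0.00345,
                       lambda_time=9.418, power_index_a=0.479),
    65: RheologyParams("65%", eta_zero=0.8592, eta_inf=0.00802,
                       lambda_time=103.088, power_index_a=0.389),
}


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties entering the particle force models."""

    density_rho: float = 1050.0          # kg/m^3
    temperature_T: float = 310.15        # K
    boltzmann_kB: float = BOLTZMANN_KB   # m^2 kg / (s^2 K)
    gravity_vector_g: tuple[float, float, float] = (0.0, -9.81, 0.0)  # m/s^2

    def __post_init__(self) -> None:
        if self.density_rho <= 0.0:
            raise ValueError("density_rho must be positive")
        if self.temperature_T < 0.0:
            raise ValueError("temperature_T must be non-negative")


@dataclass(frozen=True)
class WallMaterial:
    """Yeoh/Raghavan hyperelastic constants for the aneurysmal wall."""

    c10: float = 0.174               # MPa
    c20: float = 1.881               # MPa
    incompressibility_d: float = 1.149  # dimensionless
    density: float = 1120.0          # kg/m^3

    def __post_init__(self) -> None:
        for name in ("c10", "c20", "incompressibility_d", "density"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")


#: Default aneurysmal wall material.
AAA_WALL = WallMaterial()


def apparent_viscosity(shear_rate, params: RheologyParams):
    """Carreau-Yasuda apparent viscosity, Pa*s.

    Parameters
    ----------
    shear_rate : float or ndarray
        Local scalar shear rate, 1/s (non-negative).
    params : RheologyParams
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0.0):
        raise ValueError("shear_rate must be non-negative")
    bracket = 1.0 + (params.lambda_time * gdot) ** 2
    eta = params.eta_inf + (params.eta_zero - params.eta_inf) * bracket ** (
        (params.power_index_a - 1.0) / 2.0
    )
    if np.isscalar(shear_rate):
        return float(eta)
    return eta


def strain_rate_tensor(velocity_gradient) -> np.ndarray:
    """Deviatoric strain-rate tensor S from a velocity gradient G[i,j] = du_i/dx_j.

    S_ij = (du_i/dx_j + du_j/dx_i)/2 - (du_k/dx_k) delta_ij / 3; traceless by
    construction.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.shape[-2:] != (3, 3):
        raise ValueError("velocity_gradient must be (..., 3, 3)")
    sym = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    div = np.trace(grad, axis1=-2, axis2=-1)
    return sym - (div[..., None, None] / 3.0) * np.eye(3)


def shear_rate_magnitude(strain_rate) -> float:
    """Scalar shear rate sqrt(2 S:S); equals gdot for simple shear at rate gdot."""
    s = np.asarray(strain_rate, dtype=float)
    mag = np.sqrt(2.0 * np.sum(s * s, axis=(-2, -1)))
    return float(mag) if mag.ndim == 0 else mag


def viscous_stress(strain_rate, pressure: float, eta_app: float) -> np.ndarray:
    """Generalized-Newtonian stress tau_ij = 2 eta_app S_ij - p delta_ij, Pa."""
    if eta_app <= 0.0:
        raise ValueError("eta_app must be positive")
    s = np.asarray(strain_rate, dtype=float)
    return 2.0 * eta_app * s - pressure * np.eye(3)


def wall_traction(velocity_gradient, pressure: float, outward_normal,
                  eta_app: float) -> np.ndarray:
    """Traction exerted by the fluid on a solid boundary with outward normal n.

        f = n . [ -p I + eta_app ( (grad u + grad u^T) - 2/3 (div u) I ) ]

    A non-unit normal is normalized with a warning.
    """
    import warnings

    grad = np.asarray(velocity_gradient, dtype=float)
    n = np.asarray(outward_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0.0:
        raise ValueError("outward_normal must be non-zero")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("outward_normal not unit length; normalizing", stacklevel=2)
        n = n / norm
    div = np.trace(grad)
    sigma = -pressure * np.eye(3) + eta_app * (
        grad + grad.T - (2.0 / 3.0) * div * np.eye(3)
    )
    return n @ sigma


def strain_energy_density(i1: float, jdet: float, material: WallMaterial) -> float:
    """Hyperelastic strain-energy density, MPa.

        W = C10 (I1 - 3) + C20 (I1 - 3)^2 + (J - 1)^2 / d

    ``i1`` is the first deviatoric strain invariant (>= 3) and ``jdet`` the
    volume ratio (> 0).
    """
    if i1 < 3.0:
        raise ValueError(f"first invariant must be >= 3, got {i1}")
    if jdet <= 0.0:
        raise ValueError("volume ratio J must be positive")
    x = i1 - 3.0
    return (material.c10 * x + material.c20 * x * x
            + (jdet - 1.0) ** 2 / material.incompressibility_d)
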