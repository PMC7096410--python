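"""Run configuration: schema, validation, defaults.

A run is fully described by one structured YAML file (or an in-memory
:class:`RunConfig`); every output embeds the resolved config and its hash so
any result can be reproduced from a single artifact.  Unknown keys are
rejected; physical quantities carry explicit unit suffixes in their key
names.  A minimal config needs only a microbubble name and a seed: defaults
resolve to the study protocol (500 MBs x 4 one-second injections, 45%
hematocrit, negative inlet waveform with 0.44 m/s peak, gamma = 0.5).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .adhesion import AdhesionParams
from .forces import LJParams
from .microbubbles import InjectionSchedule, MicrobubbleSpec, builtin_specs
from .rheology import HCT_PRESETS, FluidProperties, RheologyParams


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    inlet_area_mm2: float = 377.4
    max_aneurysm_diameter_mm: float = 40.0
    bulge_center_fraction: float = 0.5
    bulge_width_m: float = 0.02
    length_m: float = 0.12
    mesh_n_z: int = Field(80, ge=4)
    mesh_n_theta: int = Field(48, ge=8)
    aaa_tag_threshold: float = 0.05
    carina_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)


class WaveformConfig(_Block):
    kind: Literal["negative", "non_negative"] = "negative"
    peak_m_s: float = Field(0.44, gt=0.0)
    period_s: float = Field(1.0, gt=0.0)


class RheologyConfig(_Block):
    hct_percent: Literal[25, 45, 65] = 45
    # optional full override of the Carreau-Yasuda preset
    eta_zero_Pa_s: float | None = None
    eta_inf_Pa_s: float | None = None
    lambda_s: float | None = None
    power_index_a: float | None = None


class FluidConfig(_Block):
    density_kg_m3: float = Field(1050.0, gt=0.0)
    temperature_K: float = Field(310.15, gt=0.0)
    gravity_m_s2: tuple[float, float, float] = (0.0, -9.81, 0.0)


class MicrobubbleConfig(_Block):
    name: Literal["definity", "micromarker", "optison", "sonovue"] = "definity"
    diameter_um: float | Literal["min", "mid", "max"] = "mid"
    density_kg_m3: float = Field(1000.0, gt=0.0)


class InjectionConfig(_Block):
    count_per_injection: int = Field(500, gt=0)
    times_s: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    r_min_frac: float = 0.0
    r_max_frac: float = 1.0


class AdhesionConfig(_Block):
    enabled: bool = True
    k_f0_per_s: float = 2.33e5
    k_r0_per_s: float = 3.4e-5
    bond_patch_area_m2: float = 8.822e-29
    beta_angstrom: float = 0.21
    delta_eq_nm: float = 50.0
    h0_nm: float = 100.0
    m_r_per_m2: float = 2.7e15
    m_l_per_m2: float = 1.0e15
    F_s: float = 1.668
    T_s: float = 0.944


class PhysicsConfig(_Block):
    lift: bool = True
    brownian: bool = True
    gravity: bool = True
    interaction: bool = True
    gamma_specular: float = Field(0.5, ge=0.0, le=1.0)
    epsilon_wall_m: float = Field(1e-6, gt=0.0)
    lj_epsilon_J: float = Field(8.20e-22, gt=0.0)
    lj_sigma_factor: float = Field(0.89, gt=0.0)
    lj_cutoff_sigma: float = Field(5.0, ge=1.0)


class NumericsConfig(_Block):
    dt_s: float = Field(1e-3, gt=0.0)
    t_end_s: float = Field(4.0, gt=0.0)


class OutputConfig(_Block):
    directory: str | None = None
    trajectories: bool = False
    events: bool = False
    trajectory_stride: int = Field(10, gt=0)


class RunConfig(_Block):
    """Fully resolved run configuration."""

    geometry: GeometryConfig = GeometryConfig()
    waveform: WaveformConfig = WaveformConfig()
    rheology: RheologyConfig = RheologyConfig()
    fluid: FluidConfig = FluidConfig()
    microbubble: MicrobubbleConfig = MicrobubbleConfig()
    injection: InjectionConfig = InjectionConfig()
    adhesion: AdhesionConfig = AdhesionConfig()
    physics: PhysicsConfig = PhysicsConfig()
    numerics: NumericsConfig = NumericsConfig()
    output: OutputConfig = OutputConfig()
    seed: int = 0

    @model_validator(mode="after")
    def _cross_field(self) -> "RunConfig":
        if self.numerics.t_end_s < max(self.injection.times_s):
            raise ValueError(
                "numerics.t_end_s must not precede the last injection time")
        if self.geometry.max_aneurysm_diameter_mm ** 2 * 3.141592653589793 / 4.0 \
                <= self.geometry.inlet_area_mm2:
            raise ValueError(
                "max aneurysm diameter must exceed the inlet diameter")
        return self

    # -- resolution helpers -------------------------------------------------

    def mb_spec(self) -> MicrobubbleSpec:
        return builtin_specs()[self.microbubble.name]

    def diameter_m(self) -> float:
        spec = self.mb_spec()
        d = self.microbubble.diameter_um
        if d == "min":
            d = spec.diameter_range_um[0]
        elif d == "max":
            d = spec.diameter_range_um[1]
        elif d == "mid":
            d = spec.mid_diameter_um
        lo, hi = spec.diameter_range_um
        if not (lo <= float(d) <= hi):
            warnings.warn(
                f"diameter {d} um outside {spec.name} range [{lo}, {hi}] um",
                stacklevel=2)
        return float(d) * 1e-6

    def rheology_params(self) -> RheologyParams:
        base = HCT_PRESETS[self.rheology.hct_percent]
        r = self.rheology
        if any(v is not None for v in
               (r.eta_zero_Pa_s, r.eta_inf_Pa_s, r.lambda_s, r.power_index_a)):
            return RheologyParams(
                hct_label=f"{r.hct_percent}% (custom)",
                eta_zero=r.eta_zero_Pa_s or base.eta_zero,
                eta_inf=r.eta_inf_Pa_s or base.eta_inf,
                lambda_time=r.lambda_s or base.lambda_time,
                power_index_a=r.power_index_a or base.power_index_a,
            )
        return base

    def fluid_properties(self) -> FluidProperties:
        return FluidProperties(
            density_rho=self.fluid.density_kg_m3,
            temperature_T=self.fluid.temperature_K,
            gravity_vector_g=self.fluid.gravity_m_s2,
        )

    def injection_schedule(self) -> InjectionSchedule:
        return InjectionSchedule(
            count_per_injection=self.injection.count_per_injection,
            injection_times=self.injection.times_s,
            r_min_frac=self.injection.r_min_frac,
            r_max_frac=self.injection.r_max_frac,
        )

    def adhesion_params(self) -> AdhesionParams:
        a = self.adhesion
        return AdhesionParams(
            k_f0=a.k_f0_per_s, k_r0=a.k_r0_per_s,
            bond_patch_area=a.bond_patch_area_m2,
            beta=a.beta_angstrom * 1e-10,
            delta_eq=a.delta_eq_nm * 1e-9,
            h_0=a.h0_nm * 1e-9,
            m_r=a.m_r_per_m2, m_l=a.m_l_per_m2,
            F_s=a.F_s, T_s=a.T_s,
            temperature=self.fluid.temperature_K,
        )

    def lj_params(self) -> LJParams:
        return LJParams(
            epsilon=self.physics.lj_epsilon_J,
            sigma_factor=self.physics.lj_sigma_factor,
            cutoff_sigma=self.physics.lj_cutoff_sigma,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; raises with every schema
    violation listed (key paths included) rather than stopping at the first."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as err:
        lines = [f"invalid run config {path}:"]
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            lines.append(f"  {loc}: {e['msg']}")
        raise ValueError("\n".join(lines)) from None
    if cfg.output.directory is not None:
        out = Path(cfg.output.directory)
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        try:
            probe.touch()
            probe.unlink()
        except OSError as exc:
            raise ValueError(f"output directory not writable: {out}") from exc
    cfg.diameter_m()  # emit the out-of-range warning at load time
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
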