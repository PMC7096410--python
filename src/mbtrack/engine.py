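"""Time integration of the microbubble equation of motion and run-level
outcome metrics.

The force balance per MB is

    m_p dv/dt = F_drag + F_lift + F_brownian + F_gravity + F_interaction.

With micrometre bubbles the drag relaxation time tau_p ~ 1e-8 -- 1e-7 s is
orders of magnitude below any practical time step, so an explicit scheme is
hopeless.  The integrator instead uses the exact relaxation (exponential)
update for locally constant fluid velocity: writing all non-drag forces as
F_other and u_eff = u + tau_p F_other / m_p,

    v(t + dt) = u_eff + (v - u_eff) exp(-dt / tau_p)
    x(t + dt) = x + u_eff dt + (v - u_eff) tau_p (1 - exp(-dt / tau_p)),

which is unconditionally stable and exact in uniform flow.  Brownian noise
enters through u_eff with a fresh Gaussian draw per step, which reproduces
Stokes-Einstein positional diffusion in the overdamped limit dt >> tau_p.

Each step ends with event handling: a sub-step segment that pierces the
lateral wall triggers the adhesion test and, on failure, the mixed
specular/diffuse reflection; crossing the outlet (or, during reverse flow,
the inlet) plane retires the particle with the corresponding status.  The
outlet cross-section is split by the configured carina plane into outlet-1
and outlet-2 sides, from which the homogeneity index is computed.

Outcome metrics mirror the study: SDM (adhered count per AAA lumen area),
MRT (mean residence time), MKE (time-averaged mean kinetic energy of active
MBs) and the homogeneity index (outlet-2 / outlet-1 exit counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import forces as F
from .adhesion import SDMField, try_adhere
from .config import RunConfig
from .microbubbles import (ACTIVE, ADHERED, EXITED_INLET, EXITED_OUTLET1,
                           EXITED_OUTLET2, PENDING, Cohort, make_cohort)
from .rheology import apparent_viscosity, shear_rate_magnitude, strain_rate_tensor
from .vasculature import build_idealized_aaa, lubrication_flow, make_waveform
from .walls import WallHit, mixed_reflect, surface_normal


def exponential_drag_update(x, v, u_eff, tau_p, dt):
    """Exact velocity-relaxation step for locally constant effective fluid
    velocity; returns (x_new, v_new).  ``tau_p`` broadcasts over particles."""
    tau = np.asarray(tau_p, dtype=float)
    if tau.ndim == 1:
        tau = tau[:, None]
    lam = np.exp(-dt / tau)
    dv = v - u_eff
    v_new = u_eff + dv * lam
    x_new = x + u_eff * dt + dv * tau * (1.0 - lam)
    return x_new, v_new


@dataclass
class RunMetrics:
    """Scalar outcomes of one run."""

    sdm_aaa: float                 # adhered MBs per AAA lumen area, 1/m^2
    mrt: float                     # mean residence time, s
    mrt_aaa: float                 # mean residence time inside the AAA region, s
    mke: float                     # time-averaged mean kinetic energy, J
    homogeneity_index: float | None  # outlet2/outlet1 exit counts
    ledger: dict[str, int]         # status counts; sums to injected total
    adhered_count: int

    def to_dict(self) -> dict:
        return {
            "sdm_aaa_per_m2": self.sdm_aaa,
            "mrt_s": self.mrt,
            "mrt_aaa_s": self.mrt_aaa,
            "mke_J": self.mke,
            "homogeneity_index": self.homogeneity_index,
            "ledger": self.ledger,
            "adhered_count": self.adhered_count,
        }


@dataclass
class RunResult:
    config: RunConfig
    metrics: RunMetrics
    sdm_field: SDMField
    cohort: Cohort
    events: list = dc_field(default_factory=list)
    trajectories: dict | None = None


class Simulation:
    """One seeded run: geometry, field, cohort and the stepping loop."""

    def __init__(self, config: RunConfig):
        self.config = config
        g = config.geometry
        self.geometry, self.mesh = build_idealized_aaa(
            inlet_area=g.inlet_area_mm2 * 1e-6,
            max_aneurysm_diameter=g.max_aneurysm_diameter_mm * 1e-3,
            bulge_center_fraction=g.bulge_center_fraction,
            bulge_width=g.bulge_width_m,
            length=g.length_m,
            n_z=g.mesh_n_z,
            n_theta=g.mesh_n_theta,
            carina_normal=g.carina_normal,
            aaa_tag_threshold=g.aaa_tag_threshold,
        )
        self.waveform = make_waveform(
            config.waveform.kind, config.waveform.peak_m_s,
            config.waveform.period_s)
        self.rheology = config.rheology_params()
        self.flow = lubrication_flow(self.geometry, self.waveform,
                                     self.rheology)
        self.fluid = config.fluid_properties()
        self.adhesion_params = config.adhesion_params()
        self.lj_params = config.lj_params()
        self.rng = np.random.default_rng(config.seed)
        self.cohort = make_cohort(
            config.mb_spec(), config.diameter_m(),
            config.injection_schedule(), self.geometry, self.flow, self.rng)
        self.sdm_field = SDMField(self.mesh)
        self.events: list[dict] = []
        self._mke_sum = 0.0
        self._mke_steps = 0
        self.trajectories: dict | None = None
        if config.output.trajectories:
            self.trajectories = {"t": [], "position": [], "status": []}

    # -- single step --------------------------------------------------------
    def step(self, t: float, dt: float) -> None:
        c = self.cohort
        cfg = self.config
        # injections fire at the onset of their interval
        newly = (c.status == PENDING) & (c.t_inject <= t + 1e-12)
        c.status[newly] = ACTIVE

        act = np.flatnonzero(c.status == ACTIVE)
        if len(act) == 0:
            return
        pos = c.position[act]
        vel = c.velocity[act]
        d = c.diameter[act]
        m = c.mass[act]

        u = self.flow.velocity(pos, t)
        grad = self.flow.velocity_gradient(pos, t)
        gdot = shear_rate_magnitude(strain_rate_tensor(grad))
        eta = apparent_viscosity(gdot, self.rheology)

        rho = self.fluid.density_rho
        re = F.relative_reynolds(u, vel, d, rho, eta)
        tau = F.relaxation_time(d, cfg.microbubble.density_kg_m3, eta, re)

        f_other = np.zeros_like(pos)
        if cfg.physics.lift:
            f_other += F.saffman_lift(u, vel, grad, d, rho, eta)
        if cfg.physics.gravity:
            f_other += F.gravity_force(m, cfg.microbubble.density_kg_m3, rho,
                                       self.fluid.gravity_vector_g)
        if cfg.physics.brownian:
            f_other += F.brownian_force(d, eta, self.fluid.temperature_T, dt,
                                        self.rng, kB=self.fluid.boltzmann_kB)
        if cfg.physics.interaction and len(act) > 1:
            f_other += F.lj_pair_forces(pos, d, self.lj_params)

        u_eff = u + tau[:, None] * f_other / m[:, None]
        x_new, v_new = exponential_drag_update(pos, vel, u_eff, tau, dt)
        if not np.all(np.isfinite(x_new)):
            bad = act[~np.all(np.isfinite(x_new), axis=1)]
            raise FloatingPointError(
                f"non-finite particle state at t={t:.6g}s, ids {bad[:5]}")

        # residence bookkeeping uses the start-of-step axial position
        z_lo, z_hi = self.geometry.aaa_interval
        in_aaa = (pos[:, 2] >= z_lo) & (pos[:, 2] <= z_hi)
        c.aaa_time[act[in_aaa]] += dt

        # event detection on the sub-step segments
        r_new = np.hypot(x_new[:, 0], x_new[:, 1])
        z_new = x_new[:, 2]
        length = self.geometry.domain_length
        flagged = np.flatnonzero(
            (r_new > self.geometry.radius(z_new))
            | (z_new < 0.0) | (z_new > length))
        for k in flagged:
            self._handle_event(act[k], pos[k], x_new[k], v_new[k], t, dt)
        ok = np.ones(len(act), dtype=bool)
        ok[flagged] = False
        c.position[act[ok]] = x_new[ok]
        c.velocity[act[ok]] = v_new[ok]

        # kinetic-energy accumulator (active particles after the step)
        still = c.status == ACTIVE
        if np.any(still):
            ke = 0.5 * c.mass[still] * np.sum(c.velocity[still] ** 2, axis=1)
            self._mke_sum += float(np.mean(ke))
            self._mke_steps += 1

    def _handle_event(self, pid: int, x0, x1, v1, t: float, dt: float) -> None:
        """Resolve the first boundary event on one particle's sub-step."""
        c = self.cohort
        geom = self.geometry
        seg = x1 - x0
        candidates: list[tuple[float, str]] = []
        if x1[2] > geom.domain_length and seg[2] != 0.0:
            candidates.append(((geom.domain_length - x0[2]) / seg[2], "outlet"))
        if x1[2] < 0.0 and seg[2] != 0.0:
            candidates.append((-x0[2] / seg[2], "inlet"))

        # lateral wall: first radius crossing, if any
        def radial_excess(s):
            p = x0 + s * seg
            return float(np.hypot(p[0], p[1]) - geom.radius(p[2]))

        s_wall = None
        if radial_excess(1.0) > 0.0 and radial_excess(0.0) < 0.0:
            from scipy.optimize import brentq
            s_wall = brentq(radial_excess, 0.0, 1.0, xtol=1e-15)
            candidates.append((s_wall, "wall"))
        elif radial_excess(0.0) >= 0.0:
            # started on/outside the wall surface (post-reflection corner);
            # nudge back inside along the inward normal
            n = surface_normal(x0, geom)
            c.position[pid] = x0 - 2.0 * self.config.physics.epsilon_wall_m * n
            c.velocity[pid] = v1
            return

        if not candidates:
            # grazing numerical case: keep the particle, clamp inside
            c.position[pid] = x0
            c.velocity[pid] = v1
            return
        s_evt, kind = min(candidates, key=lambda sk: sk[0])
        s_evt = min(max(s_evt, 0.0), 1.0)
        point = x0 + s_evt * seg
        t_evt = t + s_evt * dt

        if kind == "outlet" or kind == "inlet":
            if kind == "outlet":
                side = float(np.dot(point - [0.0, 0.0, geom.domain_length],
                                    geom.carina_normal))
                status = EXITED_OUTLET2 if side >= 0.0 else EXITED_OUTLET1
            else:
                status = EXITED_INLET
            c.status[pid] = status
            c.position[pid] = point
            c.velocity[pid] = v1
            c.t_final[pid] = t_evt
            if self.config.output.events:
                self.events.append({"particle": int(pid), "type": kind,
                                    "t": t_evt, "x": point[0], "y": point[1],
                                    "z": point[2], "element": -1})
            return

        # lateral wall: adhesion test first, then reflection
        normal = surface_normal(point, geom)
        elem = self.mesh.locate_lateral(point)
        hit = WallHit(particle_id=pid, point=point, element_id=elem,
                      normal=normal, velocity=v1, time=t_evt)
        if self.config.adhesion.enabled and try_adhere(
                hit, self.flow, self.adhesion_params, self.rng, self.cohort):
            self.sdm_field.accumulate(elem)
            if self.config.output.events:
                self.events.append({"particle": int(pid), "type": "adhered",
                                    "t": t_evt, "x": point[0], "y": point[1],
                                    "z": point[2], "element": int(elem)})
            return
        v_out = mixed_reflect(hit, self.config.physics.gamma_specular,
                              self.rng)
        eps = self.config.physics.epsilon_wall_m
        c.position[pid] = point - eps * normal
        c.velocity[pid] = v_out
        if self.config.output.events:
            self.events.append({"particle": int(pid), "type": "reflected",
                                "t": t_evt, "x": point[0], "y": point[1],
                                "z": point[2], "element": int(elem)})

    # -- full run -----------------------------------------------------------
    def run(self) -> RunResult:
        dt = self.config.numerics.dt_s
        n_steps = int(round(self.config.numerics.t_end_s / dt))
        stride = self.config.output.trajectory_stride
        for k in range(n_steps):
            t = k * dt
            self.step(t, dt)
            if self.trajectories is not None and k % stride == 0:
                self.trajectories["t"].append(t + dt)
                self.trajectories["position"].append(
                    self.cohort.position.copy())
                self.trajectories["status"].append(self.cohort.status.copy())
        metrics = compute_metrics(
            self.cohort, self.sdm_field, self.config.numerics.t_end_s,
            mke=(self._mke_sum / self._mke_steps) if self._mke_steps else 0.0)
        return RunResult(config=self.config, metrics=metrics,
                         sdm_field=self.sdm_field, cohort=self.cohort,
                         events=self.events, trajectories=self.trajectories)


def compute_metrics(cohort: Cohort, sdm_field: SDMField, t_end: float,
                    mke: float) -> RunMetrics:
    """Aggregate run outcomes; still-active particles contribute
    t_end - t_inject to the residence time."""
    t_final = np.where(np.isnan(cohort.t_final), t_end, cohort.t_final)
    mrt = float(np.mean(t_final - cohort.t_inject))
    mrt_aaa = float(np.mean(cohort.aaa_time))
    ledger = cohort.status_counts()
    n1 = ledger["exited_outlet1"]
    n2 = ledger["exited_outlet2"]
    homogeneity = (n2 / n1) if n1 > 0 else None
    return RunMetrics(
        sdm_aaa=sdm_field.summary("aaa"),
        mrt=mrt,
        mrt_aaa=mrt_aaa,
        mke=mke,
        homogeneity_index=homogeneity,
        ledger=ledger,
        adhered_count=ledger["adhered"],
    )


def run(config: RunConfig) -> RunResult:
    """Execute one run; writes outputs when the config names a directory."""
    result = Simulation(config).run()
    if config.output.directory is not None:
        from .io import write_outputs
        write_outputs(result, config.output.directory)
    return result


def ablate(config: RunConfig, toggles=("lift", "brownian", "gravity",
                                       "interaction")) -> dict:
    """Force-ablation harness: rerun with each physics toggle disabled and
    report the percent change of every scalar metric versus baseline.

    The percentages depend on geometry and flow; they are diagnostics of this
    synthetic domain, not reference values.
    """
    base = run(config).metrics
    out = {"baseline": base.to_dict()}
    for name in toggles:
        mod = config.model_copy(deep=True)
        setattr(mod.physics, name, False)
        m = run(mod).metrics
        entry = m.to_dict()
        entry["pct_change_sdm_aaa"] = (
            100.0 * (m.sdm_aaa - base.sdm_aaa) / base.sdm_aaa
            if base.sdm_aaa > 0.0 else 0.0)
        entry["pct_change_mrt"] = (
            100.0 * (m.mrt - base.mrt) / base.mrt if base.mrt > 0.0 else 0.0)
        entry["pct_change_adhered"] = (
            100.0 * (m.adhered_count - base.adhered_count)
            / base.adhered_count if base.adhered_count > 0 else 0.0)
        out[f"no_{name}"] = entry
    return out


def sweep(config: RunConfig, mb_names=None, diameters=("min", "mid", "max"),
          hct_percents=(45,), waveform_kinds=("negative",)):
    """Grid sweep over MB type x diameter x hematocrit x waveform.

    Returns a tidy pandas DataFrame with one row of metrics per cell,
    mirroring the study's comparison designs at synthetic-geometry scale.
    """
    import pandas as pd

    from .microbubbles import builtin_specs

    names = list(mb_names) if mb_names is not None else list(builtin_specs())
    rows = []
    for name in names:
        for dia in diameters:
            for hct in hct_percents:
                for kind in waveform_kinds:
                    mod = config.model_copy(deep=True)
                    mod.microbubble.name = name
                    mod.microbubble.diameter_um = dia
                    mod.rheology.hct_percent = hct
                    mod.waveform.kind = kind
                    res = run(mod)
                    row = {"microbubble": name, "diameter_um":
                           res.config.diameter_m() * 1e6, "hct_percent": hct,
                           "waveform": kind}
                    md = res.metrics.to_dict()
                    md.pop("ledger")
                    row.update(md)
                    rows.append(row)
    return pd.DataFrame(rows)
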