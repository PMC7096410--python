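# Methods

`mbtrack` simulates targeted drug delivery by ultrasound-contrast
microbubbles (MBs) in an abdominal aortic aneurysm (AAA): Lagrangian
transport of injected MBs through pulsatile, shear-thinning blood flow,
collision with the vessel wall, and ligand-receptor adhesion accumulated as
a surface density on the aneurysm lumen. This note records the model, its
assumptions, the defaults and why they were chosen, and what the synthetic
domain can and cannot say about real patients.

## Blood rheology

Blood is a generalized Newtonian fluid with Carreau-Yasuda apparent
viscosity

    eta(gdot) = eta_inf + (eta_0 - eta_inf) [1 + (lambda gdot)^2]^((a-1)/2),

parameterized per hematocrit: 25% (eta_0 = 0.0178 Pa s, lambda = 12.448 s,
a = 0.330, eta_inf = 0.00257 Pa s), 45% (0.1613, 9.418, 0.479, 0.00345) and
65% (0.8592, 103.088, 0.389, 0.00802). The scalar shear rate fed into this
law is the second-invariant reduction gdot = sqrt(2 S:S) of the deviatoric
strain-rate tensor, calibrated so simple shear at rate g returns exactly g.
There is no temperature dependence. The blood mass density is not fixed by
the rheology tables; the default is 1050 kg/m^3 (typical whole blood) and it
is a config field.

The wall material model W = C10 (I1 - 3) + C20 (I1 - 3)^2 + (J - 1)^2 / d
(C10 = 0.174 MPa, C20 = 1.881 MPa, d = 1.149) is provided as a pointwise
strain-energy evaluator only; there is no structural solve and the wall does
not move.

## Synthetic vascular domain

The patient-specific geometry behind the original study (CT-derived, with a
distal bifurcation) is not public, so the package ships a synthetic
axisymmetric stand-in dimensioned from the published measurements: inlet
lumen area 377.4 mm^2 (radius R0 = 10.96 mm) and maximum aneurysm diameter
40 mm. The radius profile is a Gaussian bulge

    R(z) = R0 + (R_a - R0) exp(-((z - z_c)/w_b)^2)

on a 120 mm segment with z_c = 60 mm and w_b = 20 mm (defaults chosen to
give a fusiform aneurysm of realistic ~60-70 mm length). The "AAA region"
is the axial interval where R exceeds R0 by 5% (configurable). The distal
bifurcation is not modeled geometrically; instead a configured carina plane
splits the outlet cross-section into outlet-1 and outlet-2 sides, which is
sufficient to define the homogeneity index. Real bifurcated geometry enters
only through imported fields.

The inlet waveform is a truncated sum-of-Gaussians physiological pulse
(systolic lobe at 0.20 T with width 0.055 T and unit amplitude, retrograde
lobe at 0.47 T, width 0.06 T, amplitude -0.40, diastolic hump at 0.78 T,
width 0.12 T, amplitude 0.12; period T = 1 s), rescaled so the maximum
equals the configured peak exactly. The study peaks are 0.44 m/s for the
"negative" (retrograde-lobe) waveform and 0.30 m/s for the clamped
non-negative variant; the non-negative kind is by construction the negative
template clamped at zero and rescaled to its own peak.

The flow field is a lubrication-theory approximation: a locally parabolic
axial profile rescaled by continuity,

    u_z(r, z, t) = 2 v_in(t) (R0/R(z))^2 (1 - (r/R(z))^2),

with the radial component obtained by integrating incompressibility
exactly, so div(u) = 0 analytically, the wall is exactly no-slip, and
volumetric flux pi R0^2 v_in(t) is identical through every cross-section.
Wall shear rate is 4 |v_in| R0^2 / R^3 and wall shear stress is
eta(gdot_w) gdot_w. Pressure is identically zero in the analytic field;
traction with pressure is exercised on explicit inputs or imported fields.

What this field deliberately does not have: recirculating vortices, flow
separation, chaotic mixing, or any fluid-structure interaction. In a real
AAA those vortices are the dominant mechanism carrying MBs across
streamlines to the wall. Consequences for interpretation are discussed
under "Limitations" below.

Externally computed fields (legacy-VTK ASCII snapshots of nodal velocities,
two or more frames) can replace the analytic field. Interpolation is
barycentric over a Delaunay triangulation of the nodes with linear
interpolation in time; the velocity gradient is the per-simplex linear
reconstruction. Because the nodes are re-triangulated, a strongly
non-convex lumen is covered by its convex hull; the intended use is
near-convex segments like the one modeled here.

## Microbubbles and injection protocol

Four commercial formulations are built in (diameter ranges in um): Definity
1.1-3.3, Micromarker 2.0-5.0, Optison 3.0-4.5, Sonovue 1.5-2.5, all with
density 1000 kg/m^3. Shell surface tension, viscosity and elasticity are
stored as metadata only: they govern acoustic response, which is out of
scope (no ultrasound, no bursting, no acoustic radiation force). A run is
monodisperse (min/mid/max of the range, or an explicit diameter).

The default protocol injects 500 MBs at the onset of each of four
one-second cardiac cycles (t = 0, 1, 2, 3 s; 2000 total), seeded uniformly
over the area of the inlet disc with initial velocity equal to the local
fluid velocity at release. Uniform-over-area seeding is the natural reading
of "entered randomly"; the seeding annulus is configurable (fractions of
the local lumen radius at the seeding plane), which the wall-collision
scenarios use to place particles within a few micrometres of the wall.
The initial-velocity choice is inconsequential: the drag relaxation time
(~1e-7 s) erases any initial slip within a single step. No pre-roll ramp is
applied; the waveform starts at t = 0.

## Forces

Newton's second law per MB sums drag, Saffman-type lift, Brownian noise,
buoyancy-corrected gravity and a Lennard-Jones MB-MB interaction.

* **Drag**: F_D = (m_p / tau_p)(u - v) with
  tau_p = 4 rho_p d_p^2 / (3 eta C_D Re_r). C_D follows the standard
  piecewise sphere correlation in three Reynolds-number branches
  (<= 0.01, 0.01-20, 20-260); the middle branch's exponent
  0.82 - 0.05 w uses w = log10(Re_r), a choice validated by branch
  continuity (< 0.003% and < 0.8% relative mismatch at Re = 0.01 and 20).
  The code always evaluates the product C_D Re_r, which is finite and tends
  to the Stokes value 24 at zero slip; above Re = 260 the top branch is
  extrapolated with a warning.
* **Lift**: F_L = -20.3 d_p^2 L_v sqrt(eta rho |u - v| / |L_v|), with
  L_v = (u - v) x curl(u - v), implemented verbatim from the source
  correlation. Note the sign: in simple shear this form pushes a lagging
  particle down the velocity gradient, opposite to the classical Saffman
  result, and the prefactor 20.3 is not the classical 1.61-based constant.
  The package reproduces the printed form rather than "correcting" it, and
  documents the discrepancy here; the force is orders of magnitude below
  drag in all regimes exercised.
* **Brownian**: each component zeta sqrt(6 pi k_B eta T d_p / dt) with
  standard-normal zeta drawn fresh every step. Combined with the
  exponential drag update below, the overdamped displacement per step is
  exactly N(0, 2 D dt) with D = k_B T / (3 pi eta d_p), so Stokes-Einstein
  positional diffusion is reproduced without tuning (verified to ~1% over
  1e4 steps in the suite).
* **Gravity/buoyancy**: F_G = m_p g (rho_p - rho)/rho_p along -y (supine
  patient). MBs are lighter than blood, so the net force opposes g: bubbles
  rise, which *reduces* deposition on the lower wall.
* **MB-MB interaction**: pairwise Lennard-Jones force with
  epsilon = 8.2e-22 J and per-particle sigma = 0.89 d_p (placing the
  potential minimum r_m = 2^(1/6) sigma at contact for rigid-surface MBs);
  pair sigma is the mean of the two particles'. The default cutoff is
  5 sigma — a printed cutoff of 55 mm exceeds the aneurysm diameter and is
  treated as a typo, but remains configurable. Neighbor search uses a
  k-d tree; an all-pairs implementation is retained as the test oracle.
  Forces are pairwise antisymmetric, so momentum is conserved exactly;
  overlapping particles are softened below 1e-3 sigma with a warning.

## Time integration

With tau_p ~ 1e-8 - 1e-7 s and dt = 1e-3 s, any explicit scheme diverges.
The integrator is the exact relaxation (exponential) update for locally
constant effective fluid velocity u_eff = u + tau_p F_other / m_p:

    v+ = u_eff + (v - u_eff) exp(-dt/tau_p)
    x+ = x + u_eff dt + (v - u_eff) tau_p (1 - exp(-dt/tau_p)).

It is unconditionally stable, exact in uniform flow (machine precision in
the suite) and first-order accurate in spatially varying flow, which the
convergence test confirms (observed order >= 1 against a small-dt
reference). Default dt = 1 ms, t_end = 4 s.

One seeded numpy Generator drives the whole run, with draws made in fixed
particle-index order (vectorized Brownian draws for all active particles,
then per-event draws in ascending particle id). Two runs with the same
config and seed are byte-identical down to the output files. Per-particle
substreams were considered and rejected: at fixed processing order they
change nothing observable and cost generator setup per particle.

## Wall interaction and adhesion

A sub-step segment that pierces the lateral wall is intersected with the
surface of revolution by bisection (not with the triangle mesh — the
analytic surface is exact; the mesh supplies the surface *elements* for
accounting). The adhesion test runs first; only if it fails is the MB
reflected. Reflection is specular (v' = v - 2 (n.v) n) with probability
gamma = 0.5 and otherwise diffuse by Knudsen's cosine law: polar angle
theta = asin(sqrt(U)), azimuth uniform, speed preserved, re-emitted about
the inward normal. The printed form of the diffuse normal component
(|v| sin theta) would not preserve speed and contradicts the stated
cos-theta distribution; the implementation uses |v| cos theta, the standard
cosine-law re-emission. The tangent basis is completed deterministically
(Gram-Schmidt against the smallest-normal-component axis) so seeded runs
are reproducible; phi-uniformity makes the choice physically immaterial.
After reflection the MB is placed epsilon_wall = 1 um inside the wall and
the remainder of the step is dropped (events are rare at dt = 1 ms).
Crossing the outlet plane retires the particle as exited-outlet-1/2 by the
carina-plane side; during reverse flow a particle can also leave through
the inlet plane, recorded as a separate exited-inlet status so the count
ledger stays exact.

Adhesion follows the Decuzzi-Ferrari closed form: probability of at least
one ligand-receptor bond

    P_a = pi r0^2 m_r m_l Ka0
          exp[-beta d_p (eta S) / (k_B T r0^2 m_r)
              (3 (d_p/2 + delta_eq) F_s + (d_p^2/r0) T_s)],

capped at 1, with contact-annulus radius
r0^2 = d_p^2 [1/4 - (1/2 - (h0 - delta_eq)/d_p)^2] clipped at zero. The
P-selectin aptamer constants are k_f0 = 2.33e5 1/s, k_r0 = 3.4e-5 1/s,
delta_eq = 50 nm, beta = 0.21 A, m_r = 2.7e15 1/m^2, T = 310.15 K,
F_s = 1.668, T_s = 0.944; the wall shear stress eta S comes from the flow
field at the hit point and time. Three quantities the published constants
do not fix are declared free parameters with defaults recorded in every
run's metadata:

* ligand surface density m_l (default 1e15 1/m^2, same order as m_r);
* the bond-patch area A_bond converting the kinetic-rate ratio into the
  area-dimensioned association constant Ka0 = (k_f0/k_r0) A_bond (default
  8.822e-29 m^2, normalized once so the zero-shear P_a is ~0.5 at
  d_p = 2 um);
* the maximum bond-formation distance h0 (default 100 nm = 2 delta_eq).

With these defaults the exponential load factor is weak at physiological
wall stresses (the argument is ~1e-3 at 1 Pa for d_p = 2 um), so P_a is
dominated by the geometric prefactor; the strict monotone decrease in shear
holds everywhere the cap at 1 is inactive. The separation distance of the
underlying force/torque expressions is absorbed into the printed form and
is not an independent input. Bond rupture after adhesion, rolling, and
multivalent bond counting are not modeled: adhesion is permanent.

Each adhesion increments the hit element's counter; the element's SDM is
count/area and the scalar study outcome "SDM" is the region summary over
the aaa-tagged lumen (total count / total region area, 1/m^2).

## Outcome metrics

* **SDM**: adhered count per AAA lumen area (also exported per element).
* **MRT**: mean over all injected MBs of t_final - t_inject, where t_final
  is adhesion or exit time, or t_end for still-active MBs (the protocol
  does not define a window for survivors; counting them to t_end is the
  conservative choice). A second variant, mrt_aaa, accumulates only time
  spent inside the AAA axial interval.
* **MKE**: time average over steps of the mean 1/2 m |v|^2 over active MBs
  (the averaging window — the whole run — is a package choice; the metric's
  original definition leaves it open).
* **Homogeneity index**: exited-outlet-2 count / exited-outlet-1 count,
  reported as undefined (null) when no MB exits outlet 1.
* **Ledger**: counts by status; injected = active + adhered + exits holds
  exactly at every step.

## Verification strategy and problem sizes

The suite pins every closed-form value to an independent hand evaluation
(viscosity plateaus and mid-range values, drag branches, relaxation times,
Brownian amplitude, LJ force at r = sigma, strain-energy values, adhesion
exponent roots), checks distributional laws with seeded Monte Carlo
(cosine-law KS test at 1e5 draws, binomial checks of gamma mixing and
Bernoulli adhesion at 1e4 trials, Stokes-Einstein MSD at 800-1000 particles
x 1e4 steps), and exercises the full protocol (2000 MBs, 4 s, dt = 1 ms,
~8 s wall time) for conservation and byte-level determinism. Wall-collision
physics is integration-tested with cohorts seeded 0.2-2 um from the wall,
where diffusion-limited deposition actually occurs. These sizes were chosen
as the smallest that make the statistical tolerances (10% on MSD, KS
p > 0.01, +/-0.02 on binomial fractions) comfortably non-flaky.

## Limitations

* The analytic field is laminar and streamline-smooth. Drag dominance means
  free-stream MBs follow streamlines almost exactly, so with the default
  inlet seeding essentially no MB reaches the wall within four seconds and
  the default-protocol SDM is ~0. This is a faithful property of the
  stand-in flow, not of AAAs: patient-specific vortices are the
  wall-transport mechanism, and the published patient-specific SDM values
  (and force-ablation percentages) are therefore out of reach at desk scale
  by design. The adhesion pathway is validated with near-wall seeding and
  imported fields instead.
* Passing tests demonstrate correctness of the force models, wall rules,
  adhesion law, bookkeeping and determinism — not predictive accuracy for
  any patient.
* One-way coupling only: MBs do not perturb the flow. No wall motion, no
  acoustics, no drug-release kinetics, no MB deformation or polydispersity.
* The retrograde-flow comparison (longer aneurysm residence under the
  negative waveform) is directional; at equal peak the negative waveform
  carries ~12% less mean flux, which is part of the effect being measured,
  exactly as with the published 44 vs 30 cm/s pairing.
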