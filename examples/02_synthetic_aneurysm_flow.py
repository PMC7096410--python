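"""The synthetic aneurysm domain and its pulsatile flow field.

Builds the idealized axisymmetric abdominal-aortic-aneurysm geometry
(inlet lumen area 377.4 mm^2, maximum aneurysm diameter 40 mm), a
physiological inlet waveform with a retrograde lobe, and the analytic
divergence-free lubrication flow; prints flux conservation and wall shear
stress along the vessel.
"""

import numpy as np

from mbtrack import (HCT_PRESETS, build_idealized_aaa, lubrication_flow,
                     make_waveform)

geom, mesh = build_idealized_aaa()
wf = make_waveform("negative", peak=0.44, period=1.0)
flow = lubrication_flow(geom, wf, HCT_PRESETS[45])

print(f"inlet radius R0        : {1e3 * geom.inlet_radius_R0:.2f} mm")
print(f"max aneurysm radius    : {1e3 * geom.bulge_max_radius_Ra:.2f} mm")
z_lo, z_hi = geom.aaa_interval
print(f"aneurysm region        : z in [{1e3 * z_lo:.1f}, {1e3 * z_hi:.1f}] mm")
print(f"boundary mesh          : {mesh.n_elements} triangles, "
      f"AAA lumen area {1e4 * mesh.region_area('aaa'):.1f} cm^2")
print(f"waveform peak / trough : {wf.peak:.2f} / {wf.min_over_period:.2f} m/s")

t = 0.2  # near peak systole
print(f"\nat t = {t} s (inlet mean velocity {wf(t):.3f} m/s):")
print(f"{'z [mm]':>8}{'R(z) [mm]':>11}{'flux [ml/s]':>13}"
      f"{'wall shear [Pa]':>17}")
for z in (0.01, 0.04, 0.06, 0.08, 0.11):
    print(f"{1e3 * z:8.0f}{1e3 * geom.radius(z):11.2f}"
          f"{1e6 * flow.flux(z, t):13.2f}"
          f"{flow.wall_shear_stress([0, 0, z], t):17.4f}")

print()
print("Flux is identical through every cross-section (the field is exactly")
print("divergence-free); wall shear stress collapses inside the bulge --")
print("R^-3 scaling -- which is precisely where adhesion is most favorable.")
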