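"""Synthetic AAA domain tests: geometry, boundary mesh, inlet waveform, the
analytic lubrication flow field and its invariants."""

import numpy as np
import pytest

from mbtrack.rheology import HCT_PRESETS
from mbtrack.vasculature import (build_idealized_aaa, lubrication_flow,
                                 make_waveform, revolution_surface_area,
                                 vorticity)


class TestGeometry:
    def test_default_dimensions(self, geometry):
        # R0 = sqrt(A/pi) for A = 377.4 mm^2; R_a = 20 mm
        assert geometry.inlet_radius_R0 == pytest.approx(
            np.sqrt(377.4e-6 / np.pi), rel=1e-12)
        assert geometry.bulge_max_radius_Ra == pytest.approx(20e-3)

    def test_radius_profile_limits(self, geometry):
        r0 = geometry.inlet_radius_R0
        assert geometry.radius(0.0) == pytest.approx(r0, rel=1e-3)
        assert geometry.radius(geometry.domain_length) == pytest.approx(
            r0, rel=1e-3)
        zz = np.linspace(0, geometry.domain_length, 2001)
        assert np.max(geometry.radius(zz)) == pytest.approx(
            geometry.bulge_max_radius_Ra, rel=1e-6)
        assert np.all(geometry.radius(zz) >= r0 * (1 - 1e-12))

    def test_degenerate_bulge_rejected(self):
        with pytest.raises(ValueError):
            build_idealized_aaa(max_aneurysm_diameter=2 * np.sqrt(
                377.4e-6 / np.pi))

    def test_containment_predicate(self, geometry):
        assert geometry.inside([0.0, 0.0, 0.06])
        assert not geometry.inside([0.0, 0.03, 0.06])
        assert not geometry.inside([0.0, 0.0, -0.01])


class TestBoundaryMesh:
    def test_areas_positive_normals_unit(self, mesh):
        assert np.all(mesh.areas > 0.0)
        assert np.allclose(np.linalg.norm(mesh.normals, axis=1), 1.0)

    def test_lateral_area_close_to_analytic(self, geometry, mesh):
        lateral = (mesh.tags == "aaa") | (mesh.tags == "non_aaa")
        mesh_area = mesh.areas[lateral].sum()
        exact = revolution_surface_area(geometry)
        assert mesh_area == pytest.approx(exact, rel=0.02)

    def test_area_convergence_with_resolution(self, geometry):
        errs = []
        for n in (10, 20, 40):
            _, m = build_idealized_aaa(n_z=n, n_theta=n)
            lateral = (m.tags == "aaa") | (m.tags == "non_aaa")
            errs.append(abs(m.areas[lateral].sum()
                            - revolution_surface_area(geometry)))
        order = np.log2(errs[0] / errs[2]) / 2.0
        assert order >= 1.0

    def test_aaa_region_has_area(self, mesh):
        assert mesh.region_area("aaa") > 0.0

    def test_locate_lateral_roundtrip(self, geometry, mesh, rng):
        # points on the surface map to elements whose centroid is nearby
        for _ in range(20):
            z = rng.uniform(0.01, 0.11)
            th = rng.uniform(0, 2 * np.pi)
            r = geometry.radius(z)
            p = np.array([r * np.cos(th), r * np.sin(th), z])
            eid = mesh.locate_lateral(p)
            assert np.linalg.norm(mesh.centroids[eid] - p) < 5e-3


class TestWaveform:
    def test_negative_kind_peak_and_sign(self):
        wf = make_waveform("negative", 0.44, 1.0)
        tt = np.linspace(0, 1, 20000, endpoint=False)
        assert np.max(wf(tt)) == pytest.approx(0.44, abs=1e-9)
        assert wf.min_over_period < 0.0

    def test_non_negative_kind(self):
        wf = make_waveform("non_negative", 0.30, 1.0)
        tt = np.linspace(0, 1, 20000, endpoint=False)
        assert np.min(wf(tt)) == 0.0
        assert np.max(wf(tt)) == pytest.approx(0.30, abs=1e-9)

    def test_periodicity(self, rng):
        wf = make_waveform("negative", 0.44, 1.0)
        t = rng.uniform(0, 1, 50)
        assert np.allclose(wf(t), wf(t + 1.0))
        assert np.allclose(wf(t), wf(t + 7.0))

    def test_non_negative_is_clamped_negative_rescaled(self):
        neg = make_waveform("negative", 1.0, 1.0)
        nn = make_waveform("non_negative", 1.0, 1.0)
        tt = np.linspace(0, 1, 512, endpoint=False)
        assert np.allclose(nn(tt), np.clip(neg(tt), 0.0, None), atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_waveform("sinusoid", 0.3, 1.0)


class TestLubricationFlow:
    def test_centerline_velocity_is_twice_inlet_mean(self, flow, neg_waveform):
        for t in (0.1, 0.2, 0.6):
            u = flow.velocity(np.array([0.0, 0.0, 1e-6]), t)
            assert u[2] == pytest.approx(2.0 * neg_waveform(t), rel=1e-3)

    def test_flux_is_z_independent(self, flow, geometry):
        t = 0.2
        target = flow.flux(0.0, t)
        for z in (0.01, 0.04, 0.06, 0.09, 0.115):
            r_edge = geometry.radius(z)
            rr = np.linspace(0.0, r_edge, 4000)
            pts = np.column_stack([rr, np.zeros_like(rr), np.full_like(rr, z)])
            uz = flow.velocity(pts, t)[:, 2]
            flux = np.trapezoid(2 * np.pi * rr * uz, rr)
            assert flux == pytest.approx(target, rel=1e-6)

    def test_no_slip_on_wall(self, flow, geometry):
        zz = np.linspace(1e-3, geometry.domain_length - 1e-3, 100)
        pts = np.column_stack([geometry.radius(zz), np.zeros_like(zz), zz])
        speed = np.linalg.norm(flow.velocity(pts, 0.2), axis=1)
        assert np.max(speed) < 1e-10 * 0.44

    def test_divergence_free_numerically(self, flow, geometry, rng):
        z = rng.uniform(0.005, 0.115, 1000)
        frac = np.sqrt(rng.uniform(0, 1, 1000)) * 0.995
        th = rng.uniform(0, 2 * np.pi, 1000)
        r = frac * geometry.radius(z)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        h = 1e-7
        div = np.zeros(len(pts))
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            div += (flow.velocity(pts + e, 0.2)[:, i]
                    - flow.velocity(pts - e, 0.2)[:, i]) / (2 * h)
        assert np.abs(div).max() < 1e-6 * (0.44 / geometry.inlet_radius_R0)

    def test_gradient_matches_finite_differences(self, flow, rng):
        pts = np.array([[0.002, -0.003, 0.05], [0.0, 0.0, 0.06],
                        [0.008, 0.001, 0.03]])
        g = flow.velocity_gradient(pts, 0.3)
        h = 1e-7
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            fd = (flow.velocity(pts + e, 0.3) - flow.velocity(pts - e, 0.3)) \
                / (2 * h)
            assert np.allclose(g[:, :, j], fd, atol=1e-5 * 200)

    def test_wall_shear_rate_formula(self, flow, geometry, neg_waveform):
        z, t = 0.02, 0.2
        expected = 4 * abs(neg_waveform(t)) * geometry.inlet_radius_R0**2 \
            / geometry.radius(z)**3
        assert flow.wall_shear_rate(z, t) == pytest.approx(expected)

    def test_outside_query_flagged(self, flow):
        assert not flow.inside([0.0, 0.05, 0.06])


class TestVorticity:
    def test_uniform_flow_zero(self):
        class Uniform:
            def velocity_gradient(self, x, t):
                return np.zeros((3, 3))

            def inside(self, x):
                return True

        assert np.allclose(vorticity(Uniform(), np.zeros(3), 0.0), 0.0)

    def test_rigid_rotation(self):
        w = 3.0

        class Rigid:
            def velocity_gradient(self, x, t):
                g = np.zeros((3, 3))
                g[0, 1] = -w
                g[1, 0] = w
                return g

            def inside(self, x):
                return True

        assert np.allclose(vorticity(Rigid(), np.zeros(3), 0.0),
                           [0.0, 0.0, 2 * w])

    def test_wall_adjacent_magnitude_matches_shear_rate(self, flow, geometry):
        z, t = 0.03, 0.2
        r = geometry.radius(z) * 0.999
        p = np.array([r, 0.0, z])
        mag = np.linalg.norm(vorticity(flow, p, t))
        assert mag == pytest.approx(flow.wall_shear_rate(z, t), rel=0.05)

    def test_outside_point_rejected(self, flow):
        with pytest.raises(ValueError):
            vorticity(flow, np.array([0.0, 0.05, 0.06]), 0.0)
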