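"""Mooney-Rivlin hyperelastic solver: material law, boundary conditions,
pressure calibration and dynamics."""

import numpy as np
import pytest

from lungmech import fem, geometry as geo


class TestMaterial:
    def test_derived_constants(self):
        m = fem.make_material(3000.0, nu=0.2)
        assert np.isclose(m.c1, 750.0)
        assert np.isclose(m.c2, 750.0)
        assert np.isclose(m.kappa, 4000.0)

    def test_quarter_shear_modulus(self):
        m = fem.make_material(1000.0, nu=0.3)
        assert np.isclose(m.c1, 250.0)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            fem.make_material(1000.0, nu=0.5)

    def test_reference_state_stress_free(self, ball_mesh):
        model = geo.uniform_model(ball_mesh, 3000.0)
        state = fem.evaluate_state(model, fem.make_material(3000.0, 0.2),
                                   np.zeros((ball_mesh.n_nodes, 3)))
        assert np.abs(state["W"]).max() < 1e-12
        assert np.abs(state["S"]).max() < 1e-12

    def test_objectivity_under_rotation(self, ball_mesh):
        model = geo.uniform_model(ball_mesh, 3000.0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        u = ball_mesh.nodes @ (R.T - np.eye(3))
        state = fem.evaluate_state(model, fem.make_material(3000.0, 0.2), u)
        assert np.abs(state["W"]).max() < 1e-8
        assert np.abs(state["S"]).max() < 1e-6


class TestSpringFoundation:
    def test_stated_constants(self):
        s = fem.make_spring_foundation(8e5, 0.4, 0.1)
        assert np.isclose(s.kn, 1.7142857e7, rtol=1e-5)
        assert np.isclose(s.ks, 2.8571429e6, rtol=1e-5)

    def test_zero_poisson_limit(self):
        s = fem.make_spring_foundation(1000.0, 0.0, 0.5)
        assert np.isclose(s.kn, 1000.0 / 0.5)
        assert np.isclose(s.ks, 1000.0 / (2 * 0.5))

    def test_normal_at_least_tangential(self):
        s = fem.make_spring_foundation(8e5, 0.3, 0.1)
        assert s.kn >= s.ks

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            fem.make_spring_foundation(8e5, 0.5, 0.1)


class TestInflation:
    def test_unloaded_state(self, ball_mesh, sphere_options):
        model = geo.uniform_model(ball_mesh, 3000.0)
        res = fem.solve_inflation(model, fem.make_material(3000.0, 0.2),
                                  None, fem.LoadSpec(0.0),
                                  options=sphere_options)
        assert np.abs(res.displacements[-1]).max() == 0.0
        assert np.isclose(res.volume_ratio[-1], 1.0)

    def test_hydrostatic_sphere_limit(self, ball_mesh, sphere_options):
        # uniform surface tension p << kappa: J - 1 = p / kappa
        model = geo.uniform_model(ball_mesh, 3000.0)
        mat = fem.make_material(3000.0, 0.2)  # kappa = 4 kPa
        res = fem.solve_inflation(model, mat, None, fem.LoadSpec(40.0),
                                  options=sphere_options)
        expect = 1.0 + 40.0 / 4000.0
        assert abs(res.volume_ratio[-1] - expect) / (expect - 1) < 0.05

    def test_small_strain_linearity(self, ball_mesh, sphere_options):
        model = geo.uniform_model(ball_mesh, 3000.0)
        r1 = fem.solve_inflation(model, fem.make_material(3000.0, 0.2),
                                 None, fem.LoadSpec(20.0),
                                 options=sphere_options)
        r2 = fem.solve_inflation(model, fem.make_material(6000.0, 0.2),
                                 None, fem.LoadSpec(20.0),
                                 options=sphere_options)
        from lungmech.strain import principal_strain
        m1 = np.median(principal_strain(r1.strains[-1]))
        m2 = np.median(principal_strain(r2.strains[-1]))
        assert abs(m1 / m2 - 2.0) < 0.2

    def test_volume_monotone_in_pressure(self, lung_mesh_small):
        model = geo.uniform_model(lung_mesh_small, 3000.0)
        mat = fem.make_material(3000.0, 0.2)
        springs = fem.make_spring_foundation()
        prob = fem.InflationProblem(model, mat, springs)
        vrs = []
        u = np.zeros(prob.n_dof)
        for p in (100.0, 300.0, 600.0):
            u = prob.solve_static(p, u0=u)
            vrs.append(prob.volume_ratio(u))
        assert vrs[0] < vrs[1] < vrs[2]

    def test_quasistatic_matches_dynamic_at_peak(self, lung_mesh_small):
        # breathing at 0.2 Hz: inertia is negligible
        model = geo.uniform_model(lung_mesh_small, 3000.0)
        mat = fem.make_material(3000.0, 0.2, rho_tissue=500.0)
        springs = fem.make_spring_foundation()
        load = fem.LoadSpec(600.0)
        rq = fem.solve_inflation(model, mat, springs, load)
        rd = fem.solve_inflation(model, mat, springs, load, mode="dynamic")
        dv = abs(rq.volume_ratio[-1] - rd.volume_ratio[-1])
        assert dv / (rq.volume_ratio[-1] - 1.0) < 0.02


class TestCalibration:
    def test_unit_target_gives_zero_pressure(self, lung_mesh_small):
        model = geo.uniform_model(lung_mesh_small, 3000.0)
        cal = fem.calibrate_pressure(model, fem.make_material(3000.0, 0.2),
                                     fem.make_spring_foundation(), 1.0)
        assert cal.p == 0.0
        assert cal.volume_ratio == 1.0

    def test_sphere_linear_oracle(self, ball_mesh, sphere_options):
        # target J = 1.01 with kappa = 4000 Pa -> p ~ kappa (J-1) = 40 Pa
        model = geo.uniform_model(ball_mesh, 3000.0)
        cal = fem.calibrate_pressure(model, fem.make_material(3000.0, 0.2),
                                     None, 1.01, tol=1e-4, p_init=20.0,
                                     options=sphere_options)
        assert abs(cal.p - 40.0) / 40.0 < 0.10

    def test_lung_section_target(self, lung_mesh_small):
        model = geo.uniform_model(lung_mesh_small, 3000.0)
        cal = fem.calibrate_pressure(model, fem.make_material(3000.0, 0.2),
                                     fem.make_spring_foundation(), 1.083,
                                     tol=1e-3)
        assert abs(cal.volume_ratio - 1.083) <= 1e-3
        assert cal.p > 0


class TestMeshConvergence:
    def test_median_strain_converges_under_refinement(self, lung_outlines):
        # scaled-down convergence protocol: successive refinements contract
        # and the finest pair agrees within 5%
        from lungmech.strain import principal_strain, weighted_quantile
        meds = []
        for target in (700, 2000, 4500):
            outer, inner = geo.loft_outlines(lung_outlines)
            mesh = geo.mesh_solids(outer, inner, target_element_count=target)
            model = geo.uniform_model(mesh, 3000.0)
            cal = fem.calibrate_pressure(
                model, fem.make_material(3000.0, 0.2),
                fem.make_spring_foundation(), 1.167, tol=1e-3)
            ep1 = principal_strain(cal.result.strains[-1])
            vols = mesh.element_volumes()
            inner_sel = mesh.domain == 0
            meds.append(weighted_quantile(ep1[inner_sel], 0.5,
                                          vols[inner_sel]))
        d01 = abs(meds[1] - meds[0]) / meds[0]
        d12 = abs(meds[2] - meds[1]) / meds[1]
        assert d12 < d01
        assert d12 < 0.05
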