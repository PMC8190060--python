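"""Stokes solver verification against closed forms and invariants."""

import numpy as np
import pytest
from shapely.geometry import box

from chipflow.fem import (FluidProperties, CutLine, solve_stokes,
                          shear_stress_field, surface_average, surface_max,
                          scale_solution, sample_cutline, diagnostics,
                          reynolds_number, flowrate_to_inlet_velocity,
                          mesh_convergence_study, field_from_function)
from chipflow.meshing import generate_mesh
from chipflow.units import ML_PER_H

W, L = 40e-6, 400e-6
U_MEAN = 2.3046e-3      # mass-conservation oracle: 0.012291 * 0.96e-3 / (128 * 40e-6)
MU = 1e-3


@pytest.fixture(scope="module")
def rect_mesh():
    return generate_mesh(box(0, -W / 2, L, W / 2), 4e-6)


@pytest.fixture(scope="module")
def poiseuille(rect_mesh):
    return solve_stokes(rect_mesh, U_MEAN, inlet_profile="parabolic")


class TestFlowrateConversion:
    def test_printed_equivalents(self):
        # the printed velocities imply Q = 2.124 ml/h; 2.12 ml/h lands within 0.2%
        q = 2.12 * ML_PER_H
        assert flowrate_to_inlet_velocity(q, 0.96e-3, 50e-6) == pytest.approx(
            0.012291, rel=2e-3)
        assert flowrate_to_inlet_velocity(q, 0.6e-3, 50e-6) == pytest.approx(
            0.019666, rel=2e-3)

    def test_formula_and_edge_cases(self):
        assert flowrate_to_inlet_velocity(0.0, 1e-3, 1e-4) == 0.0
        assert flowrate_to_inlet_velocity(4.8e-10, 0.96e-3, 50e-6) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            flowrate_to_inlet_velocity(1e-9, -1e-3, 1e-4)
        with pytest.raises(ValueError):
            flowrate_to_inlet_velocity(-1e-9, 1e-3, 1e-4)


class TestPoiseuille:
    def test_parabolic_profile_reproduced_exactly(self, poiseuille):
        ys = np.linspace(-W / 2 * 0.98, W / 2 * 0.98, 31)
        pts = np.column_stack([np.full_like(ys, L / 2), ys])
        u = poiseuille.velocity(pts)
        exact = 1.5 * U_MEAN * (1 - (2 * ys / W) ** 2)
        assert np.nanmax(np.abs(u[:, 0] - exact)) < 1e-9 * 1.5 * U_MEAN
        assert np.nanmax(np.abs(u[:, 1])) < 1e-9 * 1.5 * U_MEAN

    def test_wall_shear_matches_6muU_over_w(self, poiseuille):
        sf = shear_stress_field(poiseuille)
        tau_wall = sf.tau([[L / 2, -W / 2 + 1e-9]])[0]
        assert tau_wall == pytest.approx(6 * MU * U_MEAN / W, rel=0.02)
        # hand value: 0.3457 Pa = 3.457 dyne/cm^2
        assert tau_wall * 10 == pytest.approx(3.457, rel=0.02)

    def test_uniform_inflow_develops_to_parabola_by_midlength(self, rect_mesh):
        flow = solve_stokes(rect_mesh, U_MEAN, inlet_profile="uniform")
        u_eff = -flow.boundary_flux("inlet") / W     # actual mean of the plug
        ys = np.linspace(-W / 2 * 0.98, W / 2 * 0.98, 31)
        u = flow.velocity(np.column_stack([np.full_like(ys, L / 2), ys]))[:, 0]
        exact = 1.5 * u_eff * (1 - (2 * ys / W) ** 2)
        assert np.nanmax(np.abs(u - exact)) / (1.5 * u_eff) < 0.01

    def test_average_shear_and_speed(self, poiseuille):
        sf = shear_stress_field(poiseuille)
        assert surface_average(sf) == pytest.approx(3 * MU * U_MEAN / W, rel=5e-3)
        assert surface_average(poiseuille) == pytest.approx(U_MEAN, rel=1e-6)

    def test_mass_conservation_and_divergence(self, poiseuille):
        d = diagnostics(poiseuille, W)
        assert d.flux_imbalance < 1e-9
        assert d.divergence_residual < 1e-8

    def test_negative_inlet_velocity_rejected(self, rect_mesh):
        with pytest.raises(ValueError):
            solve_stokes(rect_mesh, -1.0)


class TestLinearity:
    def test_solver_linear_in_inlet_velocity(self, rect_mesh, poiseuille):
        flow2 = solve_stokes(rect_mesh, 2 * U_MEAN, inlet_profile="parabolic")
        assert np.max(np.abs(flow2.u - 2 * poiseuille.u)) \
            <= 1e-10 * np.max(np.abs(flow2.u))

    def test_scale_solution_factor_one_is_identity(self, poiseuille):
        s = scale_solution(poiseuille, 1.0)
        assert np.array_equal(s.u, poiseuille.u)
        assert np.array_equal(s.p, poiseuille.p)

    def test_scale_solution_scales_all_fields(self, poiseuille):
        s = scale_solution(poiseuille, 2.5)
        sf0, sf1 = shear_stress_field(poiseuille), shear_stress_field(s)
        assert surface_average(sf1) == pytest.approx(2.5 * surface_average(sf0), rel=1e-12)
        assert s.inlet_velocity == pytest.approx(2.5 * poiseuille.inlet_velocity)

    def test_printed_rows_obey_linearity(self):
        """Data sanity: the published sweep rows scale linearly to 0.1%."""
        from chipflow.pipeline import reference_tables
        ref = reference_tables()
        for (table, chip), grp in ref.groupby(["table", "chip_width_um"]):
            for col in ("shear_dyn_cm2", "vel_m_s"):
                r = grp[col] / grp["v_inlet_m_s"]
                assert (r.max() - r.min()) / r.mean() < 1e-3


class TestManufacturedFields:
    def test_uniform_translation_has_zero_shear(self, rect_mesh):
        flow = field_from_function(rect_mesh, lambda p: np.tile([1e-3, 0], (len(p), 1)))
        sf = shear_stress_field(flow)
        # roundoff floor: gradient noise ~ u * eps / h
        assert surface_average(sf) < 1e-12
        assert np.nanmax(sf.tau([[L / 2, 0.0]])) < 1e-12

    def test_linear_shear_gives_mu_gamma_everywhere(self, rect_mesh):
        gamma = 125.0
        flow = field_from_function(
            rect_mesh, lambda p: np.column_stack([gamma * p[:, 1], np.zeros(len(p))]))
        sf = shear_stress_field(flow)
        pts = np.column_stack([np.linspace(1e-5, 3e-4, 7), np.full(7, 5e-6)])
        assert sf.tau(pts) == pytest.approx(MU * gamma, rel=1e-9)

    def test_constant_field_average_and_max(self, rect_mesh):
        flow = field_from_function(rect_mesh, lambda p: np.tile([3e-3, 4e-3], (len(p), 1)))
        assert surface_average(flow) == pytest.approx(5e-3, rel=1e-12)
        val, _ = surface_max(flow)
        assert val == pytest.approx(5e-3, rel=1e-12)

    def test_empty_region_raises(self, rect_mesh):
        flow = field_from_function(rect_mesh, lambda p: np.zeros((len(p), 2)))
        with pytest.raises(ValueError):
            surface_average(flow, region=np.zeros(rect_mesh.n_triangles, dtype=bool))


class TestCutlines:
    def test_transverse_parabola_r_squared(self, poiseuille):
        line = CutLine((L / 2, -W / 2 * 0.999), (L / 2, W / 2 * 0.999), n=101)
        prof = sample_cutline(poiseuille, line)
        y = prof.points[:, 1]
        exact = 1.5 * U_MEAN * (1 - (2 * y / W) ** 2)
        ss_res = np.nansum((prof.values - exact) ** 2)
        ss_tot = np.nansum((exact - np.nanmean(exact)) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999

    def test_line_outside_domain_raises(self, poiseuille):
        line = CutLine((0, 1e-3), (L, 1e-3), n=11)
        with pytest.raises(ValueError):
            sample_cutline(poiseuille, line)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            CutLine((0, 0), (0, 0))


class TestDiagnostics:
    def test_reynolds_at_published_average_velocity(self):
        # direct evaluation of Re = rho U l / mu
        assert reynolds_number(1000.0, 0.0039264, 40e-6, 1e-3) == pytest.approx(
            0.157, rel=2e-3)

    def test_zero_velocity_gives_zero_reynolds(self, rect_mesh):
        flow = field_from_function(rect_mesh, lambda p: np.zeros((len(p), 2)))
        assert reynolds_number(1000.0, surface_average(flow), W, MU) == 0.0


class TestConvergence:
    def test_refinement_changes_shrink_monotonically(self):
        geom = box(0, -W / 2, 160e-6, W / 2)
        df = mesh_convergence_study(
            geom, [8e-6, 5.3e-6, 3.5e-6], U_MEAN,
            mesh_fn=lambda h: generate_mesh(box(0, -W / 2, 160e-6, W / 2), h))
        changes = df["shear_rel_change"].dropna().to_numpy()
        assert len(changes) == 2
        assert changes[1] <= changes[0]
        assert df["n_elements"].is_monotonic_increasing

    def test_increasing_sequence_rejected(self):
        with pytest.raises(ValueError):
            mesh_convergence_study(box(0, 0, 1e-4, 4e-5), [1e-5, 2e-5], 1e-3)

    def test_manufactured_constant_field_is_h_independent(self):
        vals = []
        for h in (8e-6, 4e-6):
            mesh = generate_mesh(box(0, -W / 2, 120e-6, W / 2), h)
            flow = field_from_function(mesh, lambda p: np.tile([2e-3, 0], (len(p), 1)))
            vals.append(surface_average(flow))
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
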