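"""Composite chip model: patch stitching vs monolithic FEM and the network
oracle, plus the whole-chip evaluator contract."""

import numpy as np
import pytest

from chipflow.composite import CompositeChipModel, channel_fluxes
from chipflow.fem import (shear_stress_field, surface_average, surface_max,
                          diagnostics, sample_cutline, CutLine, reynolds_number)
from chipflow.network import ChannelNetwork, partition_flow
from chipflow.pipeline import reference_tables

from conftest import U_IN_40


class TestNetworkOracle:
    def test_two_channel_fem_fluxes_match_network_within_2pc(self, mini2):
        params, geom, mesh, flow = mini2
        qk = channel_fluxes(flow, geom)
        net = ChannelNetwork.parallel(np.full(2, params.channel_width),
                                      params.channel_length)
        q_net = partition_flow(net, qk.sum())
        assert np.all(np.abs(qk / q_net - 1) < 0.02)

    def test_eight_channel_fem_fluxes_match_network_within_2pc(self, mini8):
        params, geom, mesh, flow = mini8
        qk = channel_fluxes(flow, geom)
        assert np.all(np.abs(qk / (qk.sum() / 8) - 1) < 0.02)


class TestMassConservation:
    def test_inlet_outlet_and_channel_fluxes_balance(self, mini8):
        _, geom, _, flow = mini8
        d = diagnostics(flow, 40e-6)
        assert d.flux_imbalance < 0.005
        qk = channel_fluxes(flow, geom)
        assert abs(qk.sum() / -d.inlet_flux - 1) < 0.005
        assert d.divergence_residual < 1e-8


class TestSymmetryAndPoiseuilleLimit:
    def test_solved_field_mirror_symmetric(self, mini8):
        _, geom, _, flow = mini8
        rng = np.random.default_rng(0)
        H = geom.params.array_height
        pts = rng.uniform([0, -0.45 * H], [geom.x_total, 0.45 * H], (400, 2))
        v1 = flow.velocity(pts)
        v2 = flow.velocity(pts * [1, -1])
        m = np.isfinite(v1[:, 0]) & np.isfinite(v2[:, 0])
        err = np.linalg.norm(v1[m] * [1, -1] - v2[m]) / np.linalg.norm(v1[m])
        assert err < 0.01

    def test_mid_channel_profile_matches_closed_form(self, mini8):
        params, geom, _, flow = mini8
        w = params.channel_width
        qk = channel_fluxes(flow, geom)
        x = 0.5 * (geom.x_channels_start + geom.x_channels_end)
        for k in (0, 3, 7):
            yc = float(geom.channel_center_y(k))
            ys = np.linspace(yc - 0.48 * w, yc + 0.48 * w, 25)
            u = flow.velocity(np.column_stack([np.full_like(ys, x), ys]))[:, 0]
            exact = 1.5 * (qk[k] / w) * (1 - (2 * (ys - yc) / w) ** 2)
            assert np.nanmax(np.abs(u - exact)) / (1.5 * qk[k] / w) < 0.01

    def test_wall_shear_matches_6muU_over_w_within_2pc(self, mini8):
        params, geom, _, flow = mini8
        w = params.channel_width
        qk = channel_fluxes(flow, geom)
        sf = shear_stress_field(flow)
        x = 0.5 * (geom.x_channels_start + geom.x_channels_end)
        yc = float(geom.channel_center_y(4))
        tau = sf.tau([[x, yc - w / 2 + 1e-9]])[0]
        assert tau == pytest.approx(6e-3 * (qk[4] / w) / w, rel=0.02)


class TestCompositeVsMonolithic:
    def test_surface_averages_agree_within_3pc(self, mini8):
        params, geom, mesh, flow = mini8
        model = CompositeChipModel(params)
        mono_shear = surface_average(shear_stress_field(flow))
        mono_speed = surface_average(flow)
        assert model.surface_average_shear(U_IN_40) == pytest.approx(mono_shear, rel=0.03)
        assert model.surface_average_speed(U_IN_40) == pytest.approx(mono_speed, rel=0.03)

    def test_composite_area_matches_geometry(self, default_model):
        assert default_model.total_area == pytest.approx(
            default_model.geom.total_area, rel=1e-6)


class TestDefaultChipModel:
    def test_channel_mean_velocity_mass_conservation_oracle(self, default_model):
        # U_in * w_inlet / (128 * w_channel)
        assert default_model.channel_mean_velocity(U_IN_40) == pytest.approx(
            2.30e-3, rel=0.02)

    def test_max_shear_location_in_a_micropost_gap(self, default_model):
        _, loc = default_model.surface_max_shear(U_IN_40)
        g, p = default_model.geom, default_model.params
        assert g.first_post_tip_x - 5e-6 <= loc[0] <= g.x_channels_end
        k = g.channel_of([loc[1]], None)[0]
        assert k >= 0
        off = abs(loc[1] - float(g.channel_center_y(k)))
        assert off >= p.micropost_transverse_diagonal / 2 - 1e-6  # beside the post

    def test_max_speed_in_gap_scales_with_gap_flux(self, default_model):
        vmax, loc = default_model.surface_max_speed(U_IN_40)
        # per-gap flux halves the channel flux; peak ~1.5x the gap mean
        u_gap = default_model.channel_mean_velocity(U_IN_40) * 40e-6 / (2 * 2e-6)
        assert vmax == pytest.approx(1.5 * u_gap, rel=0.15)

    def test_reynolds_below_unity_for_all_study_conditions(self, default_model, model_25):
        ref = reference_tables()
        for model, wum in ((default_model, 40), (model_25, 25)):
            for v in ref[ref.chip_width_um == wum]["v_inlet_m_s"].unique():
                U = model.surface_average_speed(v)
                re = reynolds_number(1000.0, U, model.params.channel_width, 1e-3)
                assert re < 1.0

    def test_sweep_rows_linear_in_inlet_velocity(self, default_model):
        df = default_model.sweep([1e-3, 2e-3, 4e-3])
        for col in ("shear_avg_dyn_cm2", "vel_avg_m_s", "shear_max_dyn_cm2",
                    "vel_max_m_s"):
            r = df[col] / df["v_inlet_m_s"]
            assert (r.max() - r.min()) / r.mean() < 1e-9


class TestEvaluator:
    def test_channel_region_is_plane_poiseuille(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        g, p = default_model.geom, default_model.params
        yc = float(g.channel_center_y(10))
        x = g.x_channels_start + 5e-3
        ys = yc + np.linspace(-0.45, 0.45, 11) * p.channel_width
        v = ev.velocity(np.column_stack([np.full_like(ys, x), ys]))
        eta = 2 * (ys - yc) / p.channel_width
        exact = 1.5 * ev.Uc * (1 - eta ** 2)
        assert np.allclose(v[:, 0], exact, rtol=1e-12)
        assert np.allclose(v[:, 1], 0.0, atol=1e-18)

    def test_walls_and_posts_return_nan(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        g, p = default_model.geom, default_model.params
        y_wall = float(g.channel_center_y(10)) + p.pitch / 2
        assert np.isnan(ev.velocity([[g.x_channels_start + 1e-3, y_wall]])).all()
        # centre of the first post of the middle channel
        x_post = g.first_post_tip_x + p.micropost_axial_diagonal / 2
        y_post = float(g.channel_center_y(p.n_channels // 2))
        assert np.isnan(ev.velocity([[x_post, y_post]])).all()

    def test_header_flux_preserved(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        g = default_model.geom
        for x in (g.x_feed_end + 0.5e-3, g.x_feed_end + 1.5e-3):
            w = float(ev.header_width(x))
            ys = np.linspace(-w / 2 * 0.9999, w / 2 * 0.9999, 2001)
            ux = ev.velocity(np.column_stack([np.full_like(ys, x), ys]))[:, 0]
            q = np.trapezoid(ux, ys)
            assert q == pytest.approx(ev.q, rel=1e-3)

    def test_cutline_presets_sample_sensibly(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        presets = CutLine.presets(default_model.geom)
        # gap profile: zero at both walls, peaked inside
        prof = sample_cutline(ev, presets["gap_vertical"])
        v = prof.values
        interior = v[np.isfinite(v)]
        assert interior.max() > 10 * ev.Uc
        assert v[np.isfinite(v)][0] < 0.5 * interior.max() or np.isnan(v[0])
        # diagonal shear: high near walls, ~0 at channel midpoint
        tau = sample_cutline(ev, presets["channel_diagonal"], quantity="shear")
        mid = len(tau.values) // 2
        assert np.nanmin(np.abs(tau.values[mid - 5:mid + 5])) < 0.1 * np.nanmax(tau.values)
        # inlet centerline: rises toward 1.5x U_in then falls in the fan
        prof_in = sample_cutline(ev, presets["inlet_centerline"])
        assert np.nanmax(prof_in.values) == pytest.approx(1.5 * U_IN_40, rel=0.01)
        assert prof_in.values[-2] < 0.5 * np.nanmax(prof_in.values)
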