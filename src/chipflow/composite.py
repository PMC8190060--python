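"""Composite full-chip flow model.

A monolithic finite-element solve of the whole chip (128 channels of 20 mm
with 2 um gap resolution) would need millions of elements, so the full-chip
fast path decomposes the domain by exploiting two facts: creeping flow is
linear, and away from the manifold and the micropost rows every microchannel
carries fully developed plane Poiseuille flow.

Regions and their treatment:

* input/output feed channel   - closed-form Poiseuille at the imposed flux;
* tapered header (x2)         - one FEM patch solve at unit inlet velocity;
* straight channel runs       - closed form at the network-partitioned flux;
* micropost row + collection  - one FEM patch solve per geometry at unit
  channel-mean velocity, reused for all channels (equal partition).

Surface statistics are exact area-weighted combinations of the region
integrals; every quantity scales linearly with the inlet velocity, so a
whole inlet-velocity sweep costs one pair of patch solves.  The same model
exposes a point velocity evaluator used by the Lagrangian cell tracer,
with flux-preserving streamline mapping at the header/array junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import pandas as pd

from .geometry import ChipParams, ChipGeometry, build_chip, post_patch_polygon, header_polygon
from .meshing import generate_mesh
from .fem import (FluidProperties, solve_stokes, shear_stress_field,
                  surface_average, surface_max, FlowField)
from .network import ChannelNetwork, partition_flow
from .units import PA_TO_DYNE_CM2

__all__ = ["CompositeChipModel", "ChipFlowEvaluator", "channel_fluxes"]


def _flux_fraction(eta):
    """Cumulative Poiseuille flux fraction F(eta) = (2 + 3 eta - eta^3)/4."""
    eta = np.clip(eta, -1.0, 1.0)
    return (2.0 + 3.0 * eta - eta ** 3) / 4.0


_ETA_GRID = np.linspace(-1.0, 1.0, 4001)
_F_GRID = _flux_fraction(_ETA_GRID)


def _eta_from_fraction(s):
    return np.interp(np.clip(s, 0.0, 1.0), _F_GRID, _ETA_GRID)


@dataclass
class _RegionStats:
    area: float
    int_speed: float       # integral of |u| at reference scale
    int_tau: float         # integral of tau at reference scale [Pa m^2]


class CompositeChipModel:
    """Flow statistics and a point evaluator for the whole chip.

    Patch solves happen once at reference scale (unit velocities); queries
    at any inlet velocity use exact linear rescaling.
    """

    def __init__(self, params: ChipParams | None = None,
                 fluid: FluidProperties | None = None,
                 h_post_patch: float | None = None,
                 h_gap: float | None = None,
                 h_header: float | None = None,
                 upstream_margin: float = 100e-6):
        self.params = params or ChipParams()
        self.fluid = fluid or FluidProperties()
        self.geom = build_chip(self.params)
        p = self.params
        self.h_post_patch = h_post_patch or p.channel_width / 8
        self.h_gap = h_gap or p.micropost_side_gap / 5
        self.h_header = h_header or min(p.inlet_width / 12, max(p.array_height, p.inlet_width) / 40)
        self.upstream_margin = upstream_margin

        # equal-geometry parallel channels: the network partition is exact
        net = ChannelNetwork.parallel(
            widths=np.full(p.n_channels, p.channel_width),
            lengths=p.channel_length + p.collection_length,
            mu=self.fluid.dynamic_viscosity)
        self.channel_flux_fractions = partition_flow(net, 1.0)  # sums to 1

        self._post_patch = None
        self._header_patch = None
        self._stats = None

    # ------------------------------------------------------------------
    # patch solves (reference scale)
    # ------------------------------------------------------------------
    @property
    def post_patch(self) -> FlowField | None:
        """FEM solve of one channel end (posts + collection) at U_mean = 1."""
        if self.params.microposts_per_channel == 0:
            return None
        if self._post_patch is None:
            poly, posts, chip_x0 = post_patch_polygon(self.params, self.upstream_margin)
            mesh = generate_mesh(poly, self.h_post_patch, self.h_gap)
            self._post_patch = solve_stokes(mesh, 1.0, self.fluid,
                                            inlet_profile="parabolic")
            self._post_patch.meta["chip_x0"] = chip_x0
            self._post_patch.meta["polygon_area"] = poly.area
        return self._post_patch

    @property
    def header_patch(self) -> FlowField:
        """FEM solve of the inlet header at U_in = 1 (uniform inflow)."""
        if self._header_patch is None:
            poly = header_polygon(self.params)
            w_in = self.params.inlet_width

            def tag(mid):
                tol = 1e-9
                tags = np.full(len(mid), "wall", dtype=object)
                tags[(np.abs(mid[:, 0]) < tol)
                     & (np.abs(mid[:, 1]) <= w_in / 2 + tol)] = "inlet"
                tags[np.abs(mid[:, 0] - self.params.header_length) < tol] = "outlet"
                return tags

            mesh = generate_mesh(poly, self.h_header, tag_fn=tag)
            self._header_patch = solve_stokes(mesh, 1.0, self.fluid,
                                              inlet_profile="uniform")
            self._header_patch.meta["polygon_area"] = poly.area
        return self._header_patch

    # ------------------------------------------------------------------
    # region bookkeeping at reference inlet velocity U_in = 1
    # ------------------------------------------------------------------
    @property
    def channel_mean_velocity_ref(self) -> float:
        """Channel-mean velocity per unit inlet velocity: w_in / (n w)."""
        p = self.params
        return p.inlet_width / (p.n_channels * p.channel_width)

    def channel_mean_velocity(self, U_in: float) -> float:
        return U_in * self.channel_mean_velocity_ref

    def _region_stats(self) -> dict:
        if self._stats is not None:
            return self._stats
        p, mu = self.params, self.fluid.dynamic_viscosity
        g = self.geom
        Uc = self.channel_mean_velocity_ref          # at U_in = 1
        stats = {}

        # feed channels (both ends), fully developed at mean U_in = 1
        a = g.area_feed
        stats["feed"] = _RegionStats(a, a * 1.0, a * 3 * mu * 1.0 / p.inlet_width)

        # headers (both ends): FEM patch at U_in = 1; by Stokes reversibility
        # the mirrored outlet header has identical statistics
        hp = self.header_patch
        w = _quad_weights(hp)
        a_h = hp.meta["polygon_area"]
        int_speed_h = float((hp._quad_speed() * w).sum())
        int_tau_h = float(mu * (hp._quad_shear_rate() * w).sum())
        stats["header"] = _RegionStats(2 * a_h, 2 * int_speed_h, 2 * int_tau_h)

        # straight channel runs (closed form at Uc)
        pp = self.post_patch
        if pp is not None:
            patch_len_in_channel = (self.upstream_margin + self._row_span()
                                    + p.micropost_end_clearance)
            L_straight = p.channel_length - patch_len_in_channel
            a_patch = pp.meta["polygon_area"] * p.n_channels
        else:
            L_straight = p.channel_length + p.collection_length
            a_patch = 0.0
        a_straight = p.n_channels * p.channel_width * L_straight
        stats["channels"] = _RegionStats(
            a_straight, a_straight * Uc, a_straight * 3 * mu * Uc / p.channel_width)

        # micropost + collection patches (FEM at U_mean = 1, scaled by Uc)
        if pp is not None:
            w = _quad_weights(pp)
            int_speed_p = float((pp._quad_speed() * w).sum()) * Uc * p.n_channels
            int_tau_p = float(mu * (pp._quad_shear_rate() * w).sum()) * Uc * p.n_channels
            stats["posts"] = _RegionStats(a_patch, int_speed_p, int_tau_p)

        self._stats = stats
        return stats

    def _row_span(self) -> float:
        p = self.params
        spacing_cc = p.micropost_axial_diagonal + p.micropost_clear_spacing
        return ((p.microposts_per_channel - 1) * spacing_cc
                + p.micropost_axial_diagonal)

    # ------------------------------------------------------------------
    # surface statistics (linear in U_in)
    # ------------------------------------------------------------------
    @property
    def total_area(self) -> float:
        return sum(r.area for r in self._region_stats().values())

    def surface_average_speed(self, U_in: float) -> float:
        s = self._region_stats()
        return U_in * sum(r.int_speed for r in s.values()) / self.total_area

    def surface_average_shear(self, U_in: float) -> float:
        """Area-average of tau over the whole fluid domain [Pa]."""
        s = self._region_stats()
        return U_in * sum(r.int_tau for r in s.values()) / self.total_area

    def surface_max_speed(self, U_in: float):
        best, loc = 1.5, np.array([self.params.feed_length / 2, 0.0])  # feed centreline
        hmax, hloc = surface_max(self.header_patch)
        if hmax > best:
            best, loc = hmax, self._header_to_chip(hloc)
        pp = self.post_patch
        if pp is not None:
            pmax, ploc = surface_max(pp)
            pmax *= self.channel_mean_velocity_ref
            if pmax > best:
                best, loc = pmax, self._patch_to_chip(ploc)
        return U_in * best, loc

    def surface_max_shear(self, U_in: float):
        mu = self.fluid.dynamic_viscosity
        p = self.params
        best = 6 * mu / p.inlet_width                         # feed wall, U_in = 1
        loc = np.array([p.feed_length / 2, p.inlet_width / 2])
        cand = 6 * mu * self.channel_mean_velocity_ref / p.channel_width
        if cand > best:
            best = cand
            loc = np.array([self.geom.x_channels_start + p.channel_length / 2,
                            self.geom.channel_center_y(p.n_channels // 2)
                            + p.channel_width / 2])
        hmax, hloc = surface_max(shear_stress_field(self.header_patch))
        if hmax > best:
            best, loc = hmax, self._header_to_chip(hloc)
        pp = self.post_patch
        if pp is not None:
            pmax, ploc = surface_max(shear_stress_field(pp))
            pmax *= self.channel_mean_velocity_ref
            if pmax > best:
                best, loc = pmax, self._patch_to_chip(ploc)
        return U_in * best, loc

    def _patch_to_chip(self, loc, k: int | None = None) -> np.ndarray:
        k = self.params.n_channels // 2 if k is None else k
        x0 = self.post_patch.meta["chip_x0"]
        return np.array([x0 + loc[0], float(self.geom.channel_center_y(k)) + loc[1]])

    def _header_to_chip(self, loc) -> np.ndarray:
        return np.array([self.params.feed_length + loc[0], loc[1]])

    # ------------------------------------------------------------------
    def sweep(self, inlet_velocities, chip_width_um: float | None = None) -> pd.DataFrame:
        """Summary table over inlet velocities, in reporting units
        (m/s and dyne/cm^2), mirroring the surface average/maximum tables."""
        rows = []
        wum = chip_width_um or self.params.channel_width * 1e6
        for U in inlet_velocities:
            smax, _ = self.surface_max_shear(U)
            vmax, _ = self.surface_max_speed(U)
            rows.append({
                "chip_width_um": wum,
                "v_inlet_m_s": U,
                "shear_avg_dyn_cm2": self.surface_average_shear(U) * PA_TO_DYNE_CM2,
                "vel_avg_m_s": self.surface_average_speed(U),
                "shear_max_dyn_cm2": smax * PA_TO_DYNE_CM2,
                "vel_max_m_s": vmax,
            })
        return pd.DataFrame(rows)

    def evaluator(self, U_in: float) -> "ChipFlowEvaluator":
        return ChipFlowEvaluator(self, U_in)


def _quad_weights(flow: FlowField) -> np.ndarray:
    from .fem import _QW
    return _QW[None, :] * flow.space.area[:, None]


def channel_fluxes(flow: FlowField, geom: ChipGeometry, x: float | None = None,
                   n_samples: int = 201) -> np.ndarray:
    """Per-channel 2D fluxes of a monolithic FEM solution, by transverse
    integration of u_x across each channel at station ``x`` (default:
    mid-channel)."""
    p = geom.params
    if x is None:
        x = 0.5 * (geom.x_channels_start + (geom.first_post_tip_x
                                            if p.microposts_per_channel else geom.x_channels_end))
    out = np.empty(p.n_channels)
    for k in range(p.n_channels):
        yc = float(geom.channel_center_y(k))
        ys = np.linspace(yc - p.channel_width / 2 + 1e-12,
                         yc + p.channel_width / 2 - 1e-12, n_samples)
        ux = flow.velocity(np.column_stack([np.full_like(ys, x), ys]))[:, 0]
        out[k] = np.trapezoid(np.nan_to_num(ux), ys)
    return out


# ---------------------------------------------------------------------------
# point evaluator for tracing and cut lines
# ---------------------------------------------------------------------------

class ChipFlowEvaluator:
    """Velocity/shear point evaluation over the whole chip at a given U_in.

    Analytic regions use closed forms (feed and channels: plane Poiseuille;
    headers: a lubrication fan whose streamlines preserve the cumulative
    flux fraction); the micropost region evaluates the FEM patch.  Queries
    in solid material (walls, posts) return NaN.
    """

    def __init__(self, model: CompositeChipModel, U_in: float):
        self.model = model
        self.U_in = float(U_in)
        self.geom = model.geom
        self.params = model.params
        g, p = self.geom, self.params
        self.q = U_in * p.inlet_width                      # total 2D flux
        self.Uc = model.channel_mean_velocity(U_in)        # channel mean
        pp = model.post_patch
        self.x_patch = pp.meta["chip_x0"] if pp is not None else g.x_collection_end
        self.stations = dict(feed_end=g.x_feed_end, array=g.x_channels_start,
                             patch=self.x_patch, coll_end=g.x_collection_end,
                             outlet_header_end=g.x_outlet_header_end, total=g.x_total)

    # region helpers -----------------------------------------------------
    def header_width(self, x) -> np.ndarray:
        """Local width of the header fan at chip-frame x (inlet side)."""
        p = self.params
        if p.manifold_style == "straight_header":
            return np.broadcast_to(p.array_height, np.shape(x)).astype(float)
        t = (np.asarray(x, float) - self.geom.x_feed_end) / p.header_length
        return p.inlet_width + (p.array_height - p.inlet_width) * np.clip(t, 0, 1)

    def outlet_header_width(self, x) -> np.ndarray:
        p = self.params
        if p.manifold_style == "straight_header":
            return np.broadcast_to(p.array_height, np.shape(x)).astype(float)
        t = (np.asarray(x, float) - self.geom.x_collection_end) / p.header_length
        return p.array_height + (p.inlet_width - p.array_height) * np.clip(t, 0, 1)

    def channel_target(self, s):
        """Map header flux fraction(s) to (channel index, local eta)."""
        p = self.params
        cum = np.concatenate([[0.0], np.cumsum(self.model.channel_flux_fractions)])
        k = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, p.n_channels - 1)
        t = (s - cum[k]) / self.model.channel_flux_fractions[k]
        return k, _eta_from_fraction(t)

    def header_fraction(self, k, eta_c):
        cum = np.concatenate([[0.0], np.cumsum(self.model.channel_flux_fractions)])
        return cum[k] + self.model.channel_flux_fractions[k] * _flux_fraction(eta_c)

    # field evaluation ---------------------------------------------------
    def velocity(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        x, y = pts[:, 0], pts[:, 1]
        out = np.full((len(pts), 2), np.nan)
        g, p = self.geom, self.params
        w_in = p.inlet_width

        feed_in = (x >= -1e-12) & (x < g.x_feed_end)
        feed_out = (x > g.x_outlet_header_end) & (x <= g.x_total + 1e-12)
        for m in (feed_in, feed_out):
            if m.any():
                eta = 2 * y[m] / w_in
                ok = np.abs(eta) <= 1.0
                u = np.where(ok, 1.5 * self.U_in * (1 - eta ** 2), np.nan)
                out[m] = np.column_stack([u, np.where(ok, 0.0, np.nan)])

        hdr_in = (x >= g.x_feed_end) & (x < g.x_channels_start)
        hdr_out = (x > g.x_collection_end) & (x <= g.x_outlet_header_end)
        taper = 0.0 if p.manifold_style == "straight_header" else \
            (p.array_height - w_in) / p.header_length
        for m, wfun, slope in ((hdr_in, self.header_width, taper),
                               (hdr_out, self.outlet_header_width, -taper)):
            if m.any():
                w = wfun(x[m])
                dw = np.full_like(w, slope)
                eta = 2 * y[m] / w
                ok = np.abs(eta) <= 1.0
                ux = 1.5 * (self.q / w) * (1 - eta ** 2)
                uy = 0.75 * self.q * eta * (1 - eta ** 2) * dw / w
                out[m] = np.column_stack([np.where(ok, ux, np.nan),
                                          np.where(ok, uy, np.nan)])

        chan = (x >= g.x_channels_start) & (x < self.x_patch)
        if chan.any():
            k = g.channel_of(y[chan], x[chan])
            yc = g.channel_center_y(np.clip(k, 0, p.n_channels - 1))
            eta = 2 * (y[chan] - yc) / p.channel_width
            u = np.where(k >= 0, 1.5 * self.Uc * (1 - eta ** 2), np.nan)
            out[chan] = np.column_stack([u, np.where(k >= 0, 0.0, np.nan)])

        patch = (x >= self.x_patch) & (x <= g.x_collection_end)
        if patch.any():
            pp = self.model.post_patch
            if pp is None:
                k = g.channel_of(y[patch], None)
                yc = g.channel_center_y(np.clip(k, 0, p.n_channels - 1))
                eta = 2 * (y[patch] - yc) / p.channel_width
                u = np.where(k >= 0, 1.5 * self.Uc * (1 - eta ** 2), np.nan)
                out[patch] = np.column_stack([u, np.where(k >= 0, 0.0, np.nan)])
            else:
                k = g.channel_of(y[patch], None)
                yc = g.channel_center_y(np.clip(k, 0, p.n_channels - 1))
                loc = np.column_stack([x[patch] - self.x_patch, y[patch] - yc])
                v = pp.velocity(loc) * self.Uc
                v[k < 0] = np.nan
                out[patch] = v
        return out

    def speed(self, pts) -> np.ndarray:
        return np.linalg.norm(self.velocity(pts), axis=1)

    def tau(self, pts) -> np.ndarray:
        """Viscous shear-stress magnitude [Pa]; analytic in closed-form
        regions, FEM-evaluated around the microposts; NaN in solid."""
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        x, y = pts[:, 0], pts[:, 1]
        out = np.full(len(pts), np.nan)
        g, p = self.geom, self.params
        mu = self.model.fluid.dynamic_viscosity
        w_in = p.inlet_width

        feed = ((x >= -1e-12) & (x < g.x_feed_end)) | \
               ((x > g.x_outlet_header_end) & (x <= g.x_total + 1e-12))
        if feed.any():
            eta = 2 * y[feed] / w_in
            out[feed] = np.where(np.abs(eta) <= 1,
                                 6 * mu * self.U_in * np.abs(eta) / w_in, np.nan)

        hdr_in = (x >= g.x_feed_end) & (x < g.x_channels_start)
        hdr_out = (x > g.x_collection_end) & (x <= g.x_outlet_header_end)
        for m, wfun in ((hdr_in, self.header_width), (hdr_out, self.outlet_header_width)):
            if m.any():
                w = wfun(x[m])
                eta = 2 * y[m] / w
                out[m] = np.where(np.abs(eta) <= 1,
                                  6 * mu * (self.q / w) * np.abs(eta) / w, np.nan)

        chan = (x >= g.x_channels_start) & (x < self.x_patch)
        if chan.any():
            k = g.channel_of(y[chan], x[chan])
            yc = g.channel_center_y(np.clip(k, 0, p.n_channels - 1))
            eta = 2 * (y[chan] - yc) / p.channel_width
            out[chan] = np.where(k >= 0,
                                 6 * mu * self.Uc * np.abs(eta) / p.channel_width, np.nan)

        patch = (x >= self.x_patch) & (x <= g.x_collection_end)
        if patch.any():
            pp = self.model.post_patch
            k = g.channel_of(y[patch], None)
            yc = g.channel_center_y(np.clip(k, 0, p.n_channels - 1))
            if pp is None:
                eta = 2 * (y[patch] - yc) / p.channel_width
                out[patch] = np.where(k >= 0,
                                      6 * mu * self.Uc * np.abs(eta) / p.channel_width,
                                      np.nan)
            else:
                loc = np.column_stack([x[patch] - self.x_patch, y[patch] - yc])
                t = mu * pp.shear_rate(loc) * self.Uc
                t[k < 0] = np.nan
                out[patch] = t
        return out
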