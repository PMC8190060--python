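"""Steady incompressible 2D Stokes flow on triangle meshes.

Discretization is the Taylor-Hood pair: continuous piecewise-quadratic (P2)
velocity and piecewise-linear (P1) pressure, an inf-sup stable mixed element.
The weak problem is

    mu (grad u, grad v) - (p, div v) = 0        for all v,
    (q, div u) = 0                              for all q,

with a Dirichlet inflow of magnitude ``U_in`` on the inlet boundary, no-slip
walls, and a natural (do-nothing, "zero pressure") outlet.  Because plane
Poiseuille flow is quadratic in y, the element reproduces it exactly, which
the tests exploit as a closed-form oracle.

Shear stress is reported as the viscous stress magnitude

    tau = mu * sqrt(2 D:D),   D = (grad u + grad u^T) / 2,

which reduces to ``mu |du/dy|`` in simple shear.  The creeping-flow problem
is linear in ``U_in``, so one solve per geometry plus exact scaling covers a
whole inlet-velocity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import matplotlib.tri as mtri
import shapely

from .meshing import Mesh
from .units import PA_TO_DYNE_CM2

__all__ = [
    "FluidProperties", "FlowField", "ShearField", "FlowDiagnostics", "CutLine",
    "Profile", "SolverError", "flowrate_to_inlet_velocity", "solve_stokes",
    "shear_stress_field", "surface_average", "surface_max", "scale_solution",
    "sample_cutline", "diagnostics", "mesh_convergence_study", "reynolds_number",
    "field_from_function",
]

WATER_DENSITY = 1000.0        # kg/m^3; culture medium approximated as water
WATER_VISCOSITY = 0.001       # Pa s


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    density: float = WATER_DENSITY
    dynamic_viscosity: float = WATER_VISCOSITY

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and dynamic_viscosity must be > 0")


def flowrate_to_inlet_velocity(Q: float, inlet_width: float, depth: float) -> float:
    """Mean inlet velocity [m/s] for a volumetric syringe rate Q [m^3/s].

    The chip cross-section at the input channel is ``inlet_width x depth``;
    the 2D plan-view model carries the same mean velocity.
    """
    if Q < 0:
        raise ValueError("flow rate Q must be >= 0")
    if inlet_width <= 0 or depth <= 0:
        raise ValueError("inlet_width and depth must be > 0")
    return Q / (inlet_width * depth)


def reynolds_number(density, U, l, viscosity) -> float:
    """Re = rho U l / mu, the ratio of inertial to viscous forces."""
    return density * U * l / viscosity


# ---------------------------------------------------------------------------
# P2 space and quadrature
# ---------------------------------------------------------------------------

# Dunavant 6-point rule, exact for degree 4
_QA1, _QB1, _QW1 = 0.445948490915965, 0.108103018168070, 0.223381589678011
_QA2, _QB2, _QW2 = 0.091576213509771, 0.816847572980459, 0.109951743655322
_QLAM = np.array([
    [_QB1, _QA1, _QA1], [_QA1, _QB1, _QA1], [_QA1, _QA1, _QB1],
    [_QB2, _QA2, _QA2], [_QA2, _QB2, _QA2], [_QA2, _QA2, _QB2],
])
_QW = np.array([_QW1, _QW1, _QW1, _QW2, _QW2, _QW2])


def _p2_basis(lam: np.ndarray):
    """P2 basis values and lambda-derivatives at barycentric points (n, 3).

    Local node order: vertices 0..2, then midpoints opposite each vertex
    (3 = mid(1,2), 4 = mid(2,0), 5 = mid(0,1))."""
    l0, l1, l2 = lam[:, 0], lam[:, 1], lam[:, 2]
    N = np.stack([l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
                  4 * l1 * l2, 4 * l2 * l0, 4 * l0 * l1], axis=1)
    z = np.zeros_like(l0)
    dN = np.stack([  # (n, 6, 3): d phi_i / d lambda_k
        np.stack([4 * l0 - 1, z, z], axis=1),
        np.stack([z, 4 * l1 - 1, z], axis=1),
        np.stack([z, z, 4 * l2 - 1], axis=1),
        np.stack([z, 4 * l2, 4 * l1], axis=1),
        np.stack([4 * l2, z, 4 * l0], axis=1),
        np.stack([4 * l1, 4 * l0, z], axis=1),
    ], axis=1)
    return N, dN


class P2Space:
    """Quadratic nodes (vertices + edge midpoints) on a triangle mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        tris = mesh.triangles
        n_v = mesh.n_points
        edges = np.sort(np.concatenate(
            [tris[:, [1, 2]], tris[:, [2, 0]], tris[:, [0, 1]]]), axis=1)
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        self.edges = uniq
        mid = inv.reshape(3, -1).T + n_v          # (nt, 3) midpoint node ids
        self.tri6 = np.hstack([tris, mid])
        self.nodes = np.vstack([mesh.points,
                                0.5 * (mesh.points[uniq[:, 0]] + mesh.points[uniq[:, 1]])])
        self._edge_keys = uniq[:, 0].astype(np.int64) * n_v + uniq[:, 1]

        # per-element affine geometry
        p0, p1, p2 = (mesh.points[tris[:, i]] for i in range(3))
        det = ((p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
               - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1]))
        self.area = 0.5 * np.abs(det)
        g1 = np.column_stack([p2[:, 1] - p0[:, 1], p0[:, 0] - p2[:, 0]]) / det[:, None]
        g2 = np.column_stack([p0[:, 1] - p1[:, 1], p1[:, 0] - p0[:, 0]]) / det[:, None]
        self.dlam = np.stack([-g1 - g2, g1, g2], axis=1)      # (nt, 3, 2)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def midpoint_node(self, a, b) -> np.ndarray:
        """P2 node index of the midpoint of vertex pair (a, b)."""
        a, b = np.asarray(a), np.asarray(b)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        key = lo.astype(np.int64) * self.mesh.n_points + hi
        return np.searchsorted(self._edge_keys, key) + self.mesh.n_points

    def quad_points(self) -> np.ndarray:
        """Physical coordinates of quadrature points, (nt, nq, 2)."""
        verts = self.mesh.points[self.mesh.triangles]         # (nt, 3, 2)
        return np.einsum("qk,tkd->tqd", _QLAM, verts)

    def shape_gradients(self, lam: np.ndarray) -> np.ndarray:
        """Physical gradients of the 6 basis fns at barycentric pts: (nt, n, 6, 2)."""
        _, dN = _p2_basis(lam)
        return np.einsum("qik,tkd->tqid", dN, self.dlam)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """Discrete Stokes solution with a point-evaluation contract.

    Point queries return NaN outside the fluid (in particular inside the
    micropost holes), never extrapolated values.
    """

    mesh: Mesh
    space: P2Space = field(repr=False, default=None)
    u: np.ndarray = field(repr=False, default=None)    # (n_p2, 2)
    p: np.ndarray = field(repr=False, default=None)    # (n_v,)
    inlet_velocity: float = 0.0
    fluid: FluidProperties = field(default_factory=FluidProperties)
    meta: dict = field(default_factory=dict)
    _finder: object = field(default=None, repr=False, compare=False)

    def _trifinder(self):
        if self._finder is None:
            t = mtri.Triangulation(self.mesh.points[:, 0], self.mesh.points[:, 1],
                                   self.mesh.triangles)
            self._finder = t.get_trifinder()
        return self._finder

    def _locate(self, pts):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        el = np.asarray(self._trifinder()(pts[:, 0], pts[:, 1]))
        ok = el >= 0
        lam = np.zeros((len(pts), 3))
        if ok.any():
            tri = self.mesh.triangles[el[ok]]
            cent = self.mesh.points[tri].mean(axis=1)
            d = self.space.dlam[el[ok]]                       # (n, 3, 2)
            lam[ok] = 1.0 / 3.0 + np.einsum("nkd,nd->nk", d, pts[ok] - cent)
        return el, ok, lam

    def velocity(self, pts) -> np.ndarray:
        el, ok, lam = self._locate(pts)
        out = np.full((len(el), 2), np.nan)
        if ok.any():
            N, _ = _p2_basis(lam[ok])
            out[ok] = np.einsum("ni,nid->nd", N, self.u[self.space.tri6[el[ok]]])
        return out

    def speed(self, pts) -> np.ndarray:
        return np.linalg.norm(self.velocity(pts), axis=1)

    def pressure(self, pts) -> np.ndarray:
        el, ok, lam = self._locate(pts)
        out = np.full(len(el), np.nan)
        if ok.any():
            out[ok] = np.einsum("nk,nk->n", lam[ok], self.p[self.mesh.triangles[el[ok]]])
        return out

    def velocity_gradient(self, pts) -> np.ndarray:
        """grad u as (n, 2, 2) with entry [c, d] = d u_c / d x_d; NaN outside."""
        el, ok, lam = self._locate(pts)
        out = np.full((len(el), 2, 2), np.nan)
        if ok.any():
            _, dN = _p2_basis(lam[ok])
            g = np.einsum("nik,nkd->nid", dN, self.space.dlam[el[ok]])
            out[ok] = np.einsum("nid,nic->ncd", g, self.u[self.space.tri6[el[ok]]])
        return out

    def shear_rate(self, pts) -> np.ndarray:
        """gamma_dot = sqrt(2 D:D); NaN outside the fluid."""
        gu = self.velocity_gradient(pts)
        D = 0.5 * (gu + np.swapaxes(gu, 1, 2))
        return np.sqrt(2.0 * np.einsum("ncd,ncd->n", D, D))

    # -- element-level quadrature values (for integrals) --------------------
    def _quad_speed(self) -> np.ndarray:
        N, _ = _p2_basis(_QLAM)
        uq = np.einsum("qi,tid->tqd", N, self.u[self.space.tri6])
        return np.linalg.norm(uq, axis=2)

    def _quad_shear_rate(self) -> np.ndarray:
        g = self.space.shape_gradients(_QLAM)                 # (nt, nq, 6, 2)
        gu = np.einsum("tqid,tic->tqcd", g, self.u[self.space.tri6])
        D = 0.5 * (gu + np.swapaxes(gu, 2, 3))
        return np.sqrt(2.0 * np.einsum("tqcd,tqcd->tq", D, D))

    # -- boundary fluxes -----------------------------------------------------
    def boundary_flux(self, tag: str) -> float:
        """Signed outward 2D flux [m^2/s] through the tagged boundary."""
        edges = self.mesh.edge_tags.get(tag)
        if edges is None or len(edges) == 0:
            raise ValueError(f"no boundary edges tagged {tag!r}")
        a, b = edges[:, 0], edges[:, 1]
        pa, pb = self.mesh.points[a], self.mesh.points[b]
        mid = self.space.midpoint_node(a, b)
        t = pb - pa
        normal = np.column_stack([t[:, 1], -t[:, 0]])  # length = edge length
        owner = self._owner_triangle(edges)
        cent = self.mesh.points[self.mesh.triangles[owner]].mean(axis=1)
        flip = np.einsum("nd,nd->n", normal, 0.5 * (pa + pb) - cent) < 0
        normal[flip] *= -1.0
        un = (np.einsum("nd,nd->n", self.u[a], normal)
              + 4 * np.einsum("nd,nd->n", self.u[mid], normal)
              + np.einsum("nd,nd->n", self.u[b], normal)) / 6.0
        return float(un.sum())

    def _owner_triangle(self, edges: np.ndarray) -> np.ndarray:
        tris = self.mesh.triangles
        all_e = np.sort(np.concatenate(
            [tris[:, [1, 2]], tris[:, [2, 0]], tris[:, [0, 1]]]), axis=1)
        owner = np.tile(np.arange(len(tris)), 3)
        key = all_e[:, 0].astype(np.int64) * self.mesh.n_points + all_e[:, 1]
        order = np.argsort(key)
        key, owner = key[order], owner[order]
        ekey = np.sort(edges, axis=1)
        ekey = ekey[:, 0].astype(np.int64) * self.mesh.n_points + ekey[:, 1]
        return owner[np.searchsorted(key, ekey)]

    def divergence_residual(self) -> float:
        """Weak incompressibility residual relative to its absolute parts."""
        Bx, By = _div_matrices(self.space)
        r = Bx @ self.u[:, 0] + By @ self.u[:, 1]
        scale = abs(Bx) @ abs(self.u[:, 0]) + abs(By) @ abs(self.u[:, 1])
        denom = np.linalg.norm(scale)
        return float(np.linalg.norm(r) / denom) if denom > 0 else 0.0


@dataclass
class ShearField:
    """Viscous shear-stress magnitude tau = mu sqrt(2 D:D) [Pa]."""

    flow: FlowField

    def tau(self, pts) -> np.ndarray:
        return self.flow.fluid.dynamic_viscosity * self.flow.shear_rate(pts)

    def tau_dyne_cm2(self, pts) -> np.ndarray:
        return self.tau(pts) * PA_TO_DYNE_CM2

    @property
    def mesh(self):
        return self.flow.mesh


def shear_stress_field(flow: FlowField) -> ShearField:
    return ShearField(flow)


@dataclass(frozen=True)
class FlowDiagnostics:
    reynolds: float
    characteristic_length: float
    average_velocity: float
    inlet_flux: float
    outlet_flux: float
    divergence_residual: float

    @property
    def flux_imbalance(self) -> float:
        """|inlet + outlet| / |inlet| (outward-signed fluxes cancel when balanced)."""
        return abs(self.inlet_flux + self.outlet_flux) / max(abs(self.inlet_flux), 1e-300)


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------

def _stiffness_matrix(space: P2Space) -> sp.csr_matrix:
    g = space.shape_gradients(_QLAM)                          # (nt, nq, 6, 2)
    w = _QW[None, :] * space.area[:, None]                    # (nt, nq)
    Ae = np.einsum("tq,tqid,tqjd->tij", w, g, g)
    rows = np.repeat(space.tri6, 6, axis=1)
    cols = np.tile(space.tri6, (1, 6))
    n = space.n_nodes
    return sp.coo_matrix((Ae.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)).tocsr()


def _div_matrices(space: P2Space):
    g = space.shape_gradients(_QLAM)
    w = _QW[None, :] * space.area[:, None]
    Bxe = np.einsum("tq,qk,tqi->tki", w, _QLAM, g[..., 0])
    Bye = np.einsum("tq,qk,tqi->tki", w, _QLAM, g[..., 1])
    rows = np.repeat(space.mesh.triangles, 6, axis=1)         # (nt, 18)
    cols = np.tile(space.tri6, (1, 3))
    nv, n2 = space.mesh.n_points, space.n_nodes
    Bx = sp.coo_matrix((Bxe.ravel(), (rows.ravel(), cols.ravel())), shape=(nv, n2)).tocsr()
    By = sp.coo_matrix((Bye.ravel(), (rows.ravel(), cols.ravel())), shape=(nv, n2)).tocsr()
    return Bx, By


def _dirichlet_nodes(mesh: Mesh, space: P2Space, tag: str) -> np.ndarray:
    edges = mesh.edge_tags.get(tag)
    if edges is None or len(edges) == 0:
        return np.empty(0, dtype=int)
    mids = space.midpoint_node(edges[:, 0], edges[:, 1])
    return np.unique(np.concatenate([edges.ravel(), mids]))


def solve_stokes(mesh: Mesh, U_in: float, fluid: FluidProperties | None = None,
                 inlet_profile: str = "uniform", inlet_tag: str = "inlet",
                 wall_tag: str = "wall") -> FlowField:
    """Solve creeping flow: inflow ``U_in``, no-slip walls, do-nothing outlet.

    ``inlet_profile='uniform'`` imposes a plug of magnitude ``U_in`` along +x
    (the chip's boundary condition); ``'parabolic'`` imposes a fully developed
    plane-Poiseuille profile with *mean* ``U_in``, which the P2 element
    represents exactly.  Walls win at inlet/wall corner nodes.
    """
    if U_in < 0:
        raise ValueError("U_in must be >= 0")
    fluid = fluid or FluidProperties()
    space = P2Space(mesh)
    mu = fluid.dynamic_viscosity

    A = _stiffness_matrix(space) * mu
    Bx, By = _div_matrices(space)
    n2, nv = space.n_nodes, mesh.n_points
    K = sp.bmat([[A, None, -Bx.T],
                 [None, A, -By.T],
                 [-Bx, -By, None]], format="csr")

    inlet_nodes = _dirichlet_nodes(mesh, space, inlet_tag)
    wall_nodes = _dirichlet_nodes(mesh, space, wall_tag)
    if len(inlet_nodes) == 0:
        raise SolverError("mesh has no inlet-tagged boundary")
    inlet_only = np.setdiff1d(inlet_nodes, wall_nodes)

    g = np.zeros(2 * n2 + nv)
    if inlet_profile == "uniform":
        g[inlet_only] = U_in
    elif inlet_profile == "parabolic":
        y = space.nodes[inlet_nodes, 1]
        yc, half = 0.5 * (y.min() + y.max()), 0.5 * (y.max() - y.min())
        eta = (space.nodes[inlet_only, 1] - yc) / half
        g[inlet_only] = 1.5 * U_in * (1.0 - eta ** 2)
    else:
        raise ValueError(f"unknown inlet_profile {inlet_profile!r}")

    fixed = np.zeros(2 * n2 + nv, dtype=bool)
    fixed[np.concatenate([inlet_nodes, wall_nodes])] = True
    fixed[n2 + np.concatenate([inlet_nodes, wall_nodes])] = True

    free = ~fixed
    rhs = -(K[:, fixed] @ g[fixed])[free]
    Kff = K[free][:, free].tocsc()
    try:
        xf = spla.spsolve(Kff, rhs)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(xf)):
        raise SolverError("solver returned non-finite values (singular system?)")
    resid = np.linalg.norm(Kff @ xf - rhs)
    scale = np.linalg.norm(rhs)
    rel = float(resid / scale) if scale > 0 else 0.0

    x = g.copy()
    x[free] = xf
    u = np.column_stack([x[:n2], x[n2:2 * n2]])
    return FlowField(mesh=mesh, space=space, u=u, p=x[2 * n2:], inlet_velocity=U_in,
                     fluid=fluid, meta={"linear_residual": rel,
                                        "solver": "superlu_direct"})


def scale_solution(flow: FlowField, factor: float) -> FlowField:
    """Exact linear rescaling of a Stokes solution (velocity, pressure, shear)."""
    if not np.isfinite(factor):
        raise ValueError("factor must be finite")
    return replace(flow, u=flow.u * factor, p=flow.p * factor,
                   inlet_velocity=flow.inlet_velocity * factor,
                   meta={**flow.meta, "scaled_by": factor}, _finder=flow._finder)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def _element_mask(mesh: Mesh, region) -> np.ndarray:
    if region is None or (isinstance(region, str) and region == "all"):
        return np.ones(mesh.n_triangles, dtype=bool)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        return region
    cent = mesh.points[mesh.triangles].mean(axis=1)
    return shapely.contains_xy(region, cent[:, 0], cent[:, 1])


def surface_average(fld, region=None) -> float:
    """Area-weighted mean over element quadrature.

    For a :class:`FlowField` the averaged quantity is the velocity magnitude
    [m/s]; for a :class:`ShearField` it is tau [Pa].  ``region`` may be None
    (whole domain), a shapely polygon, or a boolean element mask.
    """
    flow = fld.flow if isinstance(fld, ShearField) else fld
    mask = _element_mask(flow.mesh, region)
    if not mask.any():
        raise ValueError("empty averaging region")
    if isinstance(fld, ShearField):
        vals = flow.fluid.dynamic_viscosity * flow._quad_shear_rate()
    else:
        vals = flow._quad_speed()
    w = _QW[None, :] * flow.space.area[:, None]
    return float((vals[mask] * w[mask]).sum() / w[mask].sum())


def surface_max(fld, region=None):
    """(max value, location [m]) over quadrature and nodal points."""
    flow = fld.flow if isinstance(fld, ShearField) else fld
    mask = _element_mask(flow.mesh, region)
    if not mask.any():
        raise ValueError("empty region")
    pts_q = flow.space.quad_points()[mask]
    if isinstance(fld, ShearField):
        vals = flow.fluid.dynamic_viscosity * flow._quad_shear_rate()[mask]
    else:
        vals = flow._quad_speed()[mask]
    flat = vals.ravel()
    i = int(np.argmax(flat))
    best, loc = float(flat[i]), pts_q.reshape(-1, 2)[i]
    if not isinstance(fld, ShearField):
        # velocity is continuous: nodal values may exceed quadrature values
        nodes = np.unique(flow.space.tri6[mask])
        sp_nodes = np.linalg.norm(flow.u[nodes], axis=1)
        j = int(np.argmax(sp_nodes))
        if sp_nodes[j] > best:
            best, loc = float(sp_nodes[j]), flow.space.nodes[nodes[j]]
    return best, loc


@dataclass(frozen=True)
class CutLine:
    """Straight sampling line; presets mirror the standard figure cuts."""

    start: tuple
    end: tuple
    n: int = 200

    def __post_init__(self):
        if tuple(self.start) == tuple(self.end):
            raise ValueError("cut line start and end coincide")

    def points(self) -> np.ndarray:
        t = np.linspace(0.0, 1.0, self.n)[:, None]
        return np.asarray(self.start, float) + t * (np.asarray(self.end, float)
                                                    - np.asarray(self.start, float))

    @property
    def arclength(self) -> np.ndarray:
        d = float(np.hypot(*(np.subtract(self.end, self.start))))
        return np.linspace(0.0, d, self.n)

    @staticmethod
    def presets(geom, n: int = 400) -> dict:
        """Named cut lines on a chip geometry (chip frame, metres):

        - ``inlet_centerline``: along the input channel and header, y = 0
        - ``channel_centerline``: along the central microchannel, stopping
          before the terminal microposts
        - ``transverse_8_channels``: across eight consecutive microchannels
        - ``gap_vertical``: across the 2 um free gap beside a micropost
        - ``channel_diagonal``: corner-to-corner across the central channel
        """
        p = geom.params
        k_mid = p.n_channels // 2
        y_mid = float(geom.channel_center_y(k_mid))
        x_mid = 0.5 * (geom.x_channels_start + geom.first_post_tip_x)
        first_center_x = (geom.first_post_tip_x + p.micropost_axial_diagonal / 2
                          if p.microposts_per_channel else geom.x_channels_end)
        k_lo = max(p.n_channels // 2 - 4, 0)
        k_hi = min(k_lo + 7, p.n_channels - 1)
        return {
            "inlet_centerline": CutLine((0.0, 0.0), (geom.x_channels_start, 0.0), n),
            "channel_centerline": CutLine((geom.x_channels_start, y_mid),
                                          (geom.first_post_tip_x, y_mid), n),
            "transverse_8_channels": CutLine(
                (x_mid, float(geom.channel_center_y(k_lo)) - p.channel_width / 2),
                (x_mid, float(geom.channel_center_y(k_hi)) + p.channel_width / 2), n),
            "gap_vertical": CutLine(
                (first_center_x, y_mid + p.micropost_transverse_diagonal / 2),
                (first_center_x, y_mid + p.channel_width / 2), n),
            "channel_diagonal": CutLine(
                (geom.x_channels_start, y_mid - p.channel_width / 2),
                (geom.first_post_tip_x, y_mid + p.channel_width / 2), n),
        }


@dataclass
class Profile:
    line: CutLine
    points: np.ndarray
    values: np.ndarray

    @property
    def s(self) -> np.ndarray:
        return self.line.arclength


def sample_cutline(fld, line: CutLine, quantity: str | None = None) -> Profile:
    """Point-evaluate a field along a line.

    ``fld`` may be a FlowField (speed), a ShearField (tau), or any object
    exposing ``speed(pts)`` / ``tau(pts)`` (the composite chip model).
    Values are NaN where the line leaves the fluid (e.g. inside a micropost).
    """
    pts = line.points()
    if isinstance(fld, ShearField) or quantity == "shear":
        vals = fld.tau(pts)
    else:
        vals = fld.speed(pts)
    if np.all(np.isnan(vals)):
        raise ValueError("cut line lies entirely outside the fluid domain")
    return Profile(line=line, points=pts, values=vals)


def diagnostics(flow: FlowField, l: float) -> FlowDiagnostics:
    """Reynolds number and conservation checks for a solved field."""
    if l <= 0:
        raise ValueError("characteristic length must be > 0")
    U = surface_average(flow)
    return FlowDiagnostics(
        reynolds=reynolds_number(flow.fluid.density, U, l, flow.fluid.dynamic_viscosity),
        characteristic_length=l, average_velocity=U,
        inlet_flux=flow.boundary_flux("inlet"),
        outlet_flux=flow.boundary_flux("outlet"),
        divergence_residual=flow.divergence_residual())


def mesh_convergence_study(geom, h_sequence, U_in: float,
                           fluid: FluidProperties | None = None,
                           h_micropost_ratio: float = 0.1,
                           mesh_fn=None, tol: float = 0.01) -> pd.DataFrame:
    """Refinement study of surface-average shear and velocity.

    ``h_sequence`` must be strictly decreasing.  The returned table carries
    the relative change between consecutive levels and a converged flag
    (both changes < ``tol``).
    """
    from .meshing import generate_mesh
    h_sequence = list(h_sequence)
    if any(b >= a for a, b in zip(h_sequence, h_sequence[1:])):
        raise ValueError("h_sequence must be strictly decreasing")
    rows = []
    for h in h_sequence:
        mesh = (mesh_fn(h) if mesh_fn is not None
                else generate_mesh(geom, h, h * h_micropost_ratio))
        flow = solve_stokes(mesh, U_in, fluid)
        rows.append({"h": h, "n_elements": mesh.n_triangles,
                     "shear_avg_pa": surface_average(shear_stress_field(flow)),
                     "vel_avg_m_s": surface_average(flow)})
    df = pd.DataFrame(rows)
    df["shear_rel_change"] = df["shear_avg_pa"].diff().abs() / df["shear_avg_pa"]
    df["vel_rel_change"] = df["vel_avg_m_s"].diff().abs() / df["vel_avg_m_s"]
    df["converged"] = (df["shear_rel_change"] < tol) & (df["vel_rel_change"] < tol)
    return df


def field_from_function(mesh: Mesh, fn: Callable, fluid: FluidProperties | None = None,
                        U_ref: float = 0.0) -> FlowField:
    """Build a FlowField from an analytic velocity function (tests/oracles)."""
    space = P2Space(mesh)
    u = np.asarray(fn(space.nodes), dtype=float)
    return FlowField(mesh=mesh, space=space, u=u, p=np.zeros(mesh.n_points),
                     inlet_velocity=U_ref, fluid=fluid or FluidProperties(),
                     meta={"manufactured": True})
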