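"""Hydraulic-resistance network model of the chip.

A desk-fast reduced model: each channel segment is an edge with 2D (per unit
depth) lubrication resistance ``R = 12 mu L / w^3`` so that ``dP = R q`` for
a 2D flux ``q`` [m^2/s].  Kirchhoff balance at the junctions partitions the
imposed total flux among the parallel microchannels; closed-form plane
Poiseuille profiles then give per-channel velocity and wall-shear estimates.
The network serves both as a design tool and as an independent oracle for
the finite-element solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["ChannelNetwork", "hydraulic_resistance_2d", "partition_flow",
           "poiseuille_fields", "fill_time_estimate"]


def hydraulic_resistance_2d(mu: float, length: float, width: float) -> float:
    """Per-unit-depth lubrication resistance R = 12 mu L / w^3 [Pa s / m^2]."""
    if length <= 0 or width <= 0 or mu <= 0:
        raise ValueError("mu, length and width must be > 0")
    return 12.0 * mu * length / width ** 3


@dataclass
class ChannelNetwork:
    """Directed edge list between junction nodes; node 0 convention is free.

    ``inlet`` and ``outlet`` are node ids; ``resistances`` are per-edge
    positive values.  Parallel microchannel arrays are a special case built
    by :meth:`parallel`.
    """

    n_nodes: int
    edges: np.ndarray                       # (n_e, 2) node ids
    resistances: np.ndarray                 # (n_e,)
    inlet: int = 0
    outlet: int = 1

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.resistances = np.asarray(self.resistances, dtype=float)
        if np.any(self.resistances <= 0):
            raise ValueError("all resistances must be > 0")
        if len(self.edges) != len(self.resistances):
            raise ValueError("edges and resistances length mismatch")

    @classmethod
    def parallel(cls, widths, lengths, mu: float = 1e-3,
                 extra_series: float = 0.0) -> "ChannelNetwork":
        """n channels from a shared inlet node to a shared outlet node.

        ``extra_series`` adds a per-channel series resistance (e.g. the
        micropost row, calibrated once from a local FEM patch)."""
        widths = np.atleast_1d(np.asarray(widths, dtype=float))
        lengths = np.broadcast_to(np.asarray(lengths, dtype=float), widths.shape)
        R = np.array([hydraulic_resistance_2d(mu, L, w) + extra_series
                      for w, L in zip(widths, lengths)])
        edges = np.column_stack([np.zeros(len(R), int), np.ones(len(R), int)])
        return cls(n_nodes=2, edges=edges, resistances=R, inlet=0, outlet=1)

    def laplacian(self) -> sp.csr_matrix:
        g = 1.0 / self.resistances
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([i, j, j, i])
        vals = np.concatenate([g, g, -g, -g])
        return sp.coo_matrix((vals, (rows, cols)),
                             shape=(self.n_nodes, self.n_nodes)).tocsr()


def partition_flow(net: ChannelNetwork, Q_total: float) -> np.ndarray:
    """Per-edge 2D fluxes [m^2/s] for an imposed total flux.

    Solves the nodal-pressure system L p = s with the outlet grounded; the
    solution is the unique dissipation minimiser.  Raises if the network is
    disconnected between inlet and outlet.
    """
    n = net.n_nodes
    from scipy.sparse.csgraph import connected_components
    adj = sp.coo_matrix((np.ones(len(net.edges)),
                         (net.edges[:, 0], net.edges[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    if labels[net.inlet] != labels[net.outlet]:
        raise RuntimeError("network is disconnected between inlet and outlet")
    s = np.zeros(n)
    s[net.inlet] = Q_total
    s[net.outlet] = -Q_total
    keep = np.arange(n) != net.outlet
    A = net.laplacian()[keep][:, keep].tocsc()
    try:
        p_red = spla.spsolve(A, s[keep])
    except Exception as exc:
        raise RuntimeError(f"network solve failed: {exc}") from exc
    if not np.all(np.isfinite(p_red)):
        raise RuntimeError("network solve produced non-finite pressures")
    p = np.zeros(n)
    p[keep] = p_red
    q = (p[net.edges[:, 0]] - p[net.edges[:, 1]]) / net.resistances
    # Kirchhoff sanity: net outflow at inlet equals Q_total
    if Q_total != 0 and not np.isfinite(q).all():
        raise RuntimeError("network is disconnected between inlet and outlet")
    return q


def poiseuille_fields(w: float, U_mean: float, mu: float = 1e-3):
    """Closed-form plane-Poiseuille quantities for a channel of width w.

    Returns ``(profile, tau_wall, tau_mean)`` where ``profile(y)`` is
    ``1.5 U_mean (1 - (2y/w)^2)`` on ``|y| <= w/2``, ``tau_wall = 6 mu
    U_mean / w`` and ``tau_mean = 3 mu U_mean / w`` (cross-width mean of
    |tau|).
    """
    if w <= 0:
        raise ValueError("width must be > 0")

    def profile(y):
        y = np.asarray(y, dtype=float)
        return 1.5 * U_mean * (1.0 - (2.0 * y / w) ** 2)

    tau_wall = 6.0 * mu * U_mean / w
    tau_mean = 3.0 * mu * U_mean / w
    return profile, tau_wall, tau_mean


def fill_time_estimate(net: ChannelNetwork, Q_total: float, channel_length: float,
                       widths=None) -> float:
    """Advective first-arrival estimate L / (1.5 U_mean) for the fastest channel.

    ``widths`` must match the network's parallel channel edges (defaults to
    equal widths are not assumed: pass them explicitly for mixed arrays).
    """
    if Q_total <= 0 or channel_length <= 0:
        raise ValueError("Q_total and channel_length must be > 0")
    q = partition_flow(net, Q_total)
    if widths is None:
        raise ValueError("channel widths are required to convert flux to velocity")
    widths = np.broadcast_to(np.asarray(widths, dtype=float), q.shape)
    U_mean = q / widths
    return float(np.min(channel_length / (1.5 * np.max(U_mean))))
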