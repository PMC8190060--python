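"""Lagrangian cell transport in the solved chip flow.

Cells are carried by the steady creeping flow and experience Stokes drag
``F_d = 3 pi d_p mu (V - V_p)``.  Their Stokes relaxation time
``rho_p d_p^2 / (18 mu)`` is microseconds while transit times are seconds,
so the default mode is the tracer limit ``dx/dt = V(x)`` integrated with
RK4; an inertial mode integrates the drag ODE with an exponential
(unconditionally stable) update for cross-checking the tracer assumption.

Trapping: the terminal microposts leave ``side_gap`` of free width per side,
so a cell of diameter larger than twice the side gap cannot pass.  Such a
cell is marked trapped when its centre crosses a capture line one radius
upstream of the first micropost tip; smaller cells pass through the gaps.
An optional queueing mode stacks later arrivals one diameter upstream of the
cell in front.  Statuses partition the released population at all times:
released = in_domain + trapped + exited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.ops import nearest_points
from scipy import stats as sps

from .composite import ChipFlowEvaluator

__all__ = [
    "CellPopulation", "Trajectories", "DEFAULT_CV_SCHEDULE", "CELL_DENSITY",
    "sample_population", "release_positions", "stokes_drag", "relaxation_time",
    "trace", "first_arrival_time", "position_histogram", "channel_occupancy",
    "mean_cell_speed",
]

#: typical mammalian-cell mass density [kg/m^3]
CELL_DENSITY = 1050.0

#: coefficient-of-variation defaults per mean diameter: larger cell types
#: show visibly wider size distributions in culture
DEFAULT_CV_SCHEDULE = {8e-6: 0.10, 12e-6: 0.15, 14e-6: 0.17, 19e-6: 0.22}

IN_DOMAIN, TRAPPED, EXITED, PENDING = 0, 1, 2, 3


@dataclass
class CellPopulation:
    """Sampled cell diameters plus the physical scenario they represent."""

    diameters: np.ndarray                   # (n,) [m]
    mean_diameter: float
    cv: float
    seed: int
    cell_density: float = CELL_DENSITY      # [kg/m^3], used in inertial mode
    concentration: float | None = None      # cells per m^3 of medium

    @property
    def n(self) -> int:
        return len(self.diameters)


def sample_population(n: int, mean_d: float, cv: float | None = None,
                      seed: int = 0, cell_density: float = CELL_DENSITY,
                      concentration: float | None = None) -> CellPopulation:
    """Truncated-normal (+/- 3 sigma) cell diameters, deterministic per seed.

    ``cv`` defaults to the schedule keyed by the mean diameter.  ``cv >= 1/3``
    is rejected: the truncation would then visibly distort the mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_d <= 0:
        raise ValueError("mean_d must be > 0")
    if cv is None:
        cv = next((c for d, c in DEFAULT_CV_SCHEDULE.items()
                   if abs(mean_d - d) <= 1e-9 * d), 0.15)
    if not 0 <= cv < 1.0 / 3.0:
        raise ValueError("cv must satisfy 0 <= cv < 1/3")
    rng = np.random.default_rng(seed)
    if cv == 0:
        d = np.full(n, mean_d)
    else:
        d = sps.truncnorm.rvs(-3.0, 3.0, loc=mean_d, scale=cv * mean_d,
                              size=n, random_state=rng)
    return CellPopulation(diameters=d, mean_diameter=mean_d, cv=cv, seed=seed,
                          cell_density=cell_density, concentration=concentration)


def release_positions(pop: CellPopulation, evaluator: ChipFlowEvaluator,
                      seed: int = 0, release_times=None):
    """Random release at the chip inlet.

    Positions are uniform in y over the inlet segment at the inlet face
    (x = 0); the initial velocity couples to the local fluid velocity.
    ``release_times`` defaults to an instantaneous batch at t = 0.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    w = evaluator.params.inlet_width
    n = pop.n
    y = rng.uniform(-w / 2, w / 2, n)
    # keep the cell centre inside the fluid by its radius
    y = np.clip(y, -w / 2 + pop.diameters / 2, w / 2 - pop.diameters / 2)
    pos = np.column_stack([np.zeros(n), y])
    vel = evaluator.velocity(pos)
    t0 = np.zeros(n) if release_times is None else np.broadcast_to(
        np.asarray(release_times, float), (n,)).copy()
    return pos, vel, t0


def stokes_drag(d_p, mu, V, V_p) -> np.ndarray:
    """Stokes drag force [N]: F = 3 pi d_p mu (V - V_p); no lift or Magnus."""
    d_p = np.asarray(d_p, dtype=float)
    if np.any(d_p <= 0):
        raise ValueError("particle diameter must be > 0")
    return 3.0 * np.pi * d_p * mu * (np.asarray(V, float) - np.asarray(V_p, float))


def relaxation_time(d_p, rho_p, mu) -> np.ndarray:
    """Stokes relaxation time rho_p d_p^2 / (18 mu) [s]."""
    d_p = np.asarray(d_p, dtype=float)
    if np.any(d_p < 0) or rho_p <= 0 or mu <= 0:
        raise ValueError("arguments must be positive")
    return rho_p * d_p ** 2 / (18.0 * mu)


@dataclass
class Trajectories:
    """Frame-sampled particle histories plus event bookkeeping."""

    times: np.ndarray                       # (n_frames,)
    positions: np.ndarray                   # (n_frames, n, 2); NaN after exit
    status: np.ndarray                      # (n_frames, n) int8
    diameters: np.ndarray
    release_times: np.ndarray
    event_times: np.ndarray                 # trap/exit time, NaN if none
    evaluator: ChipFlowEvaluator = field(repr=False, default=None)
    wall_projections: int = 0
    mode: str = "tracer"
    seed: int | None = None
    drag: np.ndarray | None = field(default=None, repr=False)  # F_d per frame, inertial mode

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    def counts(self, frame: int) -> dict:
        s = self.status[frame]
        return {"in_domain": int((s == IN_DOMAIN).sum()),
                "trapped": int((s == TRAPPED).sum()),
                "exited": int((s == EXITED).sum()),
                "pending": int((s == PENDING).sum())}

    def every(self, step: int) -> "Trajectories":
        """View keeping every ``step``-th cell (a sparser imaging scene)."""
        from dataclasses import replace
        idx = np.arange(0, self.n, step)
        return replace(self, positions=self.positions[:, idx],
                       status=self.status[:, idx], diameters=self.diameters[idx],
                       release_times=self.release_times[idx],
                       event_times=self.event_times[idx],
                       drag=None if self.drag is None else self.drag[:, idx])

    def frame_at(self, t: float) -> int:
        return int(np.clip(np.searchsorted(self.times, t + 1e-12) - 1,
                           0, len(self.times) - 1))


def _rk4_step(vel_fn, x, dt):
    k1 = vel_fn(x)
    k2 = vel_fn(x + 0.5 * dt * k1)
    k3 = vel_fn(x + 0.5 * dt * k2)
    k4 = vel_fn(x + dt * k3)
    return x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def trace(evaluator: ChipFlowEvaluator, pop: CellPopulation, dt: float = 2e-3,
          t_end: float = 20.0, mode: str = "tracer", seed: int = 0,
          fps: float = 30.0, queueing: bool = False,
          stop_at_first_arrival: bool = False,
          release_span: float = 0.0) -> Trajectories:
    """Trace a released population through the chip flow.

    Frames are stored on the 1/fps grid (dt is snapped to divide the frame
    interval).  Event times (trapping, exit) are linearly interpolated within
    the step.  In the micropost region the step is subdivided so no particle
    moves more than a quarter of the side gap per substep.

    Release: ``release_span = 0`` is an instantaneous batch at t = 0;
    a positive span spreads release times uniformly over ``[0, span]``,
    emulating steady syringe injection.  Cells not yet released carry the
    PENDING status and do not count as part of the released set.

    Each cell carries its streamline label (the cumulative flux fraction at
    the uniform inflow face); the manifold-to-array junction assigns the
    channel and the in-channel transverse position from that label, which
    keeps trajectories exactly linear in the inlet velocity.

    ``mode='inertial'`` integrates the first-order Stokes-number correction
    ``dx/dt = V - tau_p (V . grad) V`` (the slow-manifold limit of the drag
    ODE, valid for the microsecond relaxation times of cells) and records
    the implied drag force at every frame.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be > 0")
    if mode not in ("tracer", "inertial"):
        raise ValueError("mode must be 'tracer' or 'inertial'")
    g, p = evaluator.geom, evaluator.params
    frame_dt = 1.0 / fps
    n_sub_frame = max(int(np.ceil(frame_dt / dt)), 1)
    dt = frame_dt / n_sub_frame
    n_frames = int(np.floor(t_end * fps)) + 1

    rng_span = np.random.default_rng(seed + 1)
    rel_times = (rng_span.uniform(0.0, release_span, pop.n)
                 if release_span > 0 else None)
    pos, vel, t_rel = release_positions(pop, evaluator, seed,
                                        release_times=rel_times)
    n = pop.n
    x = pos.copy()
    # streamline label: flux fraction at the uniform inflow face
    w_in = p.inlet_width
    s_frac = np.clip((pos[:, 1] + w_in / 2) / w_in, 0.0, 1.0)
    status = np.full(n, PENDING if release_span > 0 else IN_DOMAIN, dtype=np.int8)
    status[t_rel <= 0.0] = IN_DOMAIN
    event_t = np.full(n, np.nan)
    tau_p = relaxation_time(pop.diameters, pop.cell_density,
                            evaluator.model.fluid.dynamic_viscosity)
    trap_d = pop.diameters > 2 * p.micropost_side_gap
    front_x = np.full(p.n_channels, np.inf)   # queueing: front cell per channel
    front_d = np.zeros(p.n_channels)          # its diameter

    posts_union = None
    if p.microposts_per_channel > 0:
        posts_union = shapely.unary_union(_patch_posts(p))
        shapely.prepare(posts_union)

    frames_pos = np.full((n_frames, n, 2), np.nan)
    frames_status = np.zeros((n_frames, n), dtype=np.int8)
    frames_pos[0][status != PENDING] = x[status != PENDING]
    frames_status[0] = status
    times = np.arange(n_frames) * frame_dt
    drag = np.full((n_frames, n, 2), np.nan) if mode == "inertial" else None
    wall_proj = 0

    def fluid_v(pts):
        return np.nan_to_num(evaluator.velocity(pts))

    def advective_accel(pts):
        """(V . grad) V by central finite differences; the correction is
        suppressed where the stencil leaves the fluid (walls dominate the
        dynamics there and the drag correction is negligible anyway)."""
        d = 1e-7
        stencil = [evaluator.velocity(pts + off)
                   for off in ([0, 0], [d, 0], [-d, 0], [0, d], [0, -d])]
        ok = np.all([np.isfinite(s).all(axis=1) for s in stencil], axis=0)
        v, vxp, vxm, vyp, vym = (np.nan_to_num(s) for s in stencil)
        acc = (v[:, 0:1] * (vxp - vxm) + v[:, 1:2] * (vyp - vym)) / (2 * d)
        acc[~ok] = 0.0
        return acc

    t = 0.0
    for fi in range(1, n_frames):
        for _ in range(n_sub_frame):
            born = (status == PENDING) & (t_rel <= t)
            if born.any():
                status[born] = IN_DOMAIN
            act = status == IN_DOMAIN
            if not act.any():
                t += dt
                continue
            xa = x[act]
            ids = np.where(act)[0]

            # substep control in the micropost region
            in_patch = (xa[:, 0] >= evaluator.x_patch) & ~trap_d[ids]
            nsub = np.ones(len(xa), dtype=int)
            if in_patch.any():
                sp_loc = np.linalg.norm(fluid_v(xa[in_patch]), axis=1)
                nsub[in_patch] = np.maximum(1, np.ceil(
                    sp_loc * dt / (0.25 * p.micropost_side_gap)).astype(int))
            new = np.empty_like(xa)
            for ns in np.unique(nsub):
                m = nsub == ns
                xi = xa[m]
                h = dt / ns
                if mode == "tracer":
                    fn = fluid_v
                else:
                    tpm = tau_p[ids[m], None]

                    def fn(pts, tpm=tpm):
                        return fluid_v(pts) - tpm * advective_accel(pts)
                for _ in range(ns):
                    xi = _rk4_step(fn, xi, h)
                new[m] = xi
            x_old, x_new = xa, new

            # header -> channel snap on the release streamline label
            x_arr = g.x_channels_start
            cross = (x_old[:, 0] < x_arr) & (x_new[:, 0] >= x_arr)
            if cross.any():
                k, eta_c = evaluator.channel_target(s_frac[ids[cross]])
                yc = g.channel_center_y(k)
                # advance the remainder of the step inside the channel
                frac = (x_arr - x_old[cross, 0]) / np.maximum(
                    x_new[cross, 0] - x_old[cross, 0], 1e-300)
                rem = dt * (1.0 - np.clip(frac, 0, 1))
                eta_c = np.clip(eta_c, -1 + 1e-9, 1 - 1e-9)
                uc = 1.5 * evaluator.Uc * (1 - eta_c ** 2)
                x_new[cross, 0] = x_arr + uc * rem
                x_new[cross, 1] = yc + eta_c * p.channel_width / 2

            # collection end -> outlet header snap (same streamline label)
            x_out = g.x_collection_end
            cross = (x_old[:, 0] < x_out) & (x_new[:, 0] >= x_out) \
                & (status[ids] == IN_DOMAIN)
            if cross.any():
                w_loc = evaluator.outlet_header_width(x_new[cross, 0])
                eta_h = _eta_of_fraction(s_frac[ids[cross]])
                x_new[cross, 1] = eta_h * w_loc / 2

            # trapping at the capture line (one radius upstream of first post)
            if p.microposts_per_channel > 0:
                cap_geom = g.capture_x(0.0)
                radius = pop.diameters[ids] / 2
                k_now = g.channel_of(x_new[:, 1], None)
                kcl = np.clip(k_now, 0, p.n_channels - 1)
                cap = cap_geom - radius
                if queueing:
                    queued = np.isfinite(front_x[kcl])
                    cap = np.where(queued,
                                   front_x[kcl] - (pop.diameters[ids] + front_d[kcl]) / 2,
                                   cap)
                hit = trap_d[ids] & (k_now >= 0) & (x_new[:, 0] >= cap)
                if hit.any():
                    frac = np.clip((cap[hit] - x_old[hit, 0])
                                   / np.maximum(x_new[hit, 0] - x_old[hit, 0], 1e-300), 0, 1)
                    event_t[ids[hit]] = t + dt * frac
                    x_new[hit, 0] = cap[hit]
                    status[ids[hit]] = TRAPPED
                    if queueing:
                        for kk, xx, dd in zip(kcl[hit], cap[hit], pop.diameters[ids[hit]]):
                            if xx < front_x[kk]:
                                front_x[kk] = xx
                                front_d[kk] = dd

            # exit through the chip outlet
            gone = x_new[:, 0] >= g.x_total
            gone &= status[ids] == IN_DOMAIN
            if gone.any():
                frac = np.clip((g.x_total - x_old[gone, 0])
                               / np.maximum(x_new[gone, 0] - x_old[gone, 0], 1e-300), 0, 1)
                event_t[ids[gone]] = t + dt * frac
                status[ids[gone]] = EXITED
                x_new[gone] = np.nan

            # keep particles out of solid posts (numerical safety)
            if posts_union is not None:
                live = status[ids] == IN_DOMAIN
                inpost = np.zeros(len(x_new), dtype=bool)
                patch_zone = live & (x_new[:, 0] >= evaluator.x_patch) \
                    & (x_new[:, 0] <= g.x_collection_end)
                if patch_zone.any():
                    k = np.clip(g.channel_of(x_new[patch_zone, 1], None), 0, p.n_channels - 1)
                    loc = np.column_stack([x_new[patch_zone, 0] - evaluator.x_patch,
                                           x_new[patch_zone, 1] - g.channel_center_y(k)])
                    bad = shapely.contains_xy(posts_union, loc[:, 0], loc[:, 1])
                    if bad.any():
                        idx = np.where(patch_zone)[0][bad]
                        for i in idx:
                            kk = int(np.clip(g.channel_of(x_new[i, 1], None), 0,
                                             p.n_channels - 1))
                            yc = float(g.channel_center_y(kk))
                            pt = shapely.points(x_new[i, 0] - evaluator.x_patch,
                                                x_new[i, 1] - yc)
                            q = nearest_points(posts_union.boundary, pt)[0]
                            d = np.array([q.x - (x_new[i, 0] - evaluator.x_patch),
                                          q.y - (x_new[i, 1] - yc)])
                            x_new[i, 0] = q.x + evaluator.x_patch + 1e-9 * np.sign(d[0] or 1)
                            x_new[i, 1] = q.y + yc + 1e-9 * np.sign(d[1] or 1)
                            wall_proj += 1

            x[act] = x_new
            t += dt
        frames_pos[fi] = np.where((status == IN_DOMAIN)[:, None] |
                                  (status == TRAPPED)[:, None], x, np.nan)
        frames_status[fi] = status
        if drag is not None:
            live = status == IN_DOMAIN
            if live.any():
                mu = evaluator.model.fluid.dynamic_viscosity
                acc = advective_accel(x[live])
                drag[fi][live] = (3 * np.pi * pop.diameters[live, None] * mu
                                  * tau_p[live, None] * acc)
        if stop_at_first_arrival and np.any(status == TRAPPED):
            frames_pos = frames_pos[:fi + 1]
            frames_status = frames_status[:fi + 1]
            times = times[:fi + 1]
            break

    return Trajectories(times=times, positions=frames_pos, status=frames_status,
                        diameters=pop.diameters, release_times=t_rel,
                        event_times=event_t, evaluator=evaluator,
                        wall_projections=wall_proj, mode=mode, seed=seed,
                        drag=drag if drag is None else drag[:len(times)])


def _cum_fraction(eta):
    return (2.0 + 3.0 * eta - eta ** 3) / 4.0


def _eta_of_fraction(s):
    from .composite import _eta_from_fraction
    return _eta_from_fraction(s)


def _patch_posts(params):
    from .geometry import post_patch_polygon
    _, posts, _ = post_patch_polygon(params)
    return posts


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def first_arrival_time(traj: Trajectories):
    """Earliest terminal-micropost arrival [s]; None if censored (no arrival)."""
    if traj.n == 0:
        return None
    trapped = traj.status[-1] == TRAPPED
    if not trapped.any():
        return None
    return float(np.nanmin(traj.event_times[trapped]))


def position_histogram(traj: Trajectories, t: float, n_bins_x: int = 50,
                       x_range=None):
    """Counts of cells (in domain or trapped) per half-open x bin at time t,
    plus per-channel counts.  0-based bins [x_i, x_{i+1})."""
    fi = traj.frame_at(t)
    live = np.isin(traj.status[fi], (IN_DOMAIN, TRAPPED))
    xs = traj.positions[fi, live, 0]
    g = traj.evaluator.geom
    if x_range is None:
        x_range = (0.0, g.x_total)
    counts, edges = np.histogram(xs, bins=n_bins_x, range=x_range)
    k = g.channel_of(traj.positions[fi, live, 1], traj.positions[fi, live, 0])
    per_channel = np.bincount(k[k >= 0], minlength=g.params.n_channels)
    return counts, edges, per_channel


def channel_occupancy(traj: Trajectories, t: float) -> float:
    """Fraction of channels holding at least one cell at time t."""
    fi = traj.frame_at(t)
    live = np.isin(traj.status[fi], (IN_DOMAIN, TRAPPED))
    if not live.any():
        return 0.0
    g = traj.evaluator.geom
    k = g.channel_of(traj.positions[fi, live, 1], traj.positions[fi, live, 0])
    return float(len(np.unique(k[k >= 0])) / g.params.n_channels)


def mean_cell_speed(traj: Trajectories, region: str = "channels",
                    frame_dt: float | None = None,
                    weighting: str = "pairs") -> float:
    """Average frame-pair displacement speed |dx| / dt [m/s].

    ``region='channels'`` keeps only frame pairs with both samples inside
    the microchannel region (the default measurement window of the
    displacement-velocimetry validation); ``'all'`` uses the whole chip;
    an ``(x0, x1)`` tuple restricts to that x window (a microscope field of
    view).  ``weighting='pairs'`` averages over every frame pair;
    ``'tracks'`` averages per cell first (the weighting a track-linking
    estimator sees).
    """
    g = traj.evaluator.geom
    dt_frames = np.diff(traj.times)
    if frame_dt is not None:
        stride = max(int(round(frame_dt / dt_frames[0])), 1)
    else:
        stride = 1
        frame_dt = float(dt_frames[0])
    p0 = traj.positions[:-stride:stride]
    p1 = traj.positions[stride::stride]
    s0 = traj.status[:-stride:stride]
    s1 = traj.status[stride::stride]
    ok = (s0 == IN_DOMAIN) & (s1 == IN_DOMAIN)
    if region == "channels":
        x_win = (g.x_channels_start, g.x_channels_end)
    elif region == "all":
        x_win = None
    elif isinstance(region, (tuple, list)) and len(region) == 2:
        x_win = region
    else:
        raise ValueError("region must be 'channels', 'all' or an (x0, x1) window")
    if x_win is not None:
        for pp in (p0, p1):
            ok &= (pp[..., 0] >= x_win[0]) & (pp[..., 0] <= x_win[1])
    disp = np.linalg.norm(p1 - p0, axis=2)
    ok &= np.isfinite(disp)
    if not ok.any():
        raise ValueError("no frame pairs inside the requested region")
    denom = stride * float(dt_frames[0])
    if weighting == "pairs":
        return float(disp[ok].mean() / denom)
    if weighting != "tracks":
        raise ValueError("weighting must be 'pairs' or 'tracks'")
    with np.errstate(invalid="ignore"):
        per_cell = np.nansum(np.where(ok, disp, np.nan), axis=0) / ok.sum(axis=0)
    per_cell = per_cell[ok.sum(axis=0) > 0]
    return float(np.nanmean(per_cell) / denom)
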