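"""Synthetic displacement velocimetry.

Closes the validation loop without a microscope: particle trajectories are
rendered into per-frame centroid lists at a video frame rate (default 30
fps), optionally with Gaussian centroid jitter; the estimator then works
purely in pixel space - it links centroids between consecutive frames by
gated nearest neighbours, calibrates metres-per-pixel from the known
channel width, and averages per-track frame-pair displacement speeds.
The ground-truth pixel size is never given to the estimator: it must be
recovered through the calibration step, exactly as with real video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .particles import Trajectories, IN_DOMAIN

__all__ = ["FrameStack", "VelocimetryResult", "render_frames",
           "calibrate_pixels", "estimate_speeds", "percentage_error",
           "measure_channel_width_px"]


@dataclass
class FrameStack:
    """Per-frame particle centroids in pixel coordinates."""

    fps: float
    frames: list                                  # list of (n_k, 2) px arrays
    fov: tuple                                    # (x0, y0, x1, y1) [m]
    pixel_size: float                             # ground truth [m/px]
    wall_marks_px: tuple | None = None            # integer-px y of channel walls
    true_channel_width: float | None = None       # [m], the printed width

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a frame stack needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def render_frames(traj: Trajectories, fps: float = 30.0, fov=None,
                  pixel_size: float = 0.5e-6, jitter_px: float = 0.0,
                  seed: int = 0, mark_channel: int | None = None) -> FrameStack:
    """Render trajectories to per-frame centroid lists.

    Frame k holds positions interpolated to t = k/fps; centroids get
    Gaussian jitter of ``jitter_px`` pixels.  ``fov`` defaults to the
    microchannel region of the chip.  A pair of integer-pixel wall marks for
    one channel emulates reading the channel walls off the image, providing
    the calibration feature of known physical size.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    g = traj.evaluator.geom
    p = g.params
    if fov is None:
        fov = (g.x_channels_start, -p.array_height / 2,
               g.x_channels_end, p.array_height / 2)
    x0, y0, x1, y1 = fov
    rng = np.random.default_rng(seed)
    t_max = traj.times[-1]
    n_frames = int(np.floor(t_max * fps)) + 1
    frames = []
    for k in range(n_frames):
        t = k / fps
        fi = np.clip(np.searchsorted(traj.times, t) - 1, 0, len(traj.times) - 2)
        t0, t1 = traj.times[fi], traj.times[fi + 1]
        a = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        pos = (1 - a) * traj.positions[fi] + a * traj.positions[fi + 1]
        live = (traj.status[fi] == IN_DOMAIN) & (traj.status[fi + 1] == IN_DOMAIN)
        pos = pos[live & np.isfinite(pos).all(axis=1)]
        inside = ((pos[:, 0] >= x0) & (pos[:, 0] <= x1)
                  & (pos[:, 1] >= y0) & (pos[:, 1] <= y1))
        px = (pos[inside] - [x0, y0]) / pixel_size
        if jitter_px > 0:
            px = px + rng.normal(0.0, jitter_px, px.shape)
        frames.append(px)

    k_mark = p.n_channels // 2 if mark_channel is None else mark_channel
    yc = float(g.channel_center_y(k_mark))
    lo = int(round((yc - p.channel_width / 2 - y0) / pixel_size))
    hi = int(round((yc + p.channel_width / 2 - y0) / pixel_size))
    return FrameStack(fps=fps, frames=frames, fov=fov, pixel_size=pixel_size,
                      wall_marks_px=(lo, hi), true_channel_width=p.channel_width)


def measure_channel_width_px(stack: FrameStack) -> float:
    """Channel width in (integer-quantized) pixels, read from the wall marks."""
    if stack.wall_marks_px is None:
        raise ValueError("frame stack carries no wall marks")
    lo, hi = stack.wall_marks_px
    return float(hi - lo)


def calibrate_pixels(measured_channel_width_px: float, true_width: float) -> float:
    """Calibration factor [m/px] from a feature of known physical size."""
    if measured_channel_width_px <= 0 or true_width <= 0:
        raise ValueError("measured width and true width must be > 0")
    return true_width / measured_channel_width_px


@dataclass
class VelocimetryResult:
    track_speeds: np.ndarray                     # per-track mean speeds [m/s]
    mean_speed: float
    calibration: float                           # [m/px]
    n_links: int
    percentage_error_vs: float | None = None

    def __post_init__(self):
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")


def estimate_speeds(stack: FrameStack, calibration: float,
                    min_track_len: int = 2, gate_px: float | None = None,
                    expected_speed: float | None = None,
                    reference_speed: float | None = None) -> VelocimetryResult:
    """Nearest-neighbour frame-pair linking and per-track speed averaging.

    ``gate_px`` is the linking search radius.  Preferably it is derived from
    the flow solution by passing ``expected_speed`` (m/s, e.g. the channel
    centreline speed): gate = 1.5 x the implied per-frame displacement.
    Failing both, it falls back to 1.5 x the median displacement of the
    first usable frame pair (unreliable in dense scenes).  Speeds are
    ``|displacement| * calibration * fps`` averaged per track, then over
    tracks of at least ``min_track_len`` positions.
    """
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    frames = stack.frames
    if gate_px is None and expected_speed is not None:
        gate_px = 1.5 * expected_speed / (stack.fps * calibration)
    if gate_px is None:
        for a, b in zip(frames[:-1], frames[1:]):
            if len(a) and len(b):
                d, _ = cKDTree(b).query(a, k=1)
                gate_px = 1.5 * float(np.median(d))
                break
        if gate_px is None or gate_px == 0:
            raise ValueError("cannot auto-gate: no consecutive frames with particles")

    # greedy nearest-neighbour links with constant-velocity prediction:
    # once a track has two points, the search centres on the extrapolated
    # position, which disambiguates neighbours closer than one displacement
    tracks = {}                      # track id -> list of px positions
    open_tracks = {}                 # index in current frame -> track id
    next_id = 0
    for i, pts in enumerate(frames):
        if i == 0:
            for j in range(len(pts)):
                tracks[next_id] = [pts[j]]
                open_tracks[j] = next_id
                next_id += 1
            continue
        prev = frames[i - 1]
        new_open = {}
        if len(prev) and len(pts):
            pred = np.empty_like(prev)
            for j in range(len(prev)):
                tid = open_tracks.get(j)
                if tid is not None and len(tracks[tid]) >= 2:
                    pred[j] = 2 * np.asarray(tracks[tid][-1]) \
                        - np.asarray(tracks[tid][-2])
                else:
                    pred[j] = prev[j]
            d, nn = cKDTree(pts).query(pred, k=1,
                                       distance_upper_bound=gate_px)
            # resolve collisions: nearest prediction wins
            order = np.argsort(d)
            taken = set()
            for j in order:
                if not np.isfinite(d[j]) or nn[j] in taken:
                    continue
                taken.add(nn[j])
                tid = open_tracks.get(j)
                if tid is None:
                    tid = next_id
                    tracks[tid] = [prev[j]]
                    next_id += 1
                tracks[tid].append(pts[nn[j]])
                new_open[int(nn[j])] = tid
        for j in range(len(pts)):
            if j not in new_open:
                tracks[next_id] = [pts[j]]
                new_open[j] = next_id
                next_id += 1
        open_tracks = new_open

    speeds = []
    n_links = 0
    for tr in tracks.values():
        if len(tr) < max(min_track_len, 2):
            continue
        tr = np.asarray(tr)
        disp = np.linalg.norm(np.diff(tr, axis=0), axis=1)
        n_links += len(disp)
        speeds.append(float(disp.mean() * calibration * stack.fps))
    if not speeds:
        raise ValueError(
            f"no tracks of length >= {min_track_len} formed (gate {gate_px:.2f} px, "
            f"{sum(len(f) for f in frames)} centroids in {len(frames)} frames)")
    speeds = np.asarray(speeds)
    res = VelocimetryResult(track_speeds=speeds, mean_speed=float(speeds.mean()),
                            calibration=calibration, n_links=n_links)
    if reference_speed is not None:
        res.percentage_error_vs = percentage_error(res.mean_speed, reference_speed)
    return res


def percentage_error(measured: float, reference: float) -> float:
    """|measured - reference| / reference * 100, reference = simulated value."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return abs(measured - reference) / abs(reference) * 100.0
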