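"""Parametric plan-view geometry of the cell-trapping chip.

The chip is laid out along ``x`` (flow direction), mirror-symmetric about the
centreline ``y = 0``:

    inlet feed channel -> tapered header -> n parallel microchannels
    (each ending in a row of diamond microposts + a collection segment)
    -> mirrored header -> outlet feed channel

All coordinates are metres.  Channels are indexed ``0 .. n-1`` bottom to top;
channel ``k``'s centreline is ``y0 + k * pitch`` (an affine function of k).
The fluid domain is a single polygon whose holes are the wall slabs between
neighbouring channels and the diamond microposts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = ["GeometryError", "ChipParams", "ChipGeometry", "build_chip",
           "post_patch_polygon", "header_polygon"]


class GeometryError(ValueError):
    """Raised when chip parameters violate a geometric constraint."""


_DEFAULT_INLET_WIDTH = {40e-6: 0.96e-3, 25e-6: 0.6e-3}


def _default_inlet_width(channel_width: float) -> float:
    # tolerant float matching: 25 * 1e-6 differs from 25e-6 by one ulp
    for w, inlet in _DEFAULT_INLET_WIDTH.items():
        if abs(channel_width - w) <= 1e-9 * w:
            return inlet
    return 0.96e-3


@dataclass
class ChipParams:
    """Printed and configurable dimensions of the chip.

    ``depth`` enters only the flow-rate <-> inlet-velocity conversion; the
    flow model itself is 2D plan-view.
    """

    n_channels: int = 128
    channel_width: float = 40e-6
    channel_length: float = 20e-3
    depth: float = 50e-6
    inlet_width: float | None = None          # default depends on channel width
    microposts_per_channel: int = 3
    micropost_side_gap: float = 2e-6
    micropost_transverse_diagonal: float | None = None  # default: width - 2*gap
    micropost_axial_diagonal: float | None = None       # default: = transverse
    micropost_clear_spacing: float | None = None        # tip-to-tip, default: = axial diagonal
    micropost_end_clearance: float = 50e-6    # last post tip -> channel end
    wall_thickness: float = 25e-6             # solid wall between channels
    header_length: float = 2e-3
    feed_length: float = 5e-3
    collection_length: float = 200e-6
    manifold_style: str = "tapered_tree"      # or "straight_header"

    def __post_init__(self) -> None:
        if self.inlet_width is None:
            self.inlet_width = _default_inlet_width(self.channel_width)
        if self.micropost_transverse_diagonal is None:
            self.micropost_transverse_diagonal = self.channel_width - 2 * self.micropost_side_gap
        if self.micropost_axial_diagonal is None:
            self.micropost_axial_diagonal = self.micropost_transverse_diagonal
        if self.micropost_clear_spacing is None:
            self.micropost_clear_spacing = self.micropost_axial_diagonal
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_channels < 1:
            raise GeometryError("n_channels must be >= 1")
        for name in ("channel_width", "channel_length", "depth", "inlet_width",
                     "wall_thickness", "header_length", "feed_length",
                     "collection_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.microposts_per_channel < 0:
            raise GeometryError("microposts_per_channel must be >= 0")
        if self.manifold_style not in ("tapered_tree", "straight_header"):
            raise GeometryError("manifold_style must be 'tapered_tree' or 'straight_header'")
        if self.microposts_per_channel > 0:
            if self.micropost_side_gap <= 0:
                raise GeometryError("micropost_side_gap must be > 0")
            width = self.channel_width - 2 * self.micropost_side_gap
            if width <= 0:
                raise GeometryError(
                    "micropost width = channel_width - 2*micropost_side_gap must be > 0")
            if self.micropost_transverse_diagonal > width + 1e-15:
                raise GeometryError(
                    "micropost_transverse_diagonal exceeds channel_width - 2*micropost_side_gap")
            span = (self.microposts_per_channel * self.micropost_axial_diagonal
                    + (self.microposts_per_channel - 1) * self.micropost_clear_spacing
                    + self.micropost_end_clearance)
            if span >= self.channel_length:
                raise GeometryError("micropost row does not fit inside channel_length")

    # -- derived quantities -------------------------------------------------
    @property
    def pitch(self) -> float:
        return self.channel_width + self.wall_thickness

    @property
    def array_height(self) -> float:
        return (self.n_channels - 1) * self.pitch + self.channel_width

    @property
    def micropost_width(self) -> float:
        return self.channel_width - 2 * self.micropost_side_gap


def _diamond(xc: float, yc: float, axial: float, transverse: float) -> Polygon:
    return Polygon([(xc - axial / 2, yc), (xc, yc - transverse / 2),
                    (xc + axial / 2, yc), (xc, yc + transverse / 2)])


@dataclass
class ChipGeometry:
    """Fluid domain polygon plus the labelling needed by solver and tracer."""

    params: ChipParams
    domain: Polygon = field(repr=False)
    posts: list = field(repr=False)           # shapely Polygons, channel-major order
    post_centers: np.ndarray = field(repr=False)   # (n_posts, 2)
    post_channel: np.ndarray = field(repr=False)   # (n_posts,) channel index

    # key x stations
    x_feed_end: float = 0.0
    x_channels_start: float = 0.0
    x_channels_end: float = 0.0
    x_collection_end: float = 0.0
    x_outlet_header_end: float = 0.0
    x_total: float = 0.0

    # -- channel bookkeeping ------------------------------------------------
    def channel_center_y(self, k) -> np.ndarray:
        p = self.params
        return (np.asarray(k) - (p.n_channels - 1) / 2.0) * p.pitch

    def channel_of(self, y, x=None):
        """0-based channel index for points, -1 where not inside a channel."""
        p = self.params
        y = np.asarray(y, dtype=float)
        k = np.round(y / p.pitch + (p.n_channels - 1) / 2.0).astype(int)
        ok = (k >= 0) & (k < p.n_channels)
        kc = np.clip(k, 0, p.n_channels - 1)
        ok &= np.abs(y - self.channel_center_y(kc)) <= p.channel_width / 2 + 1e-15
        if x is not None:
            x = np.asarray(x, dtype=float)
            ok &= (x >= self.x_channels_start - 1e-15) & (x <= self.x_collection_end + 1e-15)
        return np.where(ok, kc, -1)

    def capture_x(self, radius: float) -> float:
        """x of the trapping line: one cell radius upstream of the first post tip."""
        p = self.params
        if p.microposts_per_channel == 0:
            return self.x_channels_end
        first_tip = self.first_post_tip_x
        return first_tip - radius

    @property
    def first_post_tip_x(self) -> float:
        p = self.params
        spacing_cc = p.micropost_axial_diagonal + p.micropost_clear_spacing
        last_center = (self.x_channels_end - p.micropost_end_clearance
                       - p.micropost_axial_diagonal / 2)
        first_center = last_center - (p.microposts_per_channel - 1) * spacing_cc
        return first_center - p.micropost_axial_diagonal / 2

    # -- boundary tagging ---------------------------------------------------
    def boundary_tag(self, points: np.ndarray) -> np.ndarray:
        """Tag boundary-edge midpoints: 'inlet' (x=0), 'outlet' (x=x_total), else 'wall'."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        tol = 1e-9 * max(self.x_total, 1.0)
        tags = np.full(len(pts), "wall", dtype=object)
        tags[np.abs(pts[:, 0]) < tol] = "inlet"
        tags[np.abs(pts[:, 0] - self.x_total) < tol] = "outlet"
        return tags

    @property
    def inlet_segment(self):
        w = self.params.inlet_width
        return ((0.0, -w / 2), (0.0, w / 2))

    @property
    def outlet_segment(self):
        w = self.params.inlet_width
        return ((self.x_total, -w / 2), (self.x_total, w / 2))

    # -- area accounting (analytic, used by tests and averages) -------------
    @property
    def area_feed(self) -> float:
        return 2 * self.params.feed_length * self.params.inlet_width

    @property
    def area_header(self) -> float:
        p = self.params
        if p.manifold_style == "tapered_tree":
            return 2 * 0.5 * (p.inlet_width + p.array_height) * p.header_length
        return 2 * p.array_height * p.header_length

    @property
    def area_channels(self) -> float:
        p = self.params
        return p.n_channels * p.channel_width * (p.channel_length + p.collection_length)

    @property
    def area_posts(self) -> float:
        p = self.params
        return (p.n_channels * p.microposts_per_channel
                * 0.5 * p.micropost_axial_diagonal * p.micropost_transverse_diagonal)

    @property
    def total_area(self) -> float:
        return self.area_feed + self.area_header + self.area_channels - self.area_posts

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "params": asdict(self.params),
            "outer": list(self.domain.exterior.coords),
            "holes": [list(r.coords) for r in self.domain.interiors],
            "posts": [list(p.exterior.coords) for p in self.posts],
            "tags": {"inlet": self.inlet_segment, "outlet": self.outlet_segment},
        })

    @classmethod
    def from_json(cls, text: str) -> "ChipGeometry":
        data = json.loads(text)
        return build_chip(ChipParams(**data["params"]))


def build_chip(params: ChipParams) -> ChipGeometry:
    """Assemble the fluid-domain polygon for the given parameters."""
    params.validate()
    p = params
    w_in, H = p.inlet_width, p.array_height
    x_feed = p.feed_length
    x_arr = x_feed + p.header_length
    x_ch_end = x_arr + p.channel_length
    x_coll = x_ch_end + p.collection_length
    x_oh = x_coll + p.header_length
    x_tot = x_oh + p.feed_length

    if p.manifold_style == "tapered_tree":
        lower = [(0.0, -w_in / 2), (x_feed, -w_in / 2), (x_arr, -H / 2),
                 (x_coll, -H / 2), (x_oh, -w_in / 2), (x_tot, -w_in / 2)]
    else:  # straight header: full-height rectangular plenums on both sides
        lower = [(0.0, -w_in / 2), (x_feed, -w_in / 2), (x_feed, -H / 2),
                 (x_oh, -H / 2), (x_oh, -w_in / 2), (x_tot, -w_in / 2)]
    upper = [(x, -y) for (x, y) in reversed(lower)]
    outer = lower + upper

    # wall slabs between neighbouring channels (holes), spanning the array
    y_centers = (np.arange(p.n_channels) - (p.n_channels - 1) / 2.0) * p.pitch
    holes = []
    x0_slab, x1_slab = x_arr, x_coll
    for k in range(p.n_channels - 1):
        y_lo = y_centers[k] + p.channel_width / 2
        y_hi = y_centers[k + 1] - p.channel_width / 2
        holes.append([(x0_slab, y_lo), (x1_slab, y_lo), (x1_slab, y_hi), (x0_slab, y_hi)])

    # microposts
    posts, centers, chan_idx = [], [], []
    if p.microposts_per_channel > 0:
        spacing_cc = p.micropost_axial_diagonal + p.micropost_clear_spacing
        last_center = x_ch_end - p.micropost_end_clearance - p.micropost_axial_diagonal / 2
        xs = [last_center - (p.microposts_per_channel - 1 - i) * spacing_cc
              for i in range(p.microposts_per_channel)]
        for k in range(p.n_channels):
            for xc in xs:
                d = _diamond(xc, y_centers[k], p.micropost_axial_diagonal,
                             p.micropost_transverse_diagonal)
                posts.append(d)
                centers.append((xc, y_centers[k]))
                chan_idx.append(k)
                holes.append(list(d.exterior.coords)[:-1])

    domain = Polygon(outer, holes=holes)
    if not domain.is_valid:
        raise GeometryError("assembled chip polygon is invalid (self-intersection)")

    return ChipGeometry(
        params=params, domain=domain, posts=posts,
        post_centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        post_channel=np.asarray(chan_idx, dtype=int),
        x_feed_end=x_feed, x_channels_start=x_arr, x_channels_end=x_ch_end,
        x_collection_end=x_coll, x_outlet_header_end=x_oh, x_total=x_tot,
    )


# ---------------------------------------------------------------------------
# local patch geometries for the composite solver
# ---------------------------------------------------------------------------

def post_patch_polygon(params: ChipParams, upstream_margin: float = 100e-6):
    """One channel end in local coordinates: straight run, micropost row,
    collection segment.  Returns ``(polygon, posts, x_inflow_offset)`` where
    ``x_inflow_offset`` is the chip-frame x of the patch's local origin."""
    p = params
    if p.microposts_per_channel == 0:
        raise GeometryError("post patch requires microposts_per_channel >= 1")
    spacing_cc = p.micropost_axial_diagonal + p.micropost_clear_spacing
    row_span = ((p.microposts_per_channel - 1) * spacing_cc + p.micropost_axial_diagonal)
    # local frame: x=0 at patch inflow, channel centreline y=0
    length = upstream_margin + row_span + p.micropost_end_clearance + p.collection_length
    rect = [(0.0, -p.channel_width / 2), (length, -p.channel_width / 2),
            (length, p.channel_width / 2), (0.0, p.channel_width / 2)]
    posts = []
    first_center = upstream_margin + p.micropost_axial_diagonal / 2
    for i in range(p.microposts_per_channel):
        posts.append(_diamond(first_center + i * spacing_cc, 0.0,
                              p.micropost_axial_diagonal, p.micropost_transverse_diagonal))
    poly = Polygon(rect, holes=[list(d.exterior.coords)[:-1] for d in posts])
    chip_x0 = (params.feed_length + params.header_length + params.channel_length
               - (row_span + p.micropost_end_clearance) - upstream_margin)
    return poly, posts, chip_x0


def header_polygon(params: ChipParams):
    """Inlet header in local coordinates (x=0 at the feed/header junction)."""
    p = params
    w_in, H, L = p.inlet_width, p.array_height, p.header_length
    if p.manifold_style == "tapered_tree":
        return Polygon([(0.0, -w_in / 2), (L, -H / 2), (L, H / 2), (0.0, w_in / 2)])
    return Polygon([(0.0, -w_in / 2), (0.0, -H / 2), (L, -H / 2),
                    (L, H / 2), (0.0, H / 2), (0.0, w_in / 2)])
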