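"""Boundary graph construction, top-down selection, and label spreading.

Active boundary pixels become graph nodes labeled with their dominant
orientation (vertical or horizontal; the diagonal channels carry no weight
downstream).  Edges are (i) local adjacency between like-oriented
neighbors and (ii) grouping links that bridge gaps between collinear,
like-oriented nodes — the analogue of illusory-contour formation.  A pair
of disk-shaped selection signals placed over the flanker tops seeds a
constant-speed geodesic spread that shifts reached nodes from the default
layer 0 into layer 1; everything unreachable from the seeds stays in
layer 0 forever.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from .cortical_dynamics import SimulationClock
from .stimuli import DisplayConfig, StimulusSpec

__all__ = [
    "BipoleParams",
    "BoundaryGraph",
    "SelectionSignal",
    "SegmentationState",
    "build_graph",
    "place_selection",
    "spread",
]

#: Node orientation codes.
VERTICAL, HORIZONTAL = 0, 1


@dataclass(frozen=True)
class BipoleParams:
    """Geometry of grouping links between collinear boundary nodes.

    ``max_bridge_deg`` must exceed the 0.4 deg flanker spacing (so terminator
    links can chain across neighboring lines) but stay below the 1.25 deg
    gap height (so gapped line segments are not bridged vertically).
    """

    max_bridge_deg: float = 0.6
    lateral_tolerance_deg: float = 0.1
    node_threshold: float = 0.12  # fraction of the map maximum

    def __post_init__(self) -> None:
        if not (0 < self.lateral_tolerance_deg < self.max_bridge_deg):
            raise ValueError("require 0 < lateral_tolerance < max_bridge")


@dataclass
class BoundaryGraph:
    """Active boundary nodes with adjacency + collinear grouping links.

    Edge weights are Euclidean distances in degrees, so graph geodesics
    measure contour length traveled.
    """

    rows: np.ndarray  # (n,) pixel row of each node
    cols: np.ndarray  # (n,) pixel col
    x_deg: np.ndarray  # (n,) degree coordinates (x rightward)
    y_deg: np.ndarray  # (n,) degree coordinates (y downward)
    orientation: np.ndarray  # (n,) VERTICAL or HORIZONTAL
    adjacency: sparse.csr_matrix  # (n, n) symmetric, weights in degrees
    shape: tuple[int, int]  # underlying image shape

    @property
    def n_nodes(self) -> int:
        return len(self.rows)

    def connected_components(self) -> tuple[int, np.ndarray]:
        if self.n_nodes == 0:
            return 0, np.zeros(0, dtype=int)
        n, labels = csgraph.connected_components(self.adjacency, directed=False)
        return int(n), labels


def _ridge(resp: np.ndarray, axis: int) -> np.ndarray:
    """Pixels that are local maxima of ``resp`` across the given axis."""
    lo = np.full_like(resp, -np.inf)
    hi = np.full_like(resp, -np.inf)
    if axis == 1:
        lo[:, 1:] = resp[:, :-1]
        hi[:, :-1] = resp[:, 1:]
    else:
        lo[1:, :] = resp[:-1, :]
        hi[:-1, :] = resp[1:, :]
    return (resp >= lo) & (resp >= hi)


def build_graph(
    accumulated: np.ndarray,
    config: DisplayConfig,
    params: BipoleParams = BipoleParams(),
) -> BoundaryGraph:
    """Boundary graph from a per-channel accumulated activity map.

    ``accumulated`` has shape (channels, rows, cols); only the vertical and
    horizontal channels define nodes.  A pixel is a node when its stronger
    of the two responses exceeds ``node_threshold`` x map maximum.
    """
    v, h = accumulated[0], accumulated[1]
    act = np.maximum(v, h)
    peak = act.max()
    if peak <= 0:
        empty = sparse.csr_matrix((0, 0))
        z = np.zeros(0)
        return BoundaryGraph(z.astype(int), z.astype(int), z, z, z.astype(int), empty, act.shape)

    thr = params.node_threshold * peak
    # Thin each channel to its ridge: a vertical-contour response must be a
    # local maximum across columns, a horizontal one across rows. Without
    # this, blur side-lobes of one element can touch a neighboring element.
    v_ok = (v > thr) & _ridge(v, axis=1)
    h_ok = (h > thr) & _ridge(h, axis=0)
    mask = v_ok | h_ok
    rows, cols = np.nonzero(mask)
    v_n, h_n = v_ok[rows, cols], h_ok[rows, cols]
    dominant_h = h[rows, cols] > v[rows, cols]
    orientation = np.where(h_n & (dominant_h | ~v_n), HORIZONTAL, VERTICAL)
    ppd = config.pixels_per_degree
    x = (cols - config.center_col) / ppd
    y = (rows - config.center_row) / ppd

    n = len(rows)
    src, dst, wgt = [], [], []
    for ori, along, across in ((VERTICAL, y, x), (HORIZONTAL, x, y)):
        idx = np.nonzero(orientation == ori)[0]
        if len(idx) == 0:
            continue
        a, c = along[idx], across[idx]
        # All like-oriented pairs whose connecting segment is nearly parallel
        # to the preferred orientation and no longer than max_bridge. This
        # covers both local adjacency along a contour and gap-bridging links.
        da = np.abs(a[:, None] - a[None, :])
        dc = np.abs(c[:, None] - c[None, :])
        link = (dc <= params.lateral_tolerance_deg + 1e-9) & (da <= params.max_bridge_deg + 1e-9)
        np.fill_diagonal(link, False)
        ii, jj = np.nonzero(link)
        keep = ii < jj
        ii, jj = ii[keep], jj[keep]
        src.append(idx[ii])
        dst.append(idx[jj])
        wgt.append(np.hypot(da[ii, jj], dc[ii, jj]))
    # Local adjacency regardless of matching orientation axis is *not*
    # added: cross-oriented nodes interact only through the spatial overlap
    # of their own collinear links (e.g. terminator nodes sitting on the
    # same pixels as the line ends).  Same-pixel-neighborhood links between
    # a vertical node and a horizontal node are added below so contours
    # connect to their own terminators.
    vert = np.nonzero(orientation == VERTICAL)[0]
    horiz = np.nonzero(orientation == HORIZONTAL)[0]
    if len(vert) and len(horiz):
        dx = np.abs(x[vert][:, None] - x[horiz][None, :])
        dy = np.abs(y[vert][:, None] - y[horiz][None, :])
        # A terminator joins the contour it ends: same column, small vertical
        # offset. Laterally adjacent contours must not be captured here.
        near = (dx * ppd <= 0.5) & (dy * ppd <= 2.5)
        ii, jj = np.nonzero(near)
        src.append(vert[ii])
        dst.append(horiz[jj])
        wgt.append(np.hypot(dx[ii, jj], dy[ii, jj]))

    if src:
        src_a = np.concatenate(src)
        dst_a = np.concatenate(dst)
        wgt_a = np.concatenate(wgt)
    else:
        src_a = dst_a = np.zeros(0, dtype=int)
        wgt_a = np.zeros(0)
    # Zero-length parallel duplicates are harmless; make symmetric.
    adj = sparse.coo_matrix(
        (np.concatenate([wgt_a, wgt_a]), (np.concatenate([src_a, dst_a]), np.concatenate([dst_a, src_a]))),
        shape=(n, n),
    ).tocsr()

    # Off-ridge horizontal side lobes can form tiny islands detached from
    # every contour; a genuine contour component always contains nodes of
    # both kinds (a line plus its terminators).  Drop all-horizontal islands.
    _, comp = csgraph.connected_components(adj, directed=False)
    has_vertical = np.zeros(comp.max() + 1, dtype=bool)
    np.logical_or.at(has_vertical, comp, orientation == VERTICAL)
    keep = has_vertical[comp]
    if not keep.all():
        idx = np.nonzero(keep)[0]
        adj = adj[idx][:, idx].tocsr()
        rows, cols, x, y = rows[idx], cols[idx], x[idx], y[idx]
        orientation = orientation[idx]
    return BoundaryGraph(rows, cols, x, y, orientation, adj, act.shape)


@dataclass(frozen=True)
class SelectionSignal:
    """Disk-shaped top-down seed regions in degree coordinates."""

    centers_deg: tuple[tuple[float, float], ...] = ()
    radius_deg: float = 1.5

    @property
    def empty(self) -> bool:
        return len(self.centers_deg) == 0

    def covers(self, x_deg: np.ndarray, y_deg: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside any selection disk."""
        inside = np.zeros(len(x_deg), dtype=bool)
        for cx, cy in self.centers_deg:
            inside |= (x_deg - cx) ** 2 + (y_deg - cy) ** 2 <= self.radius_deg**2
        return inside


def place_selection(spec: StimulusSpec, radius_deg: float = 1.5) -> SelectionSignal:
    """Two disks over the top ends of the left and right flanker triplets.

    Returns an empty signal when the stimulus has no flankers.
    """
    if spec.flankers is None:
        return SelectionSignal(radius_deg=radius_deg)
    fl = spec.flankers
    offsets = fl.column_offsets_deg()
    cx = float(np.mean(offsets[offsets > 0]))
    top_y = -fl.height_deg / 2.0
    return SelectionSignal(centers_deg=((-cx, top_y), (cx, top_y)), radius_deg=radius_deg)


@dataclass
class SegmentationState:
    """Layer membership over time, derived from geodesic distances to seeds.

    A node enters layer 1 once the spreading front, launched from the seed
    set at ``start_ms`` and traveling at ``speed_deg_per_ms`` along graph
    edges, reaches it.  Membership is monotone by construction.
    """

    graph: BoundaryGraph
    seeds: np.ndarray  # (n,) bool
    distance_deg: np.ndarray  # (n,) geodesic distance from seed set
    start_ms: float
    speed_deg_per_ms: float
    clock: SimulationClock

    def layer1(self, t_ms: float) -> np.ndarray:
        """Boolean layer-1 membership per node at time ``t_ms``."""
        if t_ms < self.start_ms:
            return np.zeros(self.graph.n_nodes, dtype=bool)
        reach = self.speed_deg_per_ms * (t_ms - self.start_ms)
        return self.distance_deg <= reach + 1e-12

    def layer(self, t_ms: float) -> np.ndarray:
        """Integer layer labels (0 or 1) per node."""
        return self.layer1(t_ms).astype(int)

    def layer1_pixel_mask(self, t_ms: float) -> np.ndarray:
        """Layer-1 membership painted back onto the image grid.

        A contour's activity footprint extends beyond its thinned ridge
        (filter side lobes), so every pixel is owned by its nearest node:
        a pixel is layer 1 exactly when that node is.
        """
        in1 = self.layer1(t_ms)
        if not in1.any():
            return np.zeros(self.graph.shape, dtype=bool)
        if in1.all():
            return np.ones(self.graph.shape, dtype=bool)
        d1 = self._distance_to(in1)
        d0 = self._distance_to(~in1)
        # strict inequality: equidistant pixels stay in the default layer,
        # a rule that is invariant under mirroring (unlike nearest-node
        # index tie-breaking)
        return d1 < d0

    def _distance_to(self, node_subset: np.ndarray) -> np.ndarray:
        mask = np.zeros(self.graph.shape, dtype=bool)
        mask[self.graph.rows[node_subset], self.graph.cols[node_subset]] = True
        return ndimage.distance_transform_edt(~mask)


def spread(
    graph: BoundaryGraph,
    signal: SelectionSignal,
    clock: SimulationClock = SimulationClock(),
    speed_deg_per_ms: float = 0.08,
    start_ms: float | None = None,
) -> SegmentationState:
    """Spread selection along the graph at constant geodesic speed.

    Spreading starts at stimulus offset by default.  An empty signal (or a
    signal covering no node) leaves every node in layer 0 at all times.
    """
    start = clock.offset_ms if start_ms is None else start_ms
    n = graph.n_nodes
    if n == 0 or signal.empty:
        dist = np.full(n, np.inf)
        return SegmentationState(graph, np.zeros(n, dtype=bool), dist, start, speed_deg_per_ms, clock)
    seeds = signal.covers(graph.x_deg, graph.y_deg)
    if not seeds.any():
        dist = np.full(n, np.inf)
        return SegmentationState(graph, seeds, dist, start, speed_deg_per_ms, clock)
    dist = csgraph.dijkstra(graph.adjacency, directed=False, indices=np.nonzero(seeds)[0], min_only=True)
    return SegmentationState(graph, seeds, dist, start, speed_deg_per_ms, clock)
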