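"""Closed cell contours and binary-mask geometry.

Coordinate convention, used everywhere in morphodyn: a point is ``(x, y)``
with ``x`` the column index increasing rightward and ``y`` the row index
increasing downward; pixel centers sit at integer coordinates.  A contour is
counter-clockwise (CCW) when its shoelace signed area is positive in this
frame, which puts the cell interior on the left of the direction of travel.

An :class:`Outline` is a closed, ordered, sub-pixel polygon of contour nodes
for one cell in one frame.  Binary masks use 0 for background; any value > 0
is foreground on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .errors import (
    ComponentCountError,
    OutlineInvariantError,
    ParameterError,
    TooSmallComponentError,
)

log = logging.getLogger(__name__)

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


class Outline:
    """Closed, ordered, sub-pixel cell contour.

    Parameters
    ----------
    nodes : (N, 2) array_like
        Node positions ``(x, y)`` in pixels, N >= 3.  Orientation is
        normalised to CCW (positive shoelace area) on construction.
    frame_index : int
        Index of the movie frame this outline belongs to.
    attrs : dict of str -> (N,) array, optional
        Per-node attributes (fluorescence, curvature ...).  Reordered /
        interpolated together with the nodes.
    validate : bool
        If true (default) check simplicity and minimal spacing.
    """

    def __init__(self, nodes, frame_index: int = 0, attrs=None, validate: bool = True):
        nodes = np.asarray(nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2 or nodes.shape[0] < 3:
            raise OutlineInvariantError("an outline needs an (N>=3, 2) node array")
        # drop an explicitly repeated closing node
        if np.allclose(nodes[0], nodes[-1]):
            nodes = nodes[:-1]
        if nodes.shape[0] < 3:
            raise OutlineInvariantError("fewer than 3 distinct nodes")
        attrs = {k: np.asarray(v, dtype=float) for k, v in (attrs or {}).items()}
        if _signed_area(nodes) < 0:
            nodes = nodes[::-1].copy()
            attrs = {k: v[::-1].copy() for k, v in attrs.items()}
        self.nodes = nodes
        self.frame_index = int(frame_index)
        self.attrs = attrs
        for k, v in attrs.items():
            if v.shape[0] != nodes.shape[0]:
                raise OutlineInvariantError(f"attribute {k!r} length mismatch")
        if validate:
            self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        d = np.linalg.norm(np.diff(np.vstack([self.nodes, self.nodes[:1]]), axis=0), axis=1)
        if np.any(d <= 1e-12):
            raise OutlineInvariantError("consecutive duplicate nodes")
        if not Polygon(self.nodes).is_valid:
            raise OutlineInvariantError("polygon is not simple")
        if _signed_area(self.nodes) <= 0:
            raise OutlineInvariantError("polygon is not CCW / has no area")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def closed_nodes(self) -> np.ndarray:
        """Nodes with the first node appended again at the end."""
        return np.vstack([self.nodes, self.nodes[:1]])

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.closed_nodes(), axis=0), axis=1)

    def perimeter(self) -> float:
        return float(self.edge_lengths().sum())

    def area(self) -> float:
        """Enclosed (shoelace) area; positive for a valid CCW outline."""
        return float(_signed_area(self.nodes))

    def centroid(self) -> np.ndarray:
        c = Polygon(self.nodes).centroid
        return np.array([c.x, c.y])

    def polygon(self) -> Polygon:
        return Polygon(self.nodes)

    def normals(self) -> np.ndarray:
        """Outward unit normal per node (average of incident edge normals)."""
        return _outward_normals(self.nodes)

    def copy(self) -> "Outline":
        return Outline(self.nodes.copy(), self.frame_index,
                       {k: v.copy() for k, v in self.attrs.items()}, validate=False)

    # -- constructors -----------------------------------------------------
    @classmethod
    def circle(cls, cx: float, cy: float, r: float, n: int = 100,
               frame_index: int = 0) -> "Outline":
        if r <= 0 or n < 3:
            raise ParameterError("circle needs r > 0 and n >= 3")
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return cls(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]),
                   frame_index=frame_index)

    def __repr__(self) -> str:
        return f"Outline(n={self.n_nodes}, frame={self.frame_index})"


def _signed_area(nodes: np.ndarray) -> float:
    x, y = nodes[:, 0], nodes[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _outward_normals(nodes: np.ndarray) -> np.ndarray:
    e = np.roll(nodes, -1, axis=0) - nodes          # edge i: node i -> i+1
    # outward normal of a CCW edge (interior on the left) is (dy, -dx)
    en = np.column_stack([e[:, 1], -e[:, 0]])
    en /= np.maximum(np.linalg.norm(en, axis=1, keepdims=True), 1e-30)
    n = en + np.roll(en, 1, axis=0)                 # average incident edges
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
    return n


# ---------------------------------------------------------------------------
# mask <-> contour
# ---------------------------------------------------------------------------

def mask_to_contour(mask: np.ndarray, frame_index: int = 0) -> Outline:
    """Trace the outer boundary of the single foreground component of ``mask``.

    The boundary runs along the edges of the foreground pixel squares (each
    pixel is the unit square centred on its integer coordinate), so the traced
    polygon encloses every foreground pixel center, no background pixel
    center, and its shoelace area equals the foreground pixel count for
    hole-free 4-connected components.  Vertices sit at half-integer corners;
    collinear runs are merged.

    Raises
    ------
    ComponentCountError
        zero or more than one 4-connected foreground component.
    TooSmallComponentError
        a 1- or 2-pixel component (no 3-node polygon exists).
    """
    fg = np.asarray(mask) > 0
    lab, n = ndimage.label(fg, structure=_FOUR_CONN)
    if n != 1:
        raise ComponentCountError(f"expected exactly 1 foreground component, found {n}")
    filled = ndimage.binary_fill_holes(fg)
    if filled.sum() != fg.sum():
        log.info("mask_to_contour: filled %d hole pixel(s)", int(filled.sum() - fg.sum()))
        fg = filled
    npix = int(fg.sum())
    if npix < 3:
        # a 1- or 2-px component: boundary exists but spec calls it degenerate
        if npix == 1:
            r, c = np.argwhere(fg)[0]
            return Outline(np.array([[c - .5, r - .5], [c + .5, r - .5],
                                     [c + .5, r + .5], [c - .5, r + .5]]),
                           frame_index=frame_index)
        raise TooSmallComponentError(f"foreground component of {npix} px is degenerate")

    verts = _trace_crack_boundary(fg)
    verts = _merge_collinear(verts)
    return Outline(verts, frame_index=frame_index)


def _trace_crack_boundary(fg: np.ndarray) -> np.ndarray:
    """Chain the directed pixel-square edges of the outer boundary (CCW)."""
    p = np.pad(fg, 1)
    core = p[1:-1, 1:-1]
    rr, cc = np.nonzero(core)
    # vertex keys in doubled half-integer units to stay integral
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(v0, v1):
        edges.setdefault(v0, []).append(v1)

    up_bg = core & ~p[:-2, 1:-1]
    dn_bg = core & ~p[2:, 1:-1]
    lf_bg = core & ~p[1:-1, :-2]
    rt_bg = core & ~p[1:-1, 2:]
    # directed so the interior stays on the left (positive shoelace in x,y-down)
    for r, c in zip(*np.nonzero(up_bg)):
        add((2 * c - 1, 2 * r - 1), (2 * c + 1, 2 * r - 1))
    for r, c in zip(*np.nonzero(rt_bg)):
        add((2 * c + 1, 2 * r - 1), (2 * c + 1, 2 * r + 1))
    for r, c in zip(*np.nonzero(dn_bg)):
        add((2 * c + 1, 2 * r + 1), (2 * c - 1, 2 * r + 1))
    for r, c in zip(*np.nonzero(lf_bg)):
        add((2 * c - 1, 2 * r + 1), (2 * c - 1, 2 * r - 1))

    start = min(edges)
    path = [start]
    prev_dir = None
    cur = start
    total = sum(len(v) for v in edges.values())
    for _ in range(total + 1):
        outs = edges[cur]
        if len(outs) == 1 or prev_dir is None:
            nxt = sorted(outs)[0]
        else:
            # pinch vertex: take the sharpest left turn to keep the trace simple
            def turn(v):
                d = (v[0] - cur[0], v[1] - cur[1])
                return prev_dir[0] * d[1] - prev_dir[1] * d[0]
            nxt = min(outs, key=turn)
        outs.remove(nxt)
        prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
        if nxt == start:
            break
        path.append(nxt)
        cur = nxt
    return np.array(path, float) / 2.0


def _merge_collinear(verts: np.ndarray) -> np.ndarray:
    nxt = np.roll(verts, -1, axis=0)
    prv = np.roll(verts, 1, axis=0)
    a, b = verts - prv, nxt - verts
    keep = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]) > 1e-12
    return verts[keep]


def contour_to_mask(outline: Outline, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an outline: pixel (r, c) is foreground iff its center lies
    inside the polygon (even-odd); centers exactly on an edge count as inside.

    An outline exceeding the image bounds is clipped with a logged warning.
    """
    rows, cols = shape
    nodes = outline.nodes
    if (nodes[:, 0].min() < -0.5 or nodes[:, 1].min() < -0.5
            or nodes[:, 0].max() > cols - 0.5 or nodes[:, 1].max() > rows - 0.5):
        log.warning("contour_to_mask: outline exceeds image bounds, clipping")
    poly = Polygon(nodes)
    # restrict the candidate grid to the bounding box for speed
    x0 = max(0, int(np.floor(nodes[:, 0].min())))
    x1 = min(cols - 1, int(np.ceil(nodes[:, 0].max())))
    y0 = max(0, int(np.floor(nodes[:, 1].min())))
    y1 = min(rows - 1, int(np.ceil(nodes[:, 1].max())))
    mask = np.zeros(shape, dtype=np.uint8)
    if x1 < x0 or y1 < y0:
        log.warning("contour_to_mask: outline entirely outside image")
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.covers(poly, pts).reshape(ys.shape)  # covers => boundary ties inside
    if not inside.any():
        log.warning("contour_to_mask: polygon contains no pixel center")
    mask[y0:y1 + 1, x0:x1 + 1] = inside
    return mask


# ---------------------------------------------------------------------------
# resampling and curvature
# ---------------------------------------------------------------------------

def arc_positions(outline: Outline) -> np.ndarray:
    """Cumulative arc length at each node (arc 0 at node 0)."""
    el = outline.edge_lengths()
    return np.concatenate([[0.0], np.cumsum(el[:-1])])


def point_at_arc(outline: Outline, s) -> np.ndarray:
    """Point(s) on the polygon at arc position(s) ``s`` (wraps around)."""
    s = np.atleast_1d(np.asarray(s, float)) % outline.perimeter()
    cum = np.concatenate([arc_positions(outline), [outline.perimeter()]])
    closed = outline.closed_nodes()
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def resample(outline: Outline, n: int, start_arc: float = 0.0) -> Outline:
    """Resample to ``n`` nodes equally spaced by arc length along the source
    polygon, starting at arc position ``start_arc`` (default: original node 0).

    Per-node attributes are linearly interpolated in arc length.  The
    perimeter is preserved within 0.1% for ``n`` at or above the source node
    count (chords of chords only shorten second-order).
    """
    if n < 3:
        raise ParameterError("resample needs n >= 3")
    P = outline.perimeter()
    s = (start_arc + np.arange(n) * P / n)
    pts = point_at_arc(outline, s)
    attrs = {}
    if outline.attrs:
        cum = np.concatenate([arc_positions(outline), [P]])
        sm = s % P
        for k, v in outline.attrs.items():
            vv = np.concatenate([v, v[:1]])
            attrs[k] = np.interp(sm, cum, vv)
    return Outline(pts, frame_index=outline.frame_index, attrs=attrs)


def turning_angles(outline: Outline) -> np.ndarray:
    """Signed exterior (turning) angle at each node; positive = convex for a
    CCW contour.  Sums to exactly +2*pi over any simple CCW polygon."""
    nodes = outline.nodes
    e_in = nodes - np.roll(nodes, 1, axis=0)
    e_out = np.roll(nodes, -1, axis=0) - nodes
    cross = e_in[:, 0] * e_out[:, 1] - e_in[:, 1] * e_out[:, 0]
    dot = np.sum(e_in * e_out, axis=1)
    return np.arctan2(cross, dot)


def local_convexity(outline: Outline, window_px: float = 5.0) -> np.ndarray:
    """Per-node signed curvature (units 1/px), positive where the boundary
    bulges outward, negative in concavities.

    The estimate is the turning angle per unit arc length, averaged over a
    circular arc window of ``window_px``.  The averaging kernel conserves the
    total turning, so integrating the returned values against the per-node
    arc elements gives exactly +2*pi for any simple CCW polygon.  A window
    larger than the perimeter degenerates to the global average (logged).
    """
    if window_px <= 0:
        raise ParameterError("window_px must be > 0")
    th = turning_angles(outline)
    el = outline.edge_lengths()
    ds = 0.5 * (el + np.roll(el, 1))        # arc element owned by each node
    P = outline.perimeter()
    n = outline.n_nodes
    if window_px >= P:
        log.info("local_convexity: window >= perimeter, returning global mean")
        return np.full(n, 2 * np.pi / P)
    k = max(1, int(round(window_px / ds.mean())))
    if k % 2 == 0:
        k += 1
    k = min(k, n if n % 2 == 1 else n - 1)
    half = k // 2
    # D_j = total arc mass of the window centred on j; distributing theta_j / D_j
    # to every node in that window conserves the turning integral exactly.
    idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n
    D = ds[idx].sum(axis=1)
    contrib = th / D
    kappa = contrib[idx].sum(axis=1)
    return kappa


def convexity_arc_elements(outline: Outline) -> np.ndarray:
    """Arc element per node to integrate ``local_convexity`` against."""
    el = outline.edge_lengths()
    return 0.5 * (el + np.roll(el, 1))


@dataclass
class BinaryMaskInfo:
    """Bookkeeping for mask ingest (holes filled etc.)."""
    holes_filled: int = 0
    notes: list[str] = field(default_factory=list)


def ingest_mask(raw: np.ndarray) -> tuple[np.ndarray, BinaryMaskInfo]:
    """Normalise an external mask: values > 0 are foreground; holes filled."""
    fg = np.asarray(raw) > 0
    filled = ndimage.binary_fill_holes(fg)
    info = BinaryMaskInfo(holes_filled=int(filled.sum() - fg.sum()))
    if info.holes_filled:
        info.notes.append(f"filled {info.holes_filled} hole pixels")
        log.info("ingest_mask: %s", info.notes[-1])
    return filled.astype(np.uint8), info
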