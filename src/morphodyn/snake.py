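"""Active-contour segmentation of bright cells on dark background.

A closed snake is evolved per frame under three forces: first-neighbour
tension (pulls each node toward the midpoint of its neighbours),
a constant inward contraction toward the centroid, and an image force along
the outward normal whose sign follows a smooth activation of the local
intensity against a threshold — nodes over bright (cell) pixels are pushed
outward, nodes over background are released to the contraction, so the
boundary settles where the interpolated intensity crosses the threshold.
Node velocities carry over between iterations with a friction factor, which
damps the dynamics into a stationary fixed point.

The converged outline of frame t, dilated outward by one node spacing, is
the initialisation for frame t+1, which is what lets long time series run
unsupervised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .contours import Outline, _outward_normals, _signed_area
from .errors import ParameterError, SnakeCollapseError
from .seeding import offset_contour

log = logging.getLogger(__name__)


@dataclass
class AcParams:
    """Active-contour parameters.

    ``intensity_threshold`` is the activation level of the image force; if
    None it defaults to the midpoint of the frame's robust intensity range
    (1st to 99th percentile).  ``edge_softness`` scales the tanh transition
    of the image force as a fraction of the robust range; it trades boundary
    sharpness against the stability of the node update.  Forces are sampled
    from the frame smoothed with a Gaussian of ``presmooth_sigma`` px so
    camera noise does not rattle the equilibrium; evolution stops early
    (logged, flagged not-converged) when the per-iteration displacement has
    not reached a new minimum for ``stall_iterations`` iterations.
    """
    node_spacing_px: float = 4.0
    max_iterations: int = 4000
    f_image: float = 0.3
    f_contraction: float = 0.04
    f_tension: float = 0.01
    f_friction: float = 0.6
    intensity_threshold: float | None = None
    convergence_eps_px: float = 0.01
    edge_softness: float = 0.25
    presmooth_sigma: float = 1.0
    stall_iterations: int = 400

    def __post_init__(self):
        if not (0 < self.f_friction <= 1):
            raise ParameterError("f_friction must be in (0, 1]")
        if min(self.f_image, self.f_contraction, self.f_tension) < 0:
            raise ParameterError("force weights must be >= 0")
        if self.node_spacing_px <= 0:
            raise ParameterError("node_spacing_px must be > 0")


@dataclass
class SnakeResult:
    outline: Outline
    converged: bool
    iterations: int


@dataclass
class StackSegmentation:
    """Per-frame outlines plus convergence bookkeeping."""
    outlines: list = field(default_factory=list)
    converged: list = field(default_factory=list)
    iterations: list = field(default_factory=list)


def _bilinear(frame: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return map_coordinates(frame.astype(float), [pts[:, 1], pts[:, 0]],
                           order=1, mode="nearest")


def _respace(nodes: np.ndarray, vel: np.ndarray, spacing: float):
    """Insert midpoints where spacing > 1.5*s, delete where < 0.5*s.

    Velocities of inserted nodes are neighbour means; ties (several short
    edges) resolve at the lower node index first.
    """
    el = np.linalg.norm(np.roll(nodes, -1, axis=0) - nodes, axis=1)
    long_e = np.nonzero(el > 1.5 * spacing)[0]
    if long_e.size:
        out_n, out_v = [], []
        for i in range(nodes.shape[0]):
            out_n.append(nodes[i]); out_v.append(vel[i])
            if el[i] > 1.5 * spacing:
                j = (i + 1) % nodes.shape[0]
                out_n.append(0.5 * (nodes[i] + nodes[j]))
                out_v.append(0.5 * (vel[i] + vel[j]))
        nodes, vel = np.array(out_n), np.array(out_v)
        el = np.linalg.norm(np.roll(nodes, -1, axis=0) - nodes, axis=1)
    if nodes.shape[0] > 3:
        short = el < 0.5 * spacing
        if short.any():
            # delete the end node of each short edge, lowest index first,
            # never two adjacent deletions in one pass
            keep = np.ones(nodes.shape[0], bool)
            for i in np.nonzero(short)[0]:
                j = (i + 1) % nodes.shape[0]
                if keep[i] and keep[j] and keep.sum() > 3:
                    keep[j] = False
            nodes, vel = nodes[keep], vel[keep]
    return nodes, vel


def _find_crossing(nodes: np.ndarray):
    """First pair of crossing edges (i, j), or None.  O(n^2) vectorised."""
    n = nodes.shape[0]
    p = nodes
    q = np.roll(nodes, -1, axis=0)
    d = q - p
    for i in range(n - 2):
        js = np.arange(i + 2, n if i > 0 else n - 1)
        w = p[js] - p[i]
        denom = d[i, 0] * d[js, 1] - d[i, 1] * d[js, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (w[:, 0] * d[js, 1] - w[:, 1] * d[js, 0]) / denom
            u = (w[:, 1] * d[i, 0] - w[:, 0] * d[i, 1]) / -denom
        hit = (np.abs(denom) > 1e-14) & (t > 1e-12) & (t < 1 - 1e-12) \
            & (u > 1e-12) & (u < 1 - 1e-12)
        if hit.any():
            return i, int(js[np.nonzero(hit)[0][0]])
    return None


def _repair_self_intersections(nodes: np.ndarray, vel: np.ndarray):
    """Excise the shorter loop between each crossing edge pair."""
    for _ in range(nodes.shape[0]):
        hit = _find_crossing(nodes)
        if hit is None:
            return nodes, vel
        i, j = hit
        n = nodes.shape[0]
        inner = np.arange(i + 1, j + 1)        # loop between the crossings
        outer_len = n - inner.size
        keep = np.ones(n, bool)
        if inner.size <= outer_len:
            keep[inner] = False
        else:
            keep[:] = False
            keep[inner] = True
        if keep.sum() < 3:
            return nodes, vel
        nodes, vel = nodes[keep], vel[keep]
    return nodes, vel


def evolve_snake(frame: np.ndarray, init: Outline, params: AcParams | None = None,
                 return_result: bool = False):
    """Evolve a snake on one frame until the maximum node displacement per
    iteration falls below ``convergence_eps_px`` (or ``max_iterations`` is
    reached, with a logged warning).

    Raises :class:`SnakeCollapseError` when the enclosed area drops below
    4 px^2 — the no-edge shrinkage end state.
    """
    params = params or AcParams()
    frame = np.asarray(frame, float)
    if not np.all(np.isfinite(frame)):
        raise ParameterError("frame contains non-finite intensities")
    if params.presmooth_sigma > 0:
        frame = gaussian_filter(frame, params.presmooth_sigma)
    lo, hi = np.percentile(frame, [1, 99])
    g_range = max(hi - lo, 1e-12)
    thr = params.intensity_threshold
    if thr is None:
        thr = 0.5 * (lo + hi)
        log.info("evolve_snake: intensity_threshold defaulted to %.3g", thr)
    soft = max(params.edge_softness * g_range, 1e-12)

    nodes = init.nodes.copy()
    vel = np.zeros_like(nodes)
    converged = False
    it = 0
    best_disp = np.inf
    best_it = 0
    for it in range(1, params.max_iterations + 1):
        nodes, vel = _respace(nodes, vel, params.node_spacing_px)
        prev = nodes
        mid = 0.5 * (np.roll(nodes, 1, axis=0) + np.roll(nodes, -1, axis=0))
        f_ten = params.f_tension * (mid - nodes)
        centroid = nodes.mean(axis=0)
        to_c = centroid - nodes
        to_c /= np.maximum(np.linalg.norm(to_c, axis=1, keepdims=True), 1e-30)
        f_con = params.f_contraction * to_c
        normals = _outward_normals(nodes)
        act = np.tanh((_bilinear(frame, nodes) - thr) / soft)
        f_img = params.f_image * act[:, None] * normals
        if it % 100 == 0:
            # kill residual kinetic energy so marginal limit cycles around
            # the force balance decay instead of orbiting forever
            vel[:] = 0.0
        vel = params.f_friction * vel + f_ten + f_con + f_img
        nodes = nodes + vel
        nodes, vel = _repair_self_intersections(nodes, vel)
        area = _signed_area(nodes) if _signed_area(nodes) > 0 else -_signed_area(nodes)
        if area < 4.0:
            raise SnakeCollapseError(frame=init.frame_index)
        if nodes.shape[0] == prev.shape[0]:
            disp = np.abs(nodes - prev).max()
            if disp < params.convergence_eps_px:
                converged = True
                break
            if disp < best_disp * (1 - 1e-3):
                best_disp, best_it = disp, it
            elif it - best_it > params.stall_iterations:
                log.warning("evolve_snake: displacement stalled at %.3g px "
                            "after %d iterations", best_disp, it)
                break
    if not converged:
        log.warning("evolve_snake: not converged after %d iterations", it)
    out = Outline(nodes, frame_index=init.frame_index)
    if return_result:
        return SnakeResult(out, converged, it)
    return out


def segment_stack_ac(stack, init: Outline, params: AcParams | None = None
                     ) -> StackSegmentation:
    """Segment every frame of a stack, propagating each converged outline
    (dilated outward by one node spacing) as the next initialisation.

    On snake collapse at frame t the error carries the outlines of frames
    < t in its ``partial`` attribute.
    """
    params = params or AcParams()
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    result = StackSegmentation()
    cur = init
    for t, frame in enumerate(frames):
        cur = Outline(cur.nodes, frame_index=t, validate=False)
        try:
            res = evolve_snake(frame, cur, params, return_result=True)
        except SnakeCollapseError:
            raise SnakeCollapseError(frame=t, partial=result.outlines)
        result.outlines.append(res.outline)
        result.converged.append(res.converged)
        result.iterations.append(res.iterations)
        cur = offset_contour(res.outline, params.node_spacing_px, spine=False)
    return result
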