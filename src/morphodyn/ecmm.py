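"""Electrostatic contour migration: sub-pixel edge tracking.

Each node of the cell outline at frame t is mapped to a point on the
outline at frame t+1 by letting it migrate along the electric field lines
of a charge configuration: positive charges distributed uniformly along the
source contour, negative charges along the target.  Field lines of this
configuration do not cross, so the correspondence is order preserving, and
migrating along them minimises the summed path length — the energy the cell
spends deforming its boundary.  By the 2D shell property of the 1/r kernel,
a node between two nested contours feels essentially only the force driving
it toward the target, which is what makes the construction robust for both
protrusion (outward) and retraction (inward) motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

from .contours import Outline, point_at_arc
from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class EcmmMapping:
    """Per-node correspondence between two consecutive outlines."""
    landing: np.ndarray       # (n, 2) landing positions on the target contour
    path_length: np.ndarray   # (n,) migrated path length, px, >= 0
    sign: np.ndarray          # (n,) +1 expansion (landing outside source), -1 retraction
    diverged: np.ndarray      # (n,) bool, node failed to reach the target
    paths: list | None = field(default=None, repr=False)  # optional QA polylines

    @property
    def signed_path_length(self) -> np.ndarray:
        return self.sign * self.path_length

    @property
    def n_nodes(self) -> int:
        return self.landing.shape[0]


def discretize_charges(outline: Outline, density: float = 1.0) -> np.ndarray:
    """Charge positions along a contour, >= ``density`` charges per px of arc.

    Charges sit at arc midpoints (offset half a spacing from arc 0) so a
    node lying exactly on the contour falls between two charges and the
    near-field of its own contour cancels by symmetry.
    """
    P = outline.perimeter()
    n = max(8, int(np.ceil(P * density)))
    s = (np.arange(n) + 0.5) * P / n
    return point_at_arc(outline, s)


def field_at(points, src_charges: np.ndarray, tgt_charges: np.ndarray,
             exclusion: float = 1e-6) -> np.ndarray:
    """Superposed 2D Coulomb field (1/r kernel) at ``points``.

    Positive unit charges at ``src_charges`` push away from the source;
    negative unit charges at ``tgt_charges`` pull toward the target.
    Charges within ``exclusion`` px of an evaluation point are omitted
    (logged) so the field stays finite.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    E = np.zeros_like(pts)
    excluded = 0
    for charges, q in ((src_charges, +1.0), (tgt_charges, -1.0)):
        d = pts[:, None, :] - charges[None, :, :]        # (npts, nq, 2)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        close = r2 < exclusion * exclusion
        excluded += int(close.sum())
        r2 = np.where(close, np.inf, r2)
        E += q * np.einsum("ijk,ij->ik", d, 1.0 / r2)
    if excluded:
        log.debug("field_at: excluded %d near-coincident charge(s)", excluded)
    return E if np.asarray(points).ndim == 2 else E[0]


def _point_edge_distance(p, a, b):
    """Distance of each point to the nearest target edge (vectorised)."""
    e = b - a                                    # (m, 2)
    w = p[:, None, :] - a[None, :, :]            # (n, m, 2)
    ee = np.einsum("ij,ij->i", e, e)
    t = np.clip(np.einsum("nmj,mj->nm", w, e) / np.maximum(ee, 1e-30), 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * e[None, :, :]
    d = np.linalg.norm(p[:, None, :] - proj, axis=2)
    j = d.argmin(axis=1)
    n = np.arange(p.shape[0])
    return d[n, j], proj[n, j]


def _segment_crossings(p0, p1, a, b):
    """First crossing of each segment p0->p1 against target edges (a, b).

    Returns (t, point) with t in [0, 1] the fraction along p0->p1, or
    t = inf where no crossing occurs.  Vectorised over nodes x edges.
    """
    d = p1 - p0                                  # (n, 2)
    e = b - a                                    # (m, 2)
    # solve p0 + t d = a + u e
    denom = d[:, None, 0] * (-e[None, :, 1]) - d[:, None, 1] * (-e[None, :, 0])
    w = a[None, :, :] - p0[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[..., 0] * (-e[None, :, 1]) - w[..., 1] * (-e[None, :, 0])) / denom
        u = (d[:, None, 0] * w[..., 1] - d[:, None, 1] * w[..., 0]) / denom
    valid = (np.abs(denom) > 1e-14) & (t >= -1e-12) & (t <= 1 + 1e-12) \
        & (u >= -1e-9) & (u <= 1 + 1e-9)
    t = np.where(valid, t, np.inf)
    t_first = t.min(axis=1)
    return t_first


def migrate(source: Outline, target: Outline, step_px: float = 0.05,
            max_steps: int | None = None, keep_paths: bool = False,
            charge_density: float = 4.0) -> EcmmMapping:
    """Migrate every source node along the field to the target contour.

    Advection is explicit with fixed steps of ``step_px`` along the
    normalised field direction; the landing point is the first crossing of a
    step segment with the target polygon.  Nodes already on the target land
    immediately with path length 0.  A node that has not crossed after
    ``max_steps`` is mapped to its nearest target point and flagged
    diverged (logged count).
    """
    if step_px <= 0:
        raise ParameterError("step_px must be > 0")
    src = discretize_charges(source, charge_density)
    tgt = discretize_charges(target, charge_density)
    tgt_ring = LinearRing(target.nodes)
    a = target.closed_nodes()[:-1]
    b = target.closed_nodes()[1:]
    n = source.n_nodes
    pos = source.nodes.copy()
    landing = pos.copy()
    path_len = np.zeros(n)
    active = np.ones(n, bool)
    paths = [[p.copy()] for p in pos] if keep_paths else None

    # nodes already on (or within the capture radius of) the target land
    # immediately; the capture radius of half a step also stops nodes that
    # would otherwise slide tangentially along a locally static boundary
    capture = 0.5 * step_px
    d0, near0 = _point_edge_distance(pos, a, b)
    on_target = d0 <= capture
    active[on_target] = False
    landing[on_target] = np.where((d0 <= 1e-9)[:, None], pos,
                                  near0)[on_target]
    path_len[on_target] = np.where(d0 <= 1e-9, 0.0, d0)[on_target]

    if max_steps is None:
        span = np.ptp(np.vstack([source.nodes, target.nodes]), axis=0).max()
        max_steps = int(20 * span / step_px) + 1000

    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        E = field_at(pos[idx], src, tgt)
        norm = np.linalg.norm(E, axis=1)
        norm = np.where(norm < 1e-30, 1.0, norm)
        new = pos[idx] + step_px * (E / norm[:, None])
        t = _segment_crossings(pos[idx], new, a, b)
        crossed = np.isfinite(t)
        dnew, nearest = _point_edge_distance(new, a, b)
        captured = ~crossed & (dnew <= capture)
        ic = idx[crossed]
        landing[ic] = pos[ic] + t[crossed][:, None] * (new[crossed] - pos[ic])
        path_len[ic] += t[crossed] * step_px
        active[ic] = False
        icap = idx[captured]
        landing[icap] = nearest[captured]
        path_len[icap] += step_px + dnew[captured]
        active[icap] = False
        im = idx[~crossed & ~captured]
        path_len[im] += step_px
        pos[im] = new[~crossed & ~captured]
        if keep_paths:
            for i in np.concatenate([ic, icap]):
                paths[i].append(landing[i].copy())
            for i, p in zip(im, new[~crossed & ~captured]):
                paths[i].append(p.copy())

    diverged = active.copy()
    if diverged.any():
        log.warning("migrate: %d node(s) failed to reach the target in %d steps",
                    int(diverged.sum()), max_steps)
        idx = np.nonzero(diverged)[0]
        pts = shapely.points(pos[idx, 0], pos[idx, 1])
        for i, pt in zip(idx, pts):
            near = shapely.ops.nearest_points(pt, tgt_ring)[1]
            landing[i] = [near.x, near.y]
            path_len[i] += float(pt.distance(near))

    # a path many times longer than the straight displacement means the node
    # fell onto a field-line separatrix (deep cleft); its length is not a
    # meaningful local motility, so flag it like a divergence
    straight = np.linalg.norm(landing - source.nodes, axis=1)
    wild = path_len > 3.0 * straight + 2.0
    if wild.any():
        log.info("migrate: flagged %d wild path(s)", int(wild.sum()))
        diverged |= wild

    src_poly = Polygon(source.nodes)
    inside = shapely.covers(src_poly, shapely.points(landing[:, 0], landing[:, 1]))
    sign = np.where(inside, -1.0, 1.0)
    return EcmmMapping(landing=landing, path_length=path_len, sign=sign,
                       diverged=diverged,
                       paths=[np.array(p) for p in paths] if keep_paths else None)


def track_sequence(outlines: list[Outline], step_px: float = 0.05,
                   **kwargs) -> list[EcmmMapping]:
    """ECMM mapping for every consecutive outline pair of a movie."""
    if len(outlines) < 2:
        raise ParameterError("track_sequence needs at least 2 frames")
    return [migrate(outlines[t], outlines[t + 1], step_px=step_px, **kwargs)
            for t in range(len(outlines) - 1)]
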