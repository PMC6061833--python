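"""Cortical fluorescence sampling and spatio-temporal maps.

The cortex is the thin band just inside the cell membrane where
cytoskeletal and signalling fluorescence concentrates.  ``sample_cortex``
measures the mean intensity in that band per boundary node;
``build_maps`` assembles frames x boundary-position matrices (motility,
fluorescence, convexity) whose columns track the same boundary material
across frames by registering each row's origin through the ECMM landing of
the previous row's origin — without this registration the position axis
drifts when the cell rotates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import map_coordinates
from shapely.geometry import LinearRing, LineString

from .contours import (Outline, arc_positions, convexity_arc_elements,
                       local_convexity, resample)
from .ecmm import EcmmMapping, migrate
from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class CortexSample:
    """Per-node cortical sampling result."""
    values: np.ndarray      # mean band intensity per node
    band_area: np.ndarray   # px^2 of the band quad owned by each node
    truncated: np.ndarray   # bool, band clipped at the local half-thickness

    @property
    def total_signal(self) -> float:
        """Integral of intensity over the cortical band (a.u. * px^2)."""
        return float(np.sum(self.values * self.band_area))


def _inward_depths(outline: Outline, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-node inward band depth, clipped at half the local chord so the
    band never crosses the medial axis of a thin cell."""
    poly = outline.polygon()
    nodes = outline.nodes
    normals = outline.normals()
    depths = np.full(outline.n_nodes, float(width))
    truncated = np.zeros(outline.n_nodes, bool)
    probe = 4.0 * width
    for i in range(outline.n_nodes):
        inner = nodes[i] - probe * normals[i]
        seg = LineString([nodes[i] - 1e-6 * normals[i], inner])
        hit = seg.intersection(poly.exterior)
        # distance to the first re-crossing of the boundary = local chord
        dmin = probe
        if not hit.is_empty:
            pts = getattr(hit, "geoms", [hit])
            for g in pts:
                for c in getattr(g, "coords", []):
                    d = np.hypot(c[0] - nodes[i][0], c[1] - nodes[i][1])
                    if d > 1e-3:
                        dmin = min(dmin, d)
        if 0.5 * dmin < width:
            depths[i] = max(0.5 * dmin, 0.25)
            truncated[i] = True
    if truncated.any():
        log.info("sample_cortex: band truncated at the medial axis on %d node(s)",
                 int(truncated.sum()))
    return depths, truncated


def sample_cortex(frame: np.ndarray, outline: Outline,
                  cortex_width_px: float = 8.0,
                  samples_across: int = 8) -> CortexSample:
    """Mean intensity in the cortical band, per node.

    Each node owns the quadrilateral between its arc segment (midpoint to
    midpoint of the incident edges) and the same segment displaced inward by
    ``cortex_width_px`` along the node normals.  The quad is integrated by
    midpoint-rule bilinear sampling weighted by the local area element, so
    the summed ``values * band_area`` reproduces the band integral of the
    intensity within a few percent.  Where the cell is thinner than twice
    the band width the depth is truncated at the medial axis and flagged.
    """
    if cortex_width_px <= 0:
        raise ParameterError("cortex_width_px must be > 0")
    frame = np.asarray(frame, float)
    nodes = outline.nodes
    n = outline.n_nodes
    normals = outline.normals()
    depths, truncated = _inward_depths(outline, cortex_width_px)
    inner = nodes - depths[:, None] * normals

    prev_mid_o = 0.5 * (np.roll(nodes, 1, axis=0) + nodes)
    next_mid_o = 0.5 * (nodes + np.roll(nodes, -1, axis=0))
    prev_mid_i = 0.5 * (np.roll(inner, 1, axis=0) + inner)
    next_mid_i = 0.5 * (inner + np.roll(inner, -1, axis=0))

    el = outline.edge_lengths()
    ns_half = max(2, int(np.ceil(0.5 * el.mean())))       # along-arc samples per half
    nt = max(3, samples_across)                           # across-band samples

    values = np.zeros(n)
    areas = np.zeros(n)
    s_mid = (np.arange(ns_half) + 0.5) / ns_half
    t_mid = (np.arange(nt) + 0.5) / nt

    def integrate(A, B, D, C):
        # bilinear patch with outer edge A->B and inner edge D->C
        S, T = np.meshgrid(s_mid, t_mid, indexing="ij")
        top = A[:, None, None, :] + S[None, :, :, None] * (B - A)[:, None, None, :]
        bot = D[:, None, None, :] + S[None, :, :, None] * (C - D)[:, None, None, :]
        P = (1 - T[None, :, :, None]) * top + T[None, :, :, None] * bot
        dPds = ((B - A)[:, None, None, :] * (1 - T[None, :, :, None])
                + (C - D)[:, None, None, :] * T[None, :, :, None]) / ns_half
        dPdt = (bot - top) / nt
        J = np.abs(dPds[..., 0] * dPdt[..., 1] - dPds[..., 1] * dPdt[..., 0])
        I = map_coordinates(frame, [P[..., 1].ravel(), P[..., 0].ravel()],
                            order=1, mode="nearest").reshape(J.shape)
        return (I * J).sum(axis=(1, 2)), J.sum(axis=(1, 2))

    m1, a1 = integrate(prev_mid_o, nodes, prev_mid_i, inner)
    m2, a2 = integrate(nodes, next_mid_o, inner, next_mid_i)
    mass = m1 + m2
    areas = a1 + a2
    values = mass / np.maximum(areas, 1e-12)
    return CortexSample(values=values, band_area=areas, truncated=truncated)


@dataclass
class STMap:
    """Spatio-temporal map: one row per frame, one column per boundary
    position; columns are registered to boundary material via ECMM."""
    values: np.ndarray                # (T, R) or (T-1, R) for motility
    kind: str                         # motility | fluorescence | convexity
    units: str                        # px/frame | intensity a.u. | 1/px
    origins: np.ndarray | None = None # per-row arc offset of column 0

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]


@dataclass
class MapSet:
    motility: STMap
    fluorescence: STMap
    convexity: STMap
    outlines: list = field(default_factory=list)   # resampled, registered


def _arc_of_points(outline: Outline, pts: np.ndarray) -> np.ndarray:
    """Arc position on ``outline`` of each (projected) point."""
    ring = LinearRing(outline.nodes)
    return np.array([ring.project(p) for p in shapely.points(pts[:, 0], pts[:, 1])])


def build_maps(track: list[Outline], mappings: list[EcmmMapping] | None,
               stack=None, cortex_width_px: float = 8.0, R: int = 400,
               frame_interval: float | None = None) -> MapSet:
    """Build the motility / fluorescence / convexity maps for a tracked cell.

    ``track`` holds one outline per frame; ``mappings`` the ECMM mapping per
    consecutive pair (computed here if None).  Each frame's outline is
    resampled to ``R`` equally spaced positions; the origin (column 0) of
    frame t+1 is placed at the ECMM landing of frame t's origin, so a column
    follows the same boundary material.  Motility is the signed ECMM path
    length per frame interval (px/frame); a pair whose mapping is missing
    yields a NaN motility row while the other maps are still computed.
    """
    if R < 3:
        raise ParameterError("R must be >= 3")
    T = len(track)
    if mappings is not None and len(mappings) not in (0, T - 1):
        raise ParameterError("need one ECMM mapping per consecutive frame pair")
    if frame_interval is None:
        frame_interval = getattr(stack, "frame_interval", 1.0) or 1.0

    frames = None
    if stack is not None:
        frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)

    motility = np.full((max(T - 1, 0), R), np.nan)
    fluor = np.full((T, R), np.nan)
    convex = np.full((T, R), np.nan)
    origins = np.zeros(T)
    resampled = []

    origin = 0.0
    for t in range(T):
        origins[t] = origin
        rs = resample(track[t], R, start_arc=origin)
        resampled.append(rs)
        convex[t] = local_convexity(rs, window_px=5.0)
        if frames is not None:
            fluor[t] = sample_cortex(frames[t], rs, cortex_width_px).values
        if t == T - 1:
            break
        tgt = track[t + 1]
        if mappings:
            # caller-supplied mapping on the raw track nodes: interpolate the
            # signed path length and the origin landing by arc position
            m = mappings[t]
            src = track[t]
            s_src = arc_positions(src)
            s_tgt = _arc_of_points(tgt, m.landing)
            signed = np.where(m.diverged, np.nan, m.signed_path_length)
            P_src = src.perimeter()
            row_s = (origin + np.arange(R) * P_src / R) % P_src
            order = np.argsort(s_src)
            ss, vv = s_src[order], signed[order]
            motility[t] = np.interp(row_s, np.concatenate([ss, [ss[0] + P_src]]),
                                    np.concatenate([vv, [vv[0]]]),
                                    period=P_src) / frame_interval
            tt = np.unwrap(s_tgt[order] * 2 * np.pi / tgt.perimeter()) \
                * tgt.perimeter() / (2 * np.pi)
            o_next = np.interp(row_s[0], np.concatenate([ss, [ss[0] + P_src]]),
                               np.concatenate([tt, [tt[0] + tgt.perimeter()]]),
                               period=P_src)
            origin = o_next % tgt.perimeter()
        else:
            # map the registered row nodes themselves: column r's motility is
            # exactly the signed path of its own ECMM migration
            m = migrate(rs, tgt)
            motility[t] = np.where(m.diverged, np.nan,
                                   m.signed_path_length) / frame_interval
            ring = LinearRing(tgt.nodes)
            origin = float(ring.project(shapely.points(*m.landing[0])))
    return MapSet(
        motility=STMap(motility, "motility", "px/frame", origins[:-1] if T > 1 else None),
        fluorescence=STMap(fluor, "fluorescence", "intensity a.u.", origins),
        convexity=STMap(convex, "convexity", "1/px", origins),
        outlines=resampled,
    )


def per_frame_stats(track: list[Outline], stack=None,
                    cortex_width_px: float = 8.0,
                    pixel_size: float | None = None,
                    frame_interval: float | None = None) -> pd.DataFrame:
    """Whole-cell statistics per frame: centroid, area, perimeter,
    circularity 4*pi*A/P^2, displacement from frame 0, cumulative distance,
    instantaneous speed, and (with a stack) mean/total cortical fluorescence.
    """
    if pixel_size is None:
        pixel_size = getattr(stack, "pixel_size", 1.0) or 1.0
    if frame_interval is None:
        frame_interval = getattr(stack, "frame_interval", 1.0) or 1.0
    frames = None
    if stack is not None:
        frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    rows = []
    prev_c = None
    c0 = None
    dist = 0.0
    for t, o in enumerate(track):
        c = o.centroid()
        if c0 is None:
            c0 = c
        step = float(np.linalg.norm(c - prev_c)) if prev_c is not None else 0.0
        dist += step
        A, P = o.area(), o.perimeter()
        row = {
            "frame": t,
            "centroid_x": c[0] * pixel_size,
            "centroid_y": c[1] * pixel_size,
            "area": A * pixel_size ** 2,
            "perimeter": P * pixel_size,
            "circularity": 4 * np.pi * A / P ** 2,
            "displacement": float(np.linalg.norm(c - c0)) * pixel_size,
            "distance_traveled": dist * pixel_size,
            "speed": step * pixel_size / frame_interval,
        }
        if frames is not None:
            cs = sample_cortex(frames[t], o, cortex_width_px)
            row["mean_cortical_fluor"] = float(cs.values.mean())
            row["total_cortical_fluor"] = cs.total_signal
        rows.append(row)
        prev_c = c
    return pd.DataFrame(rows)
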