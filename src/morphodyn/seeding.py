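"""Automatic seed synthesis by shape-preserving contour offsetting.

Random-walker segmentation needs foreground/background seed pixels per
frame.  morphodyn derives them from a prior mask by *vector* contraction
(foreground) and expansion (background) of the traced cell contour.  Unlike
pixel erosion with a disk, the contraction keeps a collapsed one-pixel-wide
spine inside thin cellular processes narrower than twice the offset
distance, so pseudopodia and filopodia stay seeded and survive the
random-walk step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage.morphology import skeletonize

from .contours import Outline, contour_to_mask, mask_to_contour
from .errors import EmptyOffsetError, ParameterError, SeedError

log = logging.getLogger(__name__)


@dataclass
class SeedLabels:
    """Foreground / background seed pixels for the Dirichlet problem."""
    foreground: np.ndarray  # bool (rows, cols)
    background: np.ndarray  # bool (rows, cols)

    def __post_init__(self):
        fg, bg = np.asarray(self.foreground, bool), np.asarray(self.background, bool)
        if fg.shape != bg.shape:
            raise SeedError("seed label arrays must share a shape")
        if not fg.any() or not bg.any():
            raise SeedError("both seed sets must be non-empty")
        if (fg & bg).any():
            raise SeedError("foreground and background seeds overlap")
        self.foreground, self.background = fg, bg

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "SeedLabels":
        """Label image convention: 1 = foreground, 2 = background."""
        labels = np.asarray(labels)
        return cls(labels == 1, labels == 2)

    def to_label_image(self) -> np.ndarray:
        out = np.zeros(self.foreground.shape, np.uint8)
        out[self.foreground] = 1
        out[self.background] = 2
        return out


def _largest_polygon(geom) -> Polygon:
    if isinstance(geom, Polygon):
        return geom
    if isinstance(geom, MultiPolygon):
        return max(geom.geoms, key=lambda g: g.area)
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        raise EmptyOffsetError("offset produced no polygonal geometry")
    return max(polys, key=lambda g: g.area)


def _exterior_outline(poly: Polygon, frame_index: int) -> Outline:
    coords = np.asarray(poly.exterior.coords)[:-1]
    # drop near-duplicate consecutive vertices from the union arithmetic
    d = np.linalg.norm(np.diff(np.vstack([coords, coords[:1]]), axis=0), axis=1)
    coords = coords[d > 1e-9]
    return Outline(coords, frame_index=frame_index)


def offset_contour(outline: Outline, distance: float, spine: bool = True) -> Outline:
    """Offset a closed contour by ``distance`` px: positive = outward
    expansion, negative = inward contraction.

    Contraction is shape preserving: where the cell is thinner than
    ``2 * |distance|`` (a pseudopod, a filopodium) the result keeps a
    collapsed spine along the local medial line instead of deleting the
    structure, so downstream foreground seeding still reaches into it.
    Self-intersecting loops created by the offset are excised and the result
    is a simple polygon.

    Raises
    ------
    EmptyOffsetError
        if the contraction exceeds the maximal inscribed radius of the cell
        body (no interior survives).
    """
    if distance == 0:
        return outline.copy()
    poly = outline.polygon()
    if not poly.is_valid:
        poly = poly.buffer(0)
    if distance > 0:
        out = poly.buffer(distance, quad_segs=16)
        return _exterior_outline(_largest_polygon(out), outline.frame_index)

    d = -distance
    body = poly.buffer(-d, quad_segs=16)
    if body.is_empty:
        raise EmptyOffsetError(
            f"contraction by {d} px exceeds the maximal inscribed radius")
    body = _largest_polygon(body)
    if not spine:
        return _exterior_outline(body, outline.frame_index)

    spine_geom = _thin_part_spine(outline, body, d)
    if spine_geom is None:
        return _exterior_outline(body, outline.frame_index)
    merged = _largest_polygon(unary_union([body, spine_geom]))
    merged = Polygon(merged.exterior)          # fill any union holes
    return _exterior_outline(merged, outline.frame_index)


def _thin_part_spine(outline: Outline, body: Polygon, d: float):
    """Medial spine of the parts of the cell thinner than 2*d.

    Homotopic thinning of the rasterised cell yields a 1-px skeleton; only
    skeleton pixels whose distance to the cell boundary is below the offset
    distance (i.e. pixels the plain offset would delete) are kept, plus a
    small overlap band so the spine stays attached to the offset body.
    """
    nodes = outline.nodes
    pad = 3
    x0 = int(np.floor(nodes[:, 0].min())) - pad
    y0 = int(np.floor(nodes[:, 1].min())) - pad
    x1 = int(np.ceil(nodes[:, 0].max())) + pad
    y1 = int(np.ceil(nodes[:, 1].max())) + pad
    shifted = Outline(nodes - [x0, y0], validate=False)
    mask = contour_to_mask(shifted, (y1 - y0 + 1, x1 - x0 + 1)).astype(bool)
    if not mask.any():
        return None
    skel = skeletonize(mask)
    dist = ndimage.distance_transform_edt(mask)
    keep = skel & (dist < d + 1.5)     # +1.5 px overlap into the body
    if not keep.any():
        return None
    rr, cc = np.nonzero(keep)
    pts = shapely.points(cc + x0, rr + y0)
    return unary_union(shapely.buffer(pts, 0.71, quad_segs=4))


def seeds_from_mask(mask: np.ndarray, d_fg: float = 8.0, d_bg: float = 10.0) -> SeedLabels:
    """Generate RW seeds from a prior segmentation mask.

    Foreground seeds are the pixels inside the traced contour contracted by
    ``d_fg``; background seeds are the pixels outside the contour expanded by
    ``d_bg``.  If the contraction empties the cell entirely (cell thinner
    than ``2*d_fg`` everywhere), the mask skeleton is used as the foreground
    seed set so thin cells remain seedable (logged warning).
    """
    if d_fg <= 0 or d_bg <= 0:
        raise ParameterError("seed offsets d_fg and d_bg must be > 0")
    mask = np.asarray(mask) > 0
    shape = mask.shape
    outline = mask_to_contour(mask)
    try:
        inner = offset_contour(outline, -d_fg)
        fg = contour_to_mask(inner, shape).astype(bool)
    except EmptyOffsetError:
        fg = np.zeros(shape, bool)
    if not fg.any():
        log.warning("seeds_from_mask: contraction emptied the cell; "
                    "falling back to the mask skeleton as foreground seeds")
        fg = skeletonize(mask)
    fg &= mask                      # guard: FG seeds never leave the prior mask
    outer = offset_contour(outline, +d_bg)
    bg = ~contour_to_mask(outer, shape).astype(bool)
    if not bg.any():
        raise SeedError("expansion covered the whole image: no background seeds")
    return SeedLabels(fg, bg)
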