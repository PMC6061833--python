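"""Segmentation evaluation metrics.

Hausdorff distance (the maximum distance between a segmented contour and a
gold-standard contour) and the count of false-positive pixels per unit of
gold contour length — the two quantities used to score segmentation quality
against manually traced cells.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LinearRing

from .contours import Outline, mask_to_contour, resample


def hausdorff(a: Outline, b: Outline, sampling_px: float = 0.25) -> float:
    """Symmetric Hausdorff distance between two closed contours (px).

    Both contours are sampled densely (arc spacing <= ``sampling_px``) and
    each direction takes the maximum exact point-to-polyline distance, so
    the result does not depend on the node placement of either contour.
    Zero iff the contours coincide as point sets.
    """
    ra, rb = LinearRing(a.nodes), LinearRing(b.nodes)

    def directed(src: Outline, tgt_ring) -> float:
        n = max(src.n_nodes, int(np.ceil(src.perimeter() / sampling_px)))
        pts = resample(src, n).nodes
        d = shapely.distance(shapely.points(pts[:, 0], pts[:, 1]), tgt_ring)
        return float(d.max())

    return max(directed(a, rb), directed(b, ra))


def fp_per_contour_length(mask: np.ndarray, gold: np.ndarray) -> float:
    """False-positive pixels of ``mask`` per px of gold contour length.

    Counts pixels foreground in ``mask`` but background in ``gold`` and
    divides by the perimeter of the gold mask's traced contour.  Asymmetric
    by design: false negatives do not enter.
    """
    mask = np.asarray(mask) > 0
    gold = np.asarray(gold) > 0
    fp = int(np.sum(mask & ~gold))
    perimeter = mask_to_contour(gold).perimeter()
    return fp / perimeter


def dice(mask: np.ndarray, gold: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    mask = np.asarray(mask) > 0
    gold = np.asarray(gold) > 0
    denom = mask.sum() + gold.sum()
    return 2.0 * np.sum(mask & gold) / denom if denom else 1.0
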