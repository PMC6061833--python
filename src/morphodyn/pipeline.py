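"""Combined active-contour + random-walk segmentation of a time series.

Per frame: the active contour produces a preliminary outline; its mask is
contracted/expanded into foreground/background seeds; the locally adaptive
random walker then refines the boundary, which handles the concave outlines
and intracellular fluorescence gradients that defeat each method alone.
The refined outline initialises the next frame's snake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contours import Outline, contour_to_mask, mask_to_contour, resample
from .errors import MorphodynError, OutlineInvariantError
from .filters import apply_contour_filter, make_filter
from .randomwalk import (RwParams, probability_to_mask, segment_rw,
                         solve_random_walk)
from .seeding import seeds_from_mask
from .snake import AcParams, evolve_snake, offset_contour

log = logging.getLogger(__name__)


def condition_outline(outline: Outline, smooth_window: int = 5,
                      node_spacing_px: float = 2.0) -> Outline:
    """Smooth a mask-traced (staircase) outline and resample it to a uniform
    sub-pixel node spacing, the form the tracking and mapping stages expect."""
    if smooth_window > 1:
        outline = apply_contour_filter(
            outline, make_filter("running_mean", window=smooth_window))
    n = max(8, int(round(outline.perimeter() / node_spacing_px)))
    return resample(outline, n)


@dataclass
class SeedParams:
    """Vector offsets (px) for automatic seeding: contraction for foreground,
    expansion for background — the order of a cortical band."""
    d_fg: float = 8.0
    d_bg: float = 10.0


@dataclass
class AcrwResult:
    outlines: list = field(default_factory=list)      # combined AC+RW outlines
    ac_outlines: list = field(default_factory=list)   # preliminary AC outlines
    masks: list = field(default_factory=list)         # final binary masks


class StageError(MorphodynError):
    """Pipeline failure carrying the frame index and failing stage."""

    def __init__(self, frame: int, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed at frame {frame}: {cause}")
        self.frame = frame
        self.stage = stage
        self.__cause__ = cause


def _subpixel_outline(prob: np.ndarray, mask: np.ndarray, threshold: float,
                      frame_index: int) -> Outline:
    """Extract the cell outline at the probability iso-level with sub-pixel
    precision (marching squares); falls back to tracing the binary mask when
    the level set is open or degenerate."""
    from skimage import measure
    try:
        for c in sorted(measure.find_contours(prob, threshold),
                        key=len, reverse=True):
            if len(c) >= 8 and np.allclose(c[0], c[-1]):
                o = Outline(c[:-1, ::-1], frame_index=frame_index)  # (r,c)->(x,y)
                if o.area() >= 4.0:
                    return o
    except (OutlineInvariantError, ValueError):
        pass
    log.info("subpixel outline extraction fell back to mask tracing")
    return mask_to_contour(mask, frame_index=frame_index)


def segment_frame_acrw(frame: np.ndarray, init: Outline,
                       ac_params: AcParams | None = None,
                       rw_params: RwParams | None = None,
                       seed_params: SeedParams | None = None):
    """Single-frame AC -> seeds -> RW -> outline refinement.

    The refined outline is extracted from the walker's probability field at
    the ``prob_threshold`` level with sub-pixel precision, then smoothed and
    resampled to a uniform node spacing."""
    ac_params = ac_params or AcParams()
    rw_params = rw_params or RwParams()
    seed_params = seed_params or SeedParams()
    ac_out = evolve_snake(frame, init, ac_params)
    mask = contour_to_mask(ac_out, frame.shape)
    seeds = seeds_from_mask(mask, seed_params.d_fg, seed_params.d_bg)
    prob = solve_random_walk(frame, seeds, rw_params)
    rw_mask = probability_to_mask(prob, seeds, rw_params.prob_threshold)
    outline = condition_outline(_subpixel_outline(
        prob, rw_mask, rw_params.prob_threshold, init.frame_index))
    return outline, ac_out, rw_mask


def segment_stack_acrw(stack, init: Outline,
                       ac_params: AcParams | None = None,
                       rw_params: RwParams | None = None,
                       seed_params: SeedParams | None = None,
                       masks=None) -> AcrwResult:
    """Segment a whole stack with the combined pipeline.

    If ``masks`` (a prior mask stack) is given the AC stage is skipped and
    the provided masks seed the walker directly.  Any stage error is
    re-raised as :class:`StageError` carrying the frame index.
    """
    ac_params = ac_params or AcParams()
    rw_params = rw_params or RwParams()
    seed_params = seed_params or SeedParams()
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    result = AcrwResult()
    cur = init
    for t, frame in enumerate(frames):
        try:
            if masks is not None:
                mask = np.asarray(masks[t]) > 0
                ac_out = mask_to_contour(mask, frame_index=t)
                seeds = seeds_from_mask(mask, seed_params.d_fg, seed_params.d_bg)
                rw_mask = segment_rw(frame, seeds, rw_params)
                outline = condition_outline(mask_to_contour(rw_mask, frame_index=t))
            else:
                cur = Outline(cur.nodes, frame_index=t, validate=False)
                outline, ac_out, rw_mask = segment_frame_acrw(
                    frame, cur, ac_params, rw_params, seed_params)
                cur = offset_contour(outline, ac_params.node_spacing_px, spine=False)
        except MorphodynError as exc:
            raise StageError(t, type(exc).__name__, exc) from exc
        result.outlines.append(outline)
        result.ac_outlines.append(ac_out)
        result.masks.append(rw_mask)
    return result
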