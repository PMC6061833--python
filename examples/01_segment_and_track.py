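"""Segment a synthetic migrating cell and track its edge.

Generates a 10-frame movie of a polarised fluorescent cell, runs the
combined active-contour + random-walk segmentation unsupervised, tracks the
boundary with ECMM, and prints how well the recovered outlines match the
known ground truth.
"""

import numpy as np

from morphodyn import (AcParams, Outline, RwParams, SeedParams, hausdorff,
                       segment_stack_acrw, track_sequence)
from morphodyn.synthetic import generate_cell_movie, gradient_cell_params

params = gradient_cell_params(frames=10, base_radius=30.0, protrusion_amp=0.3,
                              rotation_deg_per_frame=3.0,
                              motion_px_per_frame=(1.0, 0.5))
movie = generate_cell_movie(params, seed=1)
print(f"movie: {params.frames} frames, cell radius {params.base_radius} px, "
      "fluorescence halving across the cell")

result = segment_stack_acrw(movie.stack, Outline.circle(64, 64, 45, 60),
                            AcParams(), RwParams(), SeedParams())
errors = [hausdorff(result.outlines[t], movie.outlines[t])
          for t in range(params.frames)]
print(f"segmentation error (Hausdorff to truth): "
      f"mean {np.mean(errors):.2f} px, worst frame {max(errors):.2f} px")
# values well below one pixel mean that the recovered boundary is
# sub-pixel accurate despite noise and the intracellular gradient

mappings = track_sequence(result.outlines)
total = sum(m.path_length.sum() for m in mappings)
mean_step = np.mean([m.path_length.mean() for m in mappings])
print(f"edge tracking: {len(mappings)} frame pairs, mean node displacement "
      f"{mean_step:.2f} px/frame, total deformation path {total:.0f} px")
# the mean displacement reflects the cell's boundary speed; the total path
# is the summed deformation 'effort' ECMM minimises
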