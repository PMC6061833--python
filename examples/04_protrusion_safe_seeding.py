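"""Seeding that survives thin protrusions.

Foreground seeds come from contracting the vectorised cell contour, not
from pixel erosion.  For a 3-px-wide pseudopod and a 4-px contraction,
erosion deletes the protrusion entirely (so the walker would never label it
cell), while the vector contraction collapses it to a spine and keeps
seeds inside it.
"""

import numpy as np
from scipy import ndimage

from morphodyn import seeds_from_mask

yy, xx = np.mgrid[0:80, 0:80]
cell = ((xx - 30) ** 2 + (yy - 40) ** 2 <= 20 ** 2).astype(np.uint8)
cell[39:42, 50:65] = 1          # 3-px-wide, 15-px-long finger
print(f"phantom: disk radius 20 with a 3x15 px finger "
      f"({int(cell.sum())} px total)")

seeds = seeds_from_mask(cell, d_fg=4.0, d_bg=4.0)
in_finger = int(seeds.foreground[39:42, 55:65].sum())
print(f"vector contraction by 4 px: {in_finger} foreground seed(s) "
      "inside the finger")

oy, ox = np.ogrid[0:9, 0:9]
ball = (ox - 4) ** 2 + (oy - 4) ** 2 <= 16
eroded = ndimage.binary_erosion(cell > 0, structure=ball)
print(f"pixel erosion by radius 4:  {int(eroded[39:42, 55:65].sum())} "
      "foreground pixel(s) inside the finger")
# >= 1 vs 0: the contraction keeps thin cellular processes seedable,
# which is what lets the random walker recover pseudopodia and filopodia
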