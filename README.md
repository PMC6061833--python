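# morphodyn

Morphodynamics of highly deformable cells in 2D time-lapse fluorescence
microscopy: segmentation, sub-pixel cell-edge tracking, cortical
fluorescence sampling, and spatio-temporal maps.

Transmembrane signalling localises to the cell membrane — actin regulators
at the front of a migrating cell, myosin at the rear — and quantifying it
requires more than segmenting each frame: points on the cell outline at
time *t* must be linked to corresponding points at *t+1* so that
fluorescence can be followed on *the same piece of boundary* as the cell
deforms.  morphodyn provides that chain for single cells in 2D movies,
aimed at studies of migration and polarisation in amoeboid, immune or
cancer cells.

## What is inside

- **Active contour (snake) segmentation** — a closed contour per frame,
  propagated through the movie, with a pluggable registry of vector
  filters that operate directly on the contour (running mean, protrusion
  removal, your own).
- **Locally adaptive random-walker segmentation** — foreground probability
  `u` solves the graph Dirichlet problem `L u = 0` on unseeded pixels
  (`u = 1` on foreground seeds, `u = 0` on background) with Gaussian edge
  weights `w_ij = exp(-beta d_ij^2)`; the adaptive variant normalises
  `d_ij` by a robust local intensity spread, which tolerates the strong
  intracellular fluorescence gradients and shot noise of polarised cells.
- **Shape-preserving automatic seeding** — seeds are derived from a prior
  mask by contracting/expanding the *vectorised* contour; thin protrusions
  collapse to a retained spine instead of being eroded away.
- **ECMM edge tracking** — each outline node migrates to the next frame's
  outline along the electric field lines of charges placed on both
  contours, an order-preserving correspondence that minimises the summed
  path length (the deformation energy) and works at sub-pixel resolution.
- **Cortical sampling and QA maps** — mean fluorescence in a band of fixed
  width inside the edge, and frames x positions maps of motility
  (signed px/frame), fluorescence and convexity, with the position axis
  registered to boundary material through ECMM.
- **DIC reconstruction**, a synthetic ground-truth movie generator, the
  Hausdorff / false-positives-per-contour-length evaluation metrics, and
  TIFF / workflow-JSON / CSV I/O with a thin `morphodyn` CLI.

## Worked example

```python
import numpy as np
from morphodyn import (AcParams, Outline, RwParams, SeedParams,
                       build_maps, hausdorff, segment_stack_acrw)
from morphodyn.synthetic import generate_cell_movie, gradient_cell_params

params = gradient_cell_params(frames=10, base_radius=30.0,
                              protrusion_amp=0.3,
                              rotation_deg_per_frame=3.0,
                              motion_px_per_frame=(1.0, 0.5))
movie = generate_cell_movie(params, seed=1)

result = segment_stack_acrw(movie.stack, Outline.circle(64, 64, 45, 60),
                            AcParams(), RwParams(), SeedParams())
errors = [hausdorff(result.outlines[t], movie.outlines[t])
          for t in range(10)]
print(f"mean Hausdorff to truth: {np.mean(errors):.2f} px")

maps = build_maps(result.outlines, None, movie.stack,
                  cortex_width_px=8.0, R=180)
print(f"motility map: {maps.motility.values.shape}, "
      f"mean {np.nanmean(np.abs(maps.motility.values)):.2f} px/frame")
```

prints

```
mean Hausdorff to truth: 0.46 px
motility map: (9, 180), mean 0.83 px/frame
```

The first number says the recovered outlines sit within half a pixel of
the known boundary of this synthetic polarised cell (fluorescence halving
across the cell, shot noise, unsupervised parameters).  The motility map
has one row per frame transition and one column per boundary position;
its entries are the signed local edge speed — positive where the boundary
protrudes, negative where it retracts.  `examples/` holds one short
script per capability, each printing the numbers it computes and what
they mean.

The same pipeline runs from the shell, stage by stage, through one
workflow file:

```bash
morphodyn synth --preset gradient-cell --seed 1 --out movie.tif
morphodyn segment-acrw movie.tif --init circle:64,64,45 --qconf run.json
morphodyn track --qconf run.json
morphodyn maps movie.tif --qconf run.json --out-prefix maps
morphodyn export --qconf run.json --what stats --out stats.csv
```

## Documentation

`docs/methods.md` describes the models, parameters and numerical choices;
`docs/qconf-schema.md` documents the workflow JSON container.
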