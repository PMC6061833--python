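# Workflow JSON schema

One JSON object per analysis.  Unknown keys at any level are preserved
verbatim on rewrite.  Numbers are shortest-round-trip doubles (bit-stable
across read/write cycles).

```
{
  "version":    "morphodyn-1",            // required, string
  "parameters": {                          // per-stage parameter echo
    "boa":   { ... AcParams fields ... },
    "rw":    { ... RwParams fields ... },
    "seeds": { "d_fg": 8.0, "d_bg": 10.0 },
    "ecmm":  { "step_px": 0.05 },
    "ana":   { "cortex_width_px": 8.0 },
    "qa":    { "R": 400 },
    "dic":   { "shear_angle_deg": 45.0, "decay": 0.98 },
    "synth": { ... MovieParams fields ... }
  },
  "cells": [                               // one entry per cell
    { "frames": [                          // one entry per movie frame
        { "frame": 0,                      // 0-based frame index
          "nodes": [[x, y], ...] }         // CCW outline, pixel units,
      ] }                                  // origin = center of pixel (0,0)
  ],
  "ecmm": [                                // one entry per frame pair t->t+1
    { "landing":     [[x, y], ...],        // per source node
      "path_length": [l, ...],             // px, >= 0
      "sign":        [s, ...] }            // +1 expansion, -1 retraction
  ],
  "maps": {
    "motility":     { "units": "px/frame",       "values": [[...], ...] },
    "fluorescence": { "units": "intensity a.u.", "values": [[...], ...] },
    "convexity":    { "units": "1/px",           "values": [[...], ...] }
  },
  "stats": { "frame": [...], "area": [...], ... },   // per-frame table
  "provenance": { "input": "movie.tif", ... }
}
```

Validation on read checks: `version` present and a string, `parameters` an
object, `cells` an array, and every outline node a `[x, y]` number pair;
violations raise an error naming the JSON path
(e.g. `$.cells[0].frames[2].nodes[5]`).
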