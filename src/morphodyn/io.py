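"""Image-stack, workflow-JSON and CSV input/output.

The workflow container is a JSON document holding the parameters of every
pipeline stage, the per-cell per-frame outlines, the ECMM mappings and the
spatio-temporal maps, so that a complete analysis can be rerun or exchanged
with other languages from one file plus the original image.  Unknown keys
are preserved verbatim on rewrite; numbers survive a round trip bit-exactly
(shortest-repr doubles).  Byte compatibility with any other tool's
container format is not claimed; the schema ships in ``docs/``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ParameterError, SchemaError

log = logging.getLogger(__name__)

FORMAT_VERSION = "morphodyn-1"


@dataclass
class ImageStack:
    """Ordered 2D frames with physical metadata.

    ``pixel_size`` is in micrometres per pixel and ``frame_interval`` in
    seconds; both default to 1.0 (results then read as px and frames).
    A second channel (fluorescence) may ride along in ``channel2``.
    """
    frames: np.ndarray                       # (T, H, W)
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    channel2: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim == 2:
            f = f[None]
        if f.ndim != 3:
            raise ParameterError("frames must be (T, H, W)")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def read_stack(path, channel2_path=None, interleaved: bool = False) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    RGB input is converted to grayscale (mean over channels) and float input
    kept, both with a warning.  Pixel size / frame interval are taken from
    ImageJ-style TIFF metadata when present, else default to 1.0 with a
    logged notice.  ``interleaved=True`` splits alternating pages into the
    segmentation and fluorescence channels; ``channel2_path`` loads the
    fluorescence channel from a second file instead.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        px, dt = 1.0, 1.0
        if "spacing" in meta:
            px = float(meta["spacing"])
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        if res is not None and px == 1.0:
            num, den = res.value
            if num:
                px = den / num
        if "finterval" in meta:
            dt = float(meta["finterval"])
        if px == 1.0 and dt == 1.0 and not meta:
            log.info("read_stack: no physical metadata in %s, using 1 px / 1 frame",
                     path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4)
                          and data.shape[-1] < min(data.shape[:-1])):
        log.warning("read_stack: RGB input converted to grayscale")
        data = data.mean(axis=-1)
        if data.ndim == 2:
            data = data[None]
    if np.issubdtype(data.dtype, np.floating):
        log.warning("read_stack: float TIFF input kept as float")
    ch2 = None
    if interleaved:
        ch2 = data[1::2]
        data = data[0::2]
    elif channel2_path is not None:
        ch2 = read_stack(channel2_path).frames
    return ImageStack(frames=data, pixel_size=px, frame_interval=dt, channel2=ch2)


def write_stack(stack: ImageStack | np.ndarray, path) -> None:
    """Write frames to a multi-page TIFF, preserving dtype."""
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    meta = None
    if isinstance(stack, ImageStack):
        meta = {"finterval": stack.frame_interval, "spacing": stack.pixel_size}
    tifffile.imwrite(str(path), frames, imagej=frames.dtype in
                     (np.uint8, np.uint16, np.float32), metadata=meta)


# ---------------------------------------------------------------------------
# workflow JSON container
# ---------------------------------------------------------------------------

class QconfDocument:
    """Workflow container: parameters + results of every stage.

    Wraps a plain dict (``.data``) so unknown sections survive a
    read-modify-write cycle untouched.  Outline nodes are stored as
    ``[[x, y], ...]`` in pixel units, origin at the center of pixel (0, 0),
    frame indices 0-based.
    """

    def __init__(self, data: dict | None = None):
        self.data = data if data is not None else {
            "version": FORMAT_VERSION,
            "parameters": {},
            "cells": [],
            "provenance": {},
        }
        self.validate()

    # -- schema ----------------------------------------------------------
    def validate(self) -> None:
        d = self.data
        if not isinstance(d, dict):
            raise SchemaError("$", "document is not a JSON object")
        if not isinstance(d.get("version"), str):
            raise SchemaError("$.version", "missing or non-string version")
        if not isinstance(d.get("parameters", {}), dict):
            raise SchemaError("$.parameters", "must be an object")
        cells = d.get("cells", [])
        if not isinstance(cells, list):
            raise SchemaError("$.cells", "must be an array")
        for ci, cell in enumerate(cells):
            frames = cell.get("frames", [])
            if not isinstance(frames, list):
                raise SchemaError(f"$.cells[{ci}].frames", "must be an array")
            for fi, fr in enumerate(frames):
                nodes = fr.get("nodes", [])
                for ni, nd in enumerate(nodes):
                    if (not isinstance(nd, (list, tuple)) or len(nd) != 2
                            or not all(isinstance(v, (int, float)) for v in nd)):
                        raise SchemaError(
                            f"$.cells[{ci}].frames[{fi}].nodes[{ni}]",
                            "node must be a [x, y] number pair")

    # -- content helpers -------------------------------------------------
    def set_outlines(self, outlines, cell: int = 0) -> None:
        cells = self.data.setdefault("cells", [])
        while len(cells) <= cell:
            cells.append({"frames": []})
        cells[cell]["frames"] = [
            {"frame": o.frame_index, "nodes": [[float(x), float(y)]
                                               for x, y in o.nodes]}
            for o in outlines]

    def get_outlines(self, cell: int = 0):
        from .contours import Outline
        frames = self.data["cells"][cell]["frames"]
        return [Outline(np.asarray(fr["nodes"]), frame_index=fr.get("frame", i))
                for i, fr in enumerate(frames)]

    def set_mappings(self, mappings) -> None:
        self.data["ecmm"] = [{
            "landing": m.landing.tolist(),
            "path_length": m.path_length.tolist(),
            "sign": m.sign.tolist(),
        } for m in mappings]

    def set_map(self, stmap) -> None:
        maps = self.data.setdefault("maps", {})
        maps[stmap.kind] = {"units": stmap.units,
                            "values": np.asarray(stmap.values).tolist()}

    def get_map_values(self, kind: str) -> np.ndarray:
        return np.asarray(self.data["maps"][kind]["values"], float)


def read_qconf(path) -> QconfDocument:
    with open(path, encoding="utf-8") as fh:
        return QconfDocument(json.load(fh))


def write_qconf(doc: QconfDocument, path) -> None:
    doc.validate()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc.data, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def export_csv(doc: QconfDocument, what: str, path) -> None:
    """Export ``stats``, ``map:<kind>`` or ``mapping`` as RFC-4180 CSV with a
    header row, '.' decimal separator and deterministic row order."""
    if what == "stats":
        from .cortex import per_frame_stats
        df = per_frame_stats(doc.get_outlines())
        df.to_csv(path, index=False, lineterminator="\r\n")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        if what.startswith("map:"):
            kind = what.split(":", 1)[1]
            values = doc.get_map_values(kind)
            wr.writerow(["frame", "position", "value"])
            for t in range(values.shape[0]):
                for r in range(values.shape[1]):
                    wr.writerow([t, r, repr(float(values[t, r]))])
        elif what == "mapping":
            outlines = doc.get_outlines()
            wr.writerow(["node", "frame", "x0", "y0", "x1", "y1",
                         "pathlen", "sign"])
            for t, m in enumerate(doc.data.get("ecmm", [])):
                nodes = outlines[t].nodes if t < len(outlines) else None
                for i, (land, pl, sg) in enumerate(zip(
                        m["landing"], m["path_length"], m["sign"])):
                    x0, y0 = (nodes[i] if nodes is not None and i < len(nodes)
                              else (float("nan"), float("nan")))
                    wr.writerow([i, t, repr(float(x0)), repr(float(y0)),
                                 repr(float(land[0])), repr(float(land[1])),
                                 repr(float(pl)), int(sg)])
        else:
            raise ParameterError(f"unknown export kind {what!r}")


def read_map_csv(path) -> np.ndarray:
    """Re-parse a map CSV back into its (T, R) value matrix."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))[1:]
    if not rows:
        return np.empty((0, 0))
    T = max(int(r[0]) for r in rows) + 1
    R = max(int(r[1]) for r in rows) + 1
    out = np.full((T, R), np.nan)
    for t, r, v in rows:
        out[int(t), int(r)] = float(v)
    return out
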