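"""Pseudo-absorption reconstruction of DIC images.

Differential interference contrast (DIC) renders a specimen roughly as the
directional derivative of its optical path length along the shear axis,
which defeats intensity-based segmentation.  Reconstruction inverts this by
line-integrating the mean-subtracted image along the shear direction with
exponential forgetting: for each line, ``out(s) = sum_{u<=s}
decay^(s-u) * (in(u) - line mean)``.  The decay keeps the integral bounded
and suppresses the streaking a plain cumulative sum would produce.

The image is rotated (bilinear) so the shear lines become rows, filtered
with a first-order IIR recursion, rotated back, and normalised to the
input's intensity range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .errors import ParameterError


def reconstruct_dic(image: np.ndarray, shear_angle_deg: float = 45.0,
                    decay: float = 0.98, normalize: bool = True) -> np.ndarray:
    """Reconstruct a segmentable pseudo-absorption image from a DIC image.

    Parameters
    ----------
    image : 2D array
        DIC image, any finite dtype.
    shear_angle_deg : float
        Direction of the DIC shear axis (degrees, image x toward image y).
    decay : float
        Exponential forgetting factor per pixel, in (0, 1).  Values near 1
        integrate over long distances (faithful inversion of a derivative);
        smaller values localise the reconstruction.
    normalize : bool
        Rescale the output to the input's [min, max] range.  Disable to get
        the raw (linear-in-input) integral.
    """
    if not (0.0 < decay < 1.0):
        raise ParameterError("decay must be in (0, 1)")
    img = np.asarray(image, float)
    if not np.all(np.isfinite(img)):
        raise ParameterError("image contains non-finite values")

    rot = ndimage.rotate(img, shear_angle_deg, reshape=True, order=1,
                         mode="constant", cval=0.0)
    support = ndimage.rotate(np.ones_like(img), shear_angle_deg, reshape=True,
                             order=1, mode="constant", cval=0.0)
    valid = support > 0.5
    # per-line mean over valid pixels only, so the padding does not bias it
    cnt = np.maximum(valid.sum(axis=1, keepdims=True), 1)
    mean = (rot * valid).sum(axis=1, keepdims=True) / cnt
    x = np.where(valid, rot - mean, 0.0)
    # y[n] = decay * y[n-1] + x[n]
    y = signal.lfilter([1.0], [1.0, -decay], x, axis=1)
    back = ndimage.rotate(y, -shear_angle_deg, reshape=True, order=1,
                          mode="constant", cval=0.0)
    # crop the double rotation back to the input dimensions
    r0 = (back.shape[0] - img.shape[0]) // 2
    c0 = (back.shape[1] - img.shape[1]) // 2
    out = back[r0:r0 + img.shape[0], c0:c0 + img.shape[1]]
    if normalize:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo) * (img.max() - img.min()) + img.min()
    return out


def directional_derivative(image: np.ndarray, shear_angle_deg: float) -> np.ndarray:
    """Forward model: derivative of ``image`` along the shear axis (the
    idealised DIC contrast of a pure phase specimen)."""
    gy, gx = np.gradient(np.asarray(image, float))
    a = np.deg2rad(shear_angle_deg)
    return gx * np.cos(a) + gy * np.sin(a)
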