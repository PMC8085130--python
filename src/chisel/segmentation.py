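"""Initial nucleus segmentation on the HSV Value channel.

Hematoxylin (blue) and DAB (brown) both render nuclei darker than the
surrounding tissue in the HSV Value channel, so a single adaptive threshold
on V captures immunopositive and immunonegative nuclei alike without color
deconvolution.  The threshold is Bradley's integral-image method: a pixel is
foreground when its value falls more than ``threshold_t`` percent below the
mean of the surrounding window.  The resulting mask initializes a
region-based (Chan–Vese) active contour that tightens each object boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.segmentation import morphological_chan_vese

from .errors import ParameterError


def value_channel(image: np.ndarray) -> np.ndarray:
    """HSV Value channel of an RGB image: per-pixel ``max(R,G,B)/255``."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ParameterError(f"expected HxWx3 RGB image, got shape {image.shape}")
    return image.max(axis=2).astype(np.float64) / 255.0


def _local_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over the window centered at each pixel, window shrunk at borders.

    Computed with an integral image so the cost is independent of window
    size.  At borders the window is truncated to the valid region and the
    mean taken over the pixels actually covered.
    """
    h, w = values.shape
    r = window // 2
    ii = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(np.cumsum(values, axis=0), axis=1, out=ii[1:, 1:])
    r0 = np.clip(np.arange(h) - r, 0, h)
    r1 = np.clip(np.arange(h) + r + 1, 0, h)
    c0 = np.clip(np.arange(w) - r, 0, w)
    c1 = np.clip(np.arange(w) + r + 1, 0, w)
    sums = (
        ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
    )
    counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return sums / counts


def bradley_threshold(
    values: np.ndarray, window: int = 51, threshold_t: float = 15.0
) -> np.ndarray:
    """Adaptive threshold: foreground where ``V < localMean * (1 - t/100)``.

    Parameters
    ----------
    values:
        Value channel in [0, 1].
    window:
        Side of the local-mean window (odd, >= 3, smaller than the image).
    threshold_t:
        Relative cut-off in percent below the local mean.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ParameterError("value channel must be 2-D")
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    if window >= min(values.shape):
        raise ParameterError(
            f"window {window} must be smaller than the image side "
            f"{min(values.shape)}; reduce --window or use a larger image"
        )
    if not 0 < threshold_t < 100:
        raise ParameterError("threshold_t must be in (0, 100)")
    mean = _local_mean(values, window)
    return values < mean * (1.0 - threshold_t / 100.0)


def refine_boundaries(
    values: np.ndarray, init: np.ndarray, iterations: int = 50, pad: int = 8
) -> np.ndarray:
    """Refine a binary mask with a localized region-based active contour.

    Each connected component of ``init`` is evolved independently with a
    morphological Chan–Vese contour on the Value channel, restricted to the
    component's padded bounding box.  Components may change shape, but no
    component is created from an empty region, and evolved foreground that
    detaches from the initial component is discarded.
    """
    values = np.asarray(values, dtype=np.float64)
    init = np.asarray(init, dtype=bool)
    if init.shape != values.shape:
        raise ParameterError("init mask and channel shapes differ")
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if iterations == 0 or not init.any():
        return init.copy()

    out = np.zeros_like(init)
    labels = measure.label(init, connectivity=2)
    for sl in ndi.find_objects(labels):
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, init.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, init.shape[1])
        box = (slice(r0, r1), slice(c0, c1))
        comp = init[box]
        evolved = morphological_chan_vese(
            values[box], num_iter=iterations, init_level_set=comp.astype(np.int8),
            smoothing=1,
        ).astype(bool)
        if not evolved.any():
            continue
        # keep only evolved pieces still touching the initial component
        pieces = measure.label(evolved, connectivity=2)
        keep = np.unique(pieces[comp & evolved])
        keep = keep[keep > 0]
        out[box] |= np.isin(pieces, keep)
    return out
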