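"""Green-vegetation segmentation on the CIELab a* channel.

Wheat seedlings are separated from the soil background by converting the
RGB image to CIELab (sRGB primaries, D65 reference white, standard gamma
decoding) and thresholding the a* channel with Otsu's method.  Green
pixels have strongly negative a*, soil is mildly positive, so vegetation
is always the *low*-a* class.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab

from .errors import DegenerateInputError, ShapeError

__all__ = ["rgb_to_lab", "otsu_threshold", "segment_green"]

_N_BINS = 256


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Validate an RGB raster and scale it to float in [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(
            f"expected H x W x 3 RGB raster, got shape {image.shape}"
        )
    if image.dtype == np.uint8:
        return image / 255.0
    if image.dtype == np.uint16:
        return image / 65535.0
    out = image.astype(float)
    if out.max() > 1.0:
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to CIELab.

    Parameters
    ----------
    image : (H, W, 3) ndarray
        8-bit RGB raster; 16-bit is accepted and rescaled.

    Returns
    -------
    (H, W, 3) float ndarray
        L*, a*, b* channels.  Greener pixels have lower a*.
    """
    return rgb2lab(_as_float_rgb(image))


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a 1-D sample.

    The sample is binned into a 256-bin histogram stretched linearly over
    its observed [min, max] range and the bin boundary maximizing the
    between-class variance is returned.

    Raises
    ------
    DegenerateInputError
        If the sample is constant (no threshold separates anything).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("empty sample")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateInputError("constant sample", value=lo)

    counts, edges = np.histogram(values, bins=_N_BINS, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(counts)[:-1]                       # class sizes below cut
    w1 = counts.sum() - w0
    m = np.cumsum(counts * centers)
    mu0 = m[:-1] / np.where(w0 > 0, w0, 1)
    mu1 = (m[-1] - m[:-1]) / np.where(w1 > 0, w1, 1)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    # cut after bin i -> threshold at edge i+1; a run of empty bins makes
    # the criterion flat, so ties resolve to the middle of the plateau
    # (tolerance: plateau values may differ in the last ulp)
    ties = sigma_b >= sigma_b.max() * (1.0 - 1e-12)
    return float(edges[1:-1][ties].mean())


def segment_green(image: np.ndarray) -> np.ndarray:
    """Segment green vegetation from an RGB field image.

    Returns a boolean mask the shape of the image plane, True where the
    a* value is strictly below the Otsu threshold of the a* sample
    (vegetation is the low-a* class; ties go to background).

    Raises
    ------
    DegenerateInputError
        If the a* channel is constant; the constant is attached to the
        error so callers may map it to an empty mask.
    """
    a_star = rgb_to_lab(image)[:, :, 1]
    thr = otsu_threshold(a_star)
    return a_star < thr
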