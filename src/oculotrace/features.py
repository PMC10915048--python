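"""Shared encoder: multi-scale feature pyramid for eye images.

Both heads of the model consume features computed here -- the
segmentation head per pixel, the blink head from pooled maps -- so the
extraction is the shared-encoder analogue of the two-module design.
Pure numpy/scipy so the exported portable runtime can reproduce it
without any training framework.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# Gaussian pyramid scales (pixels) for intensity and gradient features.
INTENSITY_SIGMAS = (1.0, 2.0, 4.0, 8.0)
GRADIENT_SIGMAS = (1.0, 2.0)
BLINK_POOL = 20  # blink head consumes a BLINK_POOL x BLINK_POOL pooled map

N_PIXEL_FEATURES = 1 + len(INTENSITY_SIGMAS) + len(GRADIENT_SIGMAS) + 2


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack, shape (H*W, N_PIXEL_FEATURES).

    Features: raw intensity, Gaussian-smoothed intensity at 4 scales,
    gradient magnitude at 2 scales, and normalized (x, y) coordinates.
    """
    img = _as_float(image)
    h, w = img.shape
    maps = [img]
    for s in INTENSITY_SIGMAS:
        maps.append(ndimage.gaussian_filter(img, s))
    for s in GRADIENT_SIGMAS:
        maps.append(ndimage.gaussian_gradient_magnitude(img, s))
    ys, xs = np.mgrid[0:h, 0:w]
    maps.append(xs / max(w - 1, 1))
    maps.append(ys / max(h - 1, 1))
    return np.stack([m.ravel() for m in maps], axis=1)


DARK_THRESHOLD = 0.45  # gray fraction separating iris/pupil from skin/sclera


def pooled_map(img: np.ndarray, p: int = BLINK_POOL) -> np.ndarray:
    """Block-mean pool a 2-D map down to p x p, flattened."""
    h, w = img.shape
    ye = np.linspace(0, h, p + 1).astype(int)
    xe = np.linspace(0, w, p + 1).astype(int)
    pooled = np.add.reduceat(np.add.reduceat(img, ye[:-1], axis=0), xe[:-1], axis=1)
    counts = np.outer(np.diff(ye), np.diff(xe))
    return (pooled / counts).ravel()


def blink_features(image: np.ndarray) -> np.ndarray:
    """Pooled encoder features for the blink head.

    Concatenates (i) block-means of the sigma=1 smoothed map
    (BLINK_POOL x BLINK_POOL) and (ii) per-column profiles of the dark
    (iris/pupil-like) region: covered fraction plus topmost and
    bottommost dark extent.  The profiles encode how much of the iris
    the eyelids leave visible -- the quantity the blink label is
    defined by.
    """
    img = ndimage.gaussian_filter(_as_float(image), 1.0)
    h, w = img.shape
    dark = img < DARK_THRESHOLD
    any_dark = dark.any(axis=0)
    col_frac = dark.mean(axis=0)
    top = np.where(any_dark, dark.argmax(axis=0), h) / h
    bottom = np.where(any_dark, h - 1 - dark[::-1].argmax(axis=0), -1) / h
    return np.concatenate([pooled_map(img), col_frac, top, bottom])
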