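"""Small morphology helpers shared across modules.

Wraps the handful of operations whose skimage signatures are in flux
(``remove_small_objects`` min/max-size rename, ``binary_erosion``
deprecation) behind stable, unambiguous semantics.
"""

from __future__ import annotations

import numpy as np
from skimage import measure, morphology

__all__ = ["drop_small", "binary_erode"]


def drop_small(mask_or_labels: np.ndarray, min_size: int) -> np.ndarray:
    """Remove connected components with strictly fewer than ``min_size`` pixels.

    Accepts a boolean mask (returns a mask) or an integer label image
    (returns the label image with small labels zeroed, ids preserved).
    """
    arr = np.asarray(mask_or_labels)
    if arr.dtype == bool:
        labels = measure.label(arr)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size
        keep[0] = False
        return keep[labels]
    sizes = np.bincount(arr.ravel())
    keep = sizes >= min_size
    keep[0] = False
    out = arr.copy()
    out[~keep[arr]] = 0
    return out


def binary_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion with a disk footprint of the given radius."""
    if radius <= 0:
        return mask.copy()
    return morphology.erosion(mask, morphology.disk(radius)).astype(bool)
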