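"""Banded binary morphology for whole-slide masks.

Dilation/erosion by a metric radius via the Euclidean distance transform,
processed in horizontal bands so the float64 distance image never spans the
full slide. Exact, because the radius is capped far below the band margin.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

BAND_ROWS = 2048


def dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """All pixels within ``radius_px`` of a True pixel."""
    return _distance_mask(mask, radius_px, invert=True)


def erode(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """True pixels farther than ``radius_px`` from any False pixel."""
    return _distance_mask(mask, radius_px, invert=False)


def close(mask: np.ndarray, radius_px: float) -> np.ndarray:
    return erode(dilate(mask, radius_px), radius_px)


def _distance_mask(mask: np.ndarray, radius_px: float, invert: bool) -> np.ndarray:
    if radius_px <= 0:
        return mask.copy()
    src = ~mask if invert else mask
    n_rows = mask.shape[0]
    margin = int(np.ceil(radius_px)) + 2
    out = np.empty(mask.shape, dtype=bool)
    for r0 in range(0, n_rows, BAND_ROWS):
        r1 = min(r0 + BAND_ROWS, n_rows)
        m0, m1 = max(0, r0 - margin), min(n_rows, r1 + margin)
        d = ndi.distance_transform_edt(src[m0:m1])
        band = d[r0 - m0:r1 - m0]
        out[r0:r1] = (band <= radius_px) if invert else (band > radius_px)
    return out
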