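"""Gray-level discretization for texture matrices."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: Optional[float] = None,
    n_bins: Optional[int] = None,
) -> Tuple[np.ndarray, int]:
    """Map ROI voxels to integer gray levels 1..Ng; 0 outside the ROI.

    Exactly one of ``bin_width`` (absolute units, e.g. 25 HU) or ``n_bins``
    (relative, equal bins over the ROI range) must be given.  A constant ROI
    maps to a single level.
    """
    if (bin_width is None) == (n_bins is None):
        raise ValueError("specify exactly one of bin_width / n_bins")
    mask = mask.astype(bool)
    x = values[mask].astype(float)
    g = np.zeros(values.shape, dtype=np.int64)
    if x.size == 0:
        return g, 0
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lev = np.floor(x / bin_width) - np.floor(x.min() / bin_width) + 1
    else:
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        rng = np.ptp(x)
        if rng == 0:
            lev = np.ones_like(x)
        else:
            lev = np.clip(np.floor((x - x.min()) / (rng / n_bins)) + 1, 1, n_bins)
    g[mask] = lev.astype(np.int64)
    return g, int(g.max())


def bbox_crop(arrays, mask: np.ndarray, pad: int = 0):
    """Crop arrays (and the mask) to the mask bounding box plus ``pad``."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad, np.array(mask.shape) - 1)
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    return [a[sl] for a in arrays], mask[sl]
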