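"""Voxelated biologically effective dose (BED) under the linear-quadratic model.

Different SBRT fractionation schemes (10 Gy x 5, 12 Gy x 4, ...) deliver
different biological effect per physical Gy.  The LQ model rescales a total
physical dose D delivered in n equal fractions of d = D/n into

    BED = n * d * (1 + d / (alpha/beta))

with the alpha/beta ratio encoding tissue radiosensitivity: voxels inside
the PTV are treated as tumor (alpha/beta = 10 Gy), voxels outside as
late-responding normal tissue (alpha/beta = 3 Gy).
"""

from __future__ import annotations

import logging

import numpy as np

from .grids import RoiMask, VolumeGrid, require_aligned

__all__ = ["alpha_beta_map", "compute_bed"]

logger = logging.getLogger(__name__)

AB_TUMOR = 10.0
AB_NORMAL = 3.0


def alpha_beta_map(
    ptv: RoiMask, ab_inside: float = AB_TUMOR, ab_outside: float = AB_NORMAL
) -> VolumeGrid:
    """Per-voxel alpha/beta ratio: ``ab_inside`` within the PTV, ``ab_outside``
    elsewhere."""
    if ab_inside <= 0 or ab_outside <= 0:
        raise ValueError("alpha/beta ratios must be strictly positive")
    vals = np.where(ptv.values > 0, float(ab_inside), float(ab_outside))
    return ptv.grid.with_values(vals)


def compute_bed(
    total_dose: VolumeGrid, n_fractions: int, ab: VolumeGrid
) -> VolumeGrid:
    """BED grid from a total physical dose grid.

    The dose grid holds the plan's *total* dose, so the per-fraction dose is
    d = total / n.  Then BED = n*d*(1 + d/(alpha/beta)) >= total dose, with
    equality exactly where dose is zero.  Negative dose voxels (interpolation
    artefacts) are clipped to zero and counted in the log.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    require_aligned(total_dose, ab)
    total = np.asarray(total_dose.values, dtype=float)
    n_neg = int((total < 0).sum())
    if n_neg:
        logger.warning("clipped %d negative dose voxels to 0", n_neg)
        total = np.clip(total, 0.0, None)
    d = total / float(n_fractions)
    bed = n_fractions * d * (1.0 + d / np.asarray(ab.values, dtype=float))
    return total_dose.with_values(bed)
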