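"""Volumes of interest: semi-automatic GTV, peritumoral ring, ISO50.

Four ROIs drive feature extraction: the HU-thresholded semi-automatic GTV
(reduces inter-observer contour variability), the given PTV, a 2 cm
peritumoral ring outside the PTV, and the ISO50 region receiving at least
half the prescription dose outside the PTV.  All constructions work in
physical millimetres so anisotropic voxels (e.g. 1x1x2 mm) are honoured.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import ndimage

from .grids import RoiMask, VolumeGrid, require_aligned

__all__ = ["semi_auto_gtv", "peritumoral_ring", "iso50", "build_rois"]

HU_LOW_DEFAULT = -550.0
HU_HIGH_DEFAULT = 2000.0
RING_OUTER_MM_DEFAULT = 20.0


class EmptyRoiWarning(UserWarning):
    """An ROI construction produced no voxels; its features will be missing."""


def semi_auto_gtv(
    ct: VolumeGrid,
    clinical_gtv: RoiMask,
    hu_low: float = HU_LOW_DEFAULT,
    hu_high: float = HU_HIGH_DEFAULT,
) -> RoiMask:
    """Voxels of the clinical GTV whose HU lies in [hu_low, hu_high].

    Bounds are inclusive; no connectivity filtering is applied.  An empty
    result triggers :class:`EmptyRoiWarning` and returns the empty mask so
    the case can be flagged rather than dropped.
    """
    if hu_low >= hu_high:
        raise ValueError("hu_low must be below hu_high")
    require_aligned(ct, clinical_gtv.grid)
    inside = (ct.values >= hu_low) & (ct.values <= hu_high)
    vals = (inside & (clinical_gtv.values > 0)).astype(np.uint8)
    mask = RoiMask(ct.with_values(vals), "semiGTV")
    if mask.is_empty:
        warnings.warn(
            "semi-automatic GTV is empty (no GTV voxel within HU window)",
            EmptyRoiWarning,
        )
    return mask


def _distance_outside(mask_values: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the nearest
    mask-voxel center; 0 inside the mask."""
    return ndimage.distance_transform_edt(mask_values == 0, sampling=spacing)


def peritumoral_ring(ptv: RoiMask, outer_mm: float = RING_OUTER_MM_DEFAULT) -> RoiMask:
    """Shell of voxels outside the PTV within ``outer_mm`` of it.

    Distance is Euclidean in physical mm from each candidate voxel center to
    the nearest PTV-voxel center (distance transform, not iterative
    dilation).  The ring is disjoint from the PTV by construction and is
    clipped at the volume borders.
    """
    if ptv.is_empty:
        raise ValueError("PTV mask is empty; cannot build a peritumoral ring")
    if outer_mm < 0:
        raise ValueError("outer_mm must be non-negative")
    dist = _distance_outside(ptv.values, ptv.grid.spacing)
    vals = ((dist > 0) & (dist <= outer_mm)).astype(np.uint8)
    return RoiMask(ptv.grid.with_values(vals), "RING")


def iso50(dose: VolumeGrid, prescription: float, ptv: RoiMask) -> RoiMask:
    """Voxels outside the PTV receiving >= 50% of the prescription dose.

    The threshold applies to total physical dose and is inclusive.
    """
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    require_aligned(dose, ptv.grid)
    vals = ((dose.values >= 0.5 * prescription) & (ptv.values == 0)).astype(np.uint8)
    mask = RoiMask(dose.with_values(vals), "ISO50")
    if mask.is_empty:
        warnings.warn("ISO50 region is empty", EmptyRoiWarning)
    return mask


def build_rois(case, outer_mm: float = RING_OUTER_MM_DEFAULT,
               hu_low: float = HU_LOW_DEFAULT, hu_high: float = HU_HIGH_DEFAULT):
    """All four ROIs for a preprocessed case, keyed by label."""
    return {
        "semiGTV": semi_auto_gtv(case.ct, case.clinical_gtv, hu_low, hu_high),
        "PTV": RoiMask(case.ptv.grid, "PTV"),
        "RING": peritumoral_ring(case.ptv, outer_mm),
        "ISO50": iso50(case.dose, case.prescription_dose, case.ptv),
    }
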