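"""Volumes, masks, cases: the shared spatial containers.

Every per-case matrix (CT, dose, BED, interaction volumes, masks) lives on a
:class:`VolumeGrid` — a 3-D scalar array plus the geometry needed to place it
in patient space (spacing, origin, direction cosines).  Arrays are indexed
``(i, j, k)`` = ``(x, y, z)``; spacing is millimetres per axis in the same
order, so the pipeline's working grid is ``spacing=(1, 1, 2)``.

All joint computations require grids to be *aligned*: same shape and
geometry within :data:`ALIGN_TOL_MM`.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk

ALIGN_TOL_MM = 1e-3

__all__ = [
    "VolumeGrid",
    "RoiMask",
    "OutcomeRecord",
    "StudyCase",
    "read_volume",
    "write_volume",
    "resample",
    "resample_mask",
    "crop_bundle",
    "preprocess_case",
]


class AlignmentError(ValueError):
    """Grids that must share a geometry do not."""


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values: HU for CT, Gy for dose/BED, unitless for interaction
        matrices.
    spacing : tuple of 3 floats
        Voxel size in mm along (x, y, z); strictly positive.
    origin : tuple of 3 floats
        Physical position (mm) of voxel (0, 0, 0).
    direction : ndarray (3, 3)
        Axis direction cosine matrix (identity = axis-aligned).
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(
            self.values.copy(), self.spacing, self.origin, self.direction.copy()
        )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same geometry, new voxel values (shape must match)."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the grid shape")
        return VolumeGrid(values, self.spacing, self.origin, self.direction.copy())

    def is_aligned(self, other: "VolumeGrid", tol: float = ALIGN_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


def require_aligned(*grids: "VolumeGrid") -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.is_aligned(g):
            raise AlignmentError(
                f"grids not aligned: shapes {ref.shape} vs {g.shape}, "
                f"spacings {ref.spacing} vs {g.spacing}"
            )


@dataclass
class RoiMask:
    """Binary mask on a :class:`VolumeGrid`, tagged with its ROI label."""

    grid: VolumeGrid
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.grid.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be binary, found {uniq[:5]}")
        self.grid = self.grid.with_values(vals.astype(np.uint8))

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0


@dataclass
class OutcomeRecord:
    """Binary failure outcome with time-to-event and competing death."""

    failure: bool
    time_months: float
    competing_death: bool = False

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("time_months must be non-negative")
        if self.failure and self.competing_death:
            raise ValueError("failure and competing_death cannot both be true")

    @property
    def event_code(self) -> int:
        """0 = censored, 1 = treatment failure, 2 = competing death."""
        if self.failure:
            return 1
        if self.competing_death:
            return 2
        return 0


@dataclass
class StudyCase:
    """One patient: CT, total physical dose, masks, prescription, outcome."""

    case_id: str
    ct: VolumeGrid
    dose: VolumeGrid
    clinical_gtv: RoiMask
    ptv: RoiMask
    prescription_dose: float
    n_fractions: int
    outcome: Optional[OutcomeRecord] = None

    def __post_init__(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    def volumes(self) -> dict:
        return {"ct": self.ct, "dose": self.dose}

    def masks(self) -> dict:
        return {"clinical_gtv": self.clinical_gtv, "ptv": self.ptv}

    def check_aligned(self) -> None:
        require_aligned(
            self.ct, self.dose, self.clinical_gtv.grid, self.ptv.grid
        )


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------

def _to_sitk(vol: VolumeGrid) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our values are (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(tuple(vol.direction.ravel()))
    return img


def _from_sitk(img: sitk.Image) -> VolumeGrid:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VolumeGrid(
        arr,
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
        np.asarray(img.GetDirection()).reshape(3, 3),
    )


_FORMAT_EXT = {"nrrd": (".nrrd", ".nhdr"), "nifti": (".nii", ".nii.gz")}


def read_volume(path: str, format: Optional[str] = None) -> VolumeGrid:
    """Read a volume or mask from NRRD, NIfTI, or a DICOM series directory.

    Geometry (spacing/origin/direction) is taken from the header; values are
    returned in native units.
    """
    if format == "dicom-series" or (format is None and os.path.isdir(path)):
        return _read_dicom_series(path)
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # pragma: no cover - message path
        raise IOError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise IOError(f"{path}: expected a 3-D volume, got {img.GetDimension()}-D")
    return _from_sitk(img)


def _read_dicom_series(directory: str) -> VolumeGrid:
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(directory)
    if not names:
        raise IOError(f"no DICOM series found in {directory}")
    reader.SetFileNames(names)
    return _from_sitk(reader.Execute())


def write_volume(vol: VolumeGrid, path: str) -> None:
    """Write a volume to NRRD or NIfTI (chosen by extension)."""
    sitk.WriteImage(_to_sitk(vol), path, useCompression=False)


# ---------------------------------------------------------------------------
# Resampling and cropping
# ---------------------------------------------------------------------------

def resample(
    vol: VolumeGrid,
    target_spacing: Sequence[float],
    mode: str = "linear",
) -> VolumeGrid:
    """Resample onto ``target_spacing`` preserving physical extent.

    ``mode='nearest'`` is mandatory for masks so outputs stay binary.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if np.allclose(target_spacing, vol.spacing, atol=ALIGN_TOL_MM):
        return vol.copy()
    new_size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vol.shape, vol.spacing, target_spacing)
    ]
    img = _to_sitk(vol)
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        target_spacing,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
        True,  # nearest-neighbor extrapolation at the physical boundary
    )
    return _from_sitk(out)


def resample_mask(mask: RoiMask, target_spacing: Sequence[float]) -> RoiMask:
    return RoiMask(resample(mask.grid, target_spacing, mode="nearest"), mask.label)


def _crop_grid(vol: VolumeGrid, lo: np.ndarray, hi: np.ndarray) -> VolumeGrid:
    new_vals = vol.values[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    shift = vol.direction @ (np.asarray(lo, dtype=float) * np.asarray(vol.spacing))
    new_origin = tuple(np.asarray(vol.origin) + shift)
    return VolumeGrid(new_vals.copy(), vol.spacing, new_origin, vol.direction.copy())


def crop_bundle(case: StudyCase, envelope: RoiMask, margin_mm: float = 10.0) -> StudyCase:
    """Crop CT, dose, and masks to the envelope bounding box plus a margin.

    The bounding box is expanded by ``ceil(margin_mm / spacing)`` voxels per
    axis and clipped at volume borders; all outputs share one grid.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    require_aligned(case.ct, envelope.grid)
    if envelope.is_empty:
        raise ValueError("crop envelope mask is empty")
    idx = np.argwhere(envelope.values > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    pad = np.array([int(np.ceil(margin_mm / s)) for s in case.ct.spacing])
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, np.array(case.ct.shape) - 1)

    def crop_mask(m: RoiMask) -> RoiMask:
        return RoiMask(_crop_grid(m.grid, lo, hi), m.label)

    return StudyCase(
        case_id=case.case_id,
        ct=_crop_grid(case.ct, lo, hi),
        dose=_crop_grid(case.dose, lo, hi),
        clinical_gtv=crop_mask(case.clinical_gtv),
        ptv=crop_mask(case.ptv),
        prescription_dose=case.prescription_dose,
        n_fractions=case.n_fractions,
        outcome=copy.copy(case.outcome),
    )


def preprocess_case(
    case: StudyCase,
    target_spacing: Sequence[float] = (1.0, 1.0, 2.0),
    margin_mm: float = 10.0,
    envelope: Optional[RoiMask] = None,
) -> StudyCase:
    """Resample everything to one grid, then crop around the envelope.

    CT and dose are resampled linearly, masks with nearest-neighbour; the
    dose grid is resampled onto the CT grid first when their geometries
    differ.  If no envelope is given the PTV expanded by the peritumoral
    ring is used downstream; here we crop around the PTV box plus margin.
    """
    ct = resample(case.ct, target_spacing, mode="linear")
    dose = resample(case.dose, target_spacing, mode="linear")
    if not dose.is_aligned(ct):
        # force the dose onto the CT grid exactly
        img = sitk.Resample(_to_sitk(case.dose), _to_sitk(ct), sitk.Transform(),
                            sitk.sitkLinear, 0.0)
        dose = _from_sitk(img)
    gtv = resample_mask(case.clinical_gtv, target_spacing)
    ptv = resample_mask(case.ptv, target_spacing)
    out = StudyCase(
        case_id=case.case_id,
        ct=ct,
        dose=dose,
        clinical_gtv=gtv,
        ptv=ptv,
        prescription_dose=case.prescription_dose,
        n_fractions=case.n_fractions,
        outcome=copy.copy(case.outcome),
    )
    env = envelope if envelope is not None else out.ptv
    return crop_bundle(out, env, margin_mm=margin_mm)
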