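"""Feature vectors and model-specific feature tables.

Feature identifiers follow ``<matrix>__<roi>__<class>__<feature>``, e.g.
``JSD__RING__firstorder__Mean``.  Four model configurations reuse the same
105-feature extraction per (ROI, matrix):

========== ============================================== ========
model      matrices                                       columns
========== ============================================== ========
CT         CT                                             420
BED        BED                                            420
CT_BED     CT, BED                                        840
COMPOSITE  CT, BED, ENTROPY, JSD, MULTIPLY, SPEARMAN,     2940
           WASSERSTEIN
========== ============================================== ========

(105 features x 4 ROIs x number of matrices.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ..bed import alpha_beta_map, compute_bed
from ..grids import RoiMask, StudyCase, VolumeGrid
from ..interaction import all_interaction_volumes
from ..roi import build_rois
from ._discretize import bbox_crop, discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

ROI_LABELS = ("semiGTV", "PTV", "RING", "ISO50")

MODEL_MATRICES: Dict[str, List[str]] = {
    "CT": ["CT"],
    "BED": ["BED"],
    "CT_BED": ["CT", "BED"],
    "COMPOSITE": ["CT", "BED", "ENTROPY", "JSD", "MULTIPLY", "SPEARMAN", "WASSERSTEIN"],
}
MODEL_KINDS = tuple(MODEL_MATRICES)

_CLASS_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

N_FEATURES = sum(len(v) for v in _CLASS_NAMES.values())  # 105
N_SHAPE = len(SHAPE_NAMES)  # 14


@dataclass
class ExtractionConfig:
    """Discretization and neighborhood settings for one matrix kind.

    CT intensities are absolute (HU), so a fixed ``bin_width`` of 25 HU is
    used; dose-like and interaction matrices have incomparable dynamic
    ranges, so they use a fixed ``n_bins`` of 32 over the ROI range.
    """

    bin_width: Optional[float] = None
    n_bins: Optional[int] = 32
    gldm_alpha: float = 0.0

    @classmethod
    def for_matrix(cls, matrix_name: str) -> "ExtractionConfig":
        if matrix_name.upper() == "CT":
            return cls(bin_width=25.0, n_bins=None)
        return cls(bin_width=None, n_bins=32)


@dataclass
class FeatureVector:
    """One (matrix, ROI) extraction: 105 named values plus status flags."""

    matrix: str
    roi: str
    values: Dict[str, float]
    missing: bool = False
    small_roi: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValueError(
                f"feature vector must have {N_FEATURES} entries, got {len(self.values)}"
            )

    @property
    def names(self) -> List[str]:
        return list(self.values)


def feature_names(matrix: str, roi: str) -> List[str]:
    """The 105 identifiers for one (matrix, ROI) pair, in extraction order."""
    return [
        f"{matrix}__{roi}__{cls}__{feat}"
        for cls, feats in _CLASS_NAMES.items()
        for feat in feats
    ]


def extract_features(
    matrix: VolumeGrid,
    roi: RoiMask,
    config: Optional[ExtractionConfig] = None,
    matrix_name: str = "CT",
) -> FeatureVector:
    """The standardized 105-feature vector for one matrix within one ROI.

    Shape features depend only on the mask.  An empty ROI yields an all-NaN
    vector flagged ``missing``; a single-voxel ROI is flagged ``small_roi``
    (its texture features are degenerate).
    """
    if config is None:
        config = ExtractionConfig.for_matrix(matrix_name)
    names = feature_names(matrix_name, roi.label or "ROI")
    mask = roi.values.astype(bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        warnings.warn(f"empty ROI {roi.label!r}: features recorded as missing")
        return FeatureVector(
            matrix_name, roi.label, dict.fromkeys(names, np.nan), missing=True
        )

    spacing = matrix.spacing
    voxel_volume = float(np.prod(spacing))

    (vals_c,), mask_c = bbox_crop([matrix.values], mask, pad=0)
    levels, Ng = discretize(vals_c, mask_c, config.bin_width, config.n_bins)

    blocks = {
        "shape": shape_features(mask_c, spacing),
        "firstorder": firstorder_features(vals_c, mask_c, levels, voxel_volume),
        "glcm": glcm_features(levels, Ng),
        "glrlm": glrlm_features(levels, Ng),
        "glszm": glszm_features(levels, Ng),
        "gldm": gldm_features(levels, Ng, config.gldm_alpha),
        "ngtdm": ngtdm_features(levels, Ng),
    }
    values = {}
    for cls, feats in _CLASS_NAMES.items():
        for feat in feats:
            values[f"{matrix_name}__{roi.label or 'ROI'}__{cls}__{feat}"] = float(
                blocks[cls][feat]
            )
    return FeatureVector(
        matrix_name, roi.label, values, missing=False, small_roi=n_vox < 2
    )


@dataclass
class FeatureTable:
    """Cases x features matrix for one model configuration."""

    data: pd.DataFrame
    model_kind: str
    exclusions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = N_FEATURES * len(ROI_LABELS) * len(MODEL_MATRICES[self.model_kind])
        if self.data.shape[1] != expected:
            raise ValueError(
                f"{self.model_kind} table must have {expected} columns, "
                f"got {self.data.shape[1]}"
            )
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated feature column names")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def compute_case_matrices(
    case: StudyCase, matrices: Sequence[str], **interaction_kwargs
) -> Dict[str, VolumeGrid]:
    """All named matrices for one preprocessed case (CT, BED, interactions)."""
    out: Dict[str, VolumeGrid] = {}
    need = set(m.upper() for m in matrices)
    if "CT" in need:
        out["CT"] = case.ct
    interaction_names = need - {"CT", "BED"}
    if "BED" in need or interaction_names:
        ab = alpha_beta_map(case.ptv)
        bed = compute_bed(case.dose, case.n_fractions, ab)
        if "BED" in need:
            out["BED"] = bed
        if interaction_names:
            vols = all_interaction_volumes(
                case.ct, bed, sorted(interaction_names), **interaction_kwargs
            )
            for name, iv in vols.items():
                out[name] = iv.values
    return out


def build_feature_table(
    cases: Sequence[StudyCase],
    model_kind: str,
    config_overrides: Optional[Dict[str, ExtractionConfig]] = None,
    rois_per_case: Optional[Dict[str, Dict[str, RoiMask]]] = None,
    matrices_per_case: Optional[Dict[str, Dict[str, VolumeGrid]]] = None,
) -> FeatureTable:
    """Assemble the model-specific feature table over a cohort.

    ROIs and matrices are computed per case unless precomputed ones are
    passed in.  A case with an empty ROI keeps its row; the affected cells
    are NaN and the case is listed in ``exclusions``.
    """
    model_kind = model_kind.upper()
    if model_kind not in MODEL_MATRICES:
        raise ValueError(f"unknown model kind {model_kind!r}")
    matrices = MODEL_MATRICES[model_kind]
    rows = {}
    exclusions: Dict[str, str] = {}
    for case in sorted(cases, key=lambda c: c.case_id):
        rois = (
            rois_per_case[case.case_id]
            if rois_per_case is not None
            else build_rois(case)
        )
        mats = (
            matrices_per_case[case.case_id]
            if matrices_per_case is not None
            else compute_case_matrices(case, matrices)
        )
        row: Dict[str, float] = {}
        for mat_name in matrices:
            if mat_name not in mats:
                exclusions[case.case_id] = f"missing matrix {mat_name}"
                row.update(
                    dict.fromkeys(
                        [n for r in ROI_LABELS for n in feature_names(mat_name, r)],
                        np.nan,
                    )
                )
                continue
            cfg = (
                config_overrides.get(mat_name)
                if config_overrides and mat_name in config_overrides
                else ExtractionConfig.for_matrix(mat_name)
            )
            for roi_label in ROI_LABELS:
                fv = extract_features(
                    mats[mat_name], rois[roi_label], cfg, matrix_name=mat_name
                )
                if fv.missing:
                    exclusions.setdefault(
                        case.case_id, f"empty ROI {roi_label}"
                    )
                row.update(fv.values)
        rows[case.case_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "case_id"
    return FeatureTable(df, model_kind, exclusions)
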