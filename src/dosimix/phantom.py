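"""Synthetic SBRT phantom cohorts with planted image-dose interaction signal.

Each phantom is a parametric lung-like CT volume (Gaussian-textured
background around -750 HU) containing a spherical tumor (around 0 HU with
correlated texture), a clinical GTV equal to the tumor sphere, a PTV from a
5 mm dilation, and a dose grid at prescription inside the PTV with
exponential falloff outside.  Cohorts jitter per-case geometry and dose
falloff, then draw the failure label from a logistic model on the
standardized mean Jensen-Shannon-divergence interaction value in the
peritumoral ring — signal planted on an interaction-matrix feature, so the
composite model's superiority over CT-only is a testable pipeline property.

The phantom is geometric, not anatomically realistic: it exercises
thresholds, rings, falloff, patches, and feature counts, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .bed import alpha_beta_map, compute_bed
from .grids import OutcomeRecord, RoiMask, StudyCase, VolumeGrid
from .interaction import interaction_volume
from .roi import peritumoral_ring

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom_case", "generate_cohort",
           "outcomes_frame"]


@dataclass
class PhantomSpec:
    """Geometry, intensity, and dose parameters of one phantom case."""

    shape: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    tumor_center_mm: Optional[Tuple[float, float, float]] = None  # default: center
    tumor_radius_mm: float = 8.0
    tumor_hu_mean: float = 0.0
    tumor_hu_sd: float = 30.0
    texture_scale_mm: float = 3.0
    lung_hu_mean: float = -750.0
    lung_hu_sd: float = 60.0
    prescription_gy: float = 50.0
    n_fractions: int = 5
    falloff_mm: float = 10.0
    ptv_margin_mm: float = 5.0
    dose_noise_frac: float = 0.05
    dose_noise_scale_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.falloff_mm <= 0:
            raise ValueError("falloff length must be positive")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        center = self.tumor_center_mm or tuple(e / 2 for e in extent)
        r_total = self.tumor_radius_mm + self.ptv_margin_mm
        if any(c - r_total < 0 or c + r_total > e for c, e in zip(center, extent)):
            raise ValueError("tumor (plus PTV margin) does not fit inside the volume")


def _textured_noise(rng, shape, mean, sd, sigma_vox) -> np.ndarray:
    """Gaussian field with spatial correlation, rescaled to the target sd."""
    noise = rng.standard_normal(shape)
    if np.any(np.asarray(sigma_vox) > 0):
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        s = noise.std()
        if s > 0:
            noise = noise / s
    return mean + sd * noise


def generate_phantom_case(spec: PhantomSpec, case_id: str = "phantom",
                          outcome: Optional[OutcomeRecord] = None) -> StudyCase:
    """One tumor-bearing CT phantom with dose falloff around the PTV.

    Fully deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = np.asarray(spec.shape) * spacing
    center = np.asarray(spec.tumor_center_mm or tuple(extent / 2))

    # voxel-center physical coordinates
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spacing)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    dist = np.sqrt(
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    )
    gtv = (dist <= spec.tumor_radius_mm).astype(np.uint8)

    # PTV = GTV dilated by the setup margin (physical mm)
    d_to_gtv = ndimage.distance_transform_edt(gtv == 0, sampling=spacing)
    ptv = (d_to_gtv <= spec.ptv_margin_mm).astype(np.uint8)

    sigma_vox = spec.texture_scale_mm / spacing
    lung = _textured_noise(rng, spec.shape, spec.lung_hu_mean, spec.lung_hu_sd,
                           sigma_vox)
    tumor = _textured_noise(rng, spec.shape, spec.tumor_hu_mean, spec.tumor_hu_sd,
                            sigma_vox)
    ct_vals = np.where(gtv > 0, tumor, lung)

    d_out = ndimage.distance_transform_edt(ptv == 0, sampling=spacing)
    dose_vals = spec.prescription_gy * np.exp(-d_out / spec.falloff_mm)
    if spec.dose_noise_frac > 0:
        # small-scale dose heterogeneity (plan/heterogeneity artefacts);
        # multiplicative so the relative ripple is uniform across falloff
        ripple = _textured_noise(
            rng, spec.shape, 0.0, spec.dose_noise_frac,
            spec.dose_noise_scale_mm / spacing,
        )
        dose_vals = dose_vals * np.clip(1.0 + ripple, 0.0, None)

    grid = VolumeGrid(ct_vals, tuple(spacing))
    return StudyCase(
        case_id=case_id,
        ct=grid,
        dose=grid.with_values(dose_vals),
        clinical_gtv=RoiMask(grid.with_values(gtv), "clinicalGTV"),
        ptv=RoiMask(grid.with_values(ptv), "PTV"),
        prescription_dose=spec.prescription_gy,
        n_fractions=spec.n_fractions,
        outcome=outcome,
    )


@dataclass
class CohortSpec:
    """Cohort-level generation: jitter, outcome model, event times.

    ``effect_size`` is the log-odds of failure per standard deviation of the
    planted signal (the mean JSD interaction value in the peritumoral ring);
    0 gives a null cohort.  Event times are exponential conditional on the
    outcome class; non-failing cases either die of the competing cause
    (probability ``death_fraction``) or are administratively censored.
    """

    n_cases: int = 179
    base: PhantomSpec = field(default_factory=PhantomSpec)
    failure_fraction: float = 54.0 / 179.0
    effect_size: float = 2.0
    radius_jitter: Tuple[float, float] = (0.8, 1.2)
    falloff_range: Tuple[float, float] = (9.0, 12.0)
    dose_noise_range: Tuple[float, float] = (0.0, 0.10)
    failure_time_mean: float = 20.0   # months
    death_time_mean: float = 40.0
    censor_time_mean: float = 48.0
    death_fraction: float = 0.35
    ring_outer_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.failure_fraction < 1:
            raise ValueError("failure_fraction must be in (0, 1)")
        for v in (self.failure_time_mean, self.death_time_mean,
                  self.censor_time_mean):
            if v <= 0:
                raise ValueError("event-time means must be positive")


def _ring_jsd_mean(case: StudyCase, outer_mm: float) -> float:
    """The planted signal: mean JSD interaction value in the peritumoral ring."""
    bed = compute_bed(case.dose, case.n_fractions, alpha_beta_map(case.ptv))
    jsd = interaction_volume(case.ct, bed, "JSD").values
    ring = peritumoral_ring(case.ptv, outer_mm)
    return float(jsd.values[ring.values.astype(bool)].mean())


def generate_cohort(spec: CohortSpec) -> List[StudyCase]:
    """A cohort of phantoms with outcomes linked to the planted signal.

    Per-case phantom parameters are jittered; the failure label is drawn
    from a logistic model on the standardized ring-JSD signal with
    intercept ``logit(failure_fraction)``, so the realized failure count
    sits within binomial noise of the target.
    """
    ss = np.random.SeedSequence(spec.seed)
    case_seeds = ss.generate_state(spec.n_cases * 2).reshape(-1, 2)
    rng = np.random.default_rng(ss.spawn(1)[0])

    cases: List[StudyCase] = []
    signals = np.empty(spec.n_cases)
    for i in range(spec.n_cases):
        crng = np.random.default_rng(case_seeds[i, 0])
        pspec = replace(
            spec.base,
            tumor_radius_mm=spec.base.tumor_radius_mm
            * crng.uniform(*spec.radius_jitter),
            falloff_mm=crng.uniform(*spec.falloff_range),
            dose_noise_frac=crng.uniform(*spec.dose_noise_range),
            seed=int(case_seeds[i, 1] % (2**31 - 1)),
        )
        case = generate_phantom_case(pspec, case_id=f"case{i:04d}")
        signals[i] = _ring_jsd_mean(case, spec.ring_outer_mm)
        cases.append(case)

    z = (signals - signals.mean()) / (signals.std() if signals.std() > 0 else 1.0)
    b0 = np.log(spec.failure_fraction / (1.0 - spec.failure_fraction))
    p_fail = 1.0 / (1.0 + np.exp(-(b0 + spec.effect_size * z)))

    for i, case in enumerate(cases):
        if rng.uniform() < p_fail[i]:
            case.outcome = OutcomeRecord(
                failure=True,
                time_months=float(rng.exponential(spec.failure_time_mean)),
                competing_death=False,
            )
        elif rng.uniform() < spec.death_fraction:
            case.outcome = OutcomeRecord(
                failure=False,
                time_months=float(rng.exponential(spec.death_time_mean)),
                competing_death=True,
            )
        else:
            case.outcome = OutcomeRecord(
                failure=False,
                time_months=float(rng.exponential(spec.censor_time_mean)),
                competing_death=False,
            )
    return cases


def outcomes_frame(cases: Sequence[StudyCase]) -> pd.DataFrame:
    """Outcome records as the standard CSV layout."""
    rows = [
        {
            "case_id": c.case_id,
            "failure": int(c.outcome.failure),
            "time_months": c.outcome.time_months,
            "competing_death": int(c.outcome.competing_death),
        }
        for c in cases
    ]
    return pd.DataFrame(rows).set_index("case_id")
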