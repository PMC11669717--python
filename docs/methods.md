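# Methods

## Problem setting

Lung SBRT delivers a handful of large fractions to a planning target volume
(PTV) with steep dose falloff into the surrounding lung. Whether a patient
later fails treatment (locally, regionally, or distantly) plausibly depends
not only on the tumor's imaging phenotype (radiomics of the planning CT) or
on the dose distribution alone (dosiomics), but on how the two *interact* at
the voxel level — e.g. whether dose heterogeneity coincides with tissue
heterogeneity in the peritumoral lung. `dosimix` implements a pipeline that
quantifies that interaction and tests whether it improves failure
prediction.

## Pipeline stages

### Grids and preprocessing (`dosimix.grids`)

All per-case matrices live on a `VolumeGrid` (values + spacing + origin +
direction). CT, dose, and masks are resampled to a common 1 x 1 x 2 mm grid
(linear for intensities, nearest-neighbour for masks; the dose grid is
forced onto the CT grid when geometries differ) and cropped to the bounding
box of an envelope structure plus a margin (default 10 mm; the envelope in
routine use is the PTV or the peritumoral region). Resampling preserves the
physical extent and extrapolates by nearest neighbour at the boundary, so
constant fields stay constant. Alignment tolerance is 1e-3 mm.

### Volumes of interest (`dosimix.roi`)

* **semiGTV** — voxels of the clinical GTV with HU in [-550, 2000]
  (inclusive); reduces inter-observer contour variability. An empty result
  is flagged, not fatal.
* **PTV** — given.
* **Peritumoral ring** — voxels outside the PTV within 20 mm of it.
  Distance is Euclidean in physical mm from the candidate voxel center to
  the nearest PTV-voxel center, computed with a distance transform rather
  than iterative dilation so anisotropic voxels are handled exactly.
* **ISO50** — voxels outside the PTV receiving >= 50% of prescription
  (inclusive threshold on total physical dose). Note that ISO50 is a
  dose-derived structure: even "CT-only" features extracted from it carry
  information about the dose distribution's geometry.

### Voxelated BED (`dosimix.bed`)

The linear-quadratic model converts total physical dose D given in n equal
fractions (d = D/n) into a biologically effective dose per voxel:

    BED = n * d * (1 + d / (alpha/beta))

with alpha/beta = 10 Gy inside the PTV (tumor) and 3 Gy outside
(late-responding normal tissue) — a deliberately binary assignment; no
density-based modulation is attempted. Properties used as tests: BED >=
physical dose with equality iff dose = 0, monotone in dose and in
1/(alpha/beta), and BED -> D as alpha/beta -> infinity. Negative input dose
voxels (interpolation artefacts) are clipped to zero and counted.

### Interaction matrices (`dosimix.interaction`)

At every voxel, 3 x 3 x 3 patches are read at identical coordinates from
the CT and BED volumes (edge replication at borders keeps output shape) and
a scalar of the pair is written back at the voxel position:

| metric | definition | range |
|---|---|---|
| ENTROPY | joint Shannon entropy (bits) of the paired, per-patch min-max normalized (ct, bed) values on an 8 x 8 joint grid | [0, log2 27] |
| JSD | Jensen-Shannon divergence (base 2) between the two marginal 8-bin histograms | [0, 1] |
| WASSERSTEIN | first-order 1-D Wasserstein distance between the empirical distributions of normalized patch values (mean absolute difference of sorted samples) | >= 0 |
| SPEARMAN | Spearman rank correlation of the 27 paired values (average ranks for ties; 0 when either patch is constant) | [-1, 1] |
| MULTIPLY | voxelwise product ct * bed, no patching | unbounded |

Numerical conventions: per-patch min-max normalization to [0, 1] before
histogramming (a constant patch puts all mass in bin 1), 8 equal bins (27
samples support few bins; configurable — this is the pipeline's single
largest free parameter), "entropy between two patches" read as *joint*
entropy of the paired values with a marginal-entropy-difference alternative
behind a switch, and Wasserstein on normalized values so HU and Gy scales
are comparable (raw-scale option exposed). The vectorized sliding-window
engine is tested to 1e-10 against an exhaustive per-voxel loop through the
scalar functions.

### Feature extraction (`dosimix.features`)

Each (matrix, ROI) pair yields a fixed 105-feature vector: 14 shape
descriptors (mask-only: mesh volume/surface by marching cubes in physical
mm, sphericity, maximum 3-D/2-D diameters, PCA axis lengths, elongation,
flatness) plus 91 intensity features — 18 first-order and 73 texture
features over five families (GLCM 22, GLRLM 16, GLSZM 16, GLDM 14,
NGTDM 5), all on IBSI-style definitions. The GLCM family omits SumAverage
(identical to 2 x JointAverage under symmetry) and the maximal correlation
coefficient, landing the vector at exactly 105; the feature list is fixed
in code and auditable.

Discretization: fixed 25 HU bin width for CT (absolute units); fixed
32-bin count for BED and interaction matrices, whose dynamic ranges differ
by orders of magnitude. No image filters (wavelet/LoG) are applied.
GLCM/GLRLM aggregate over the 13 unique 3-D directions; GLSZM zones and
GLDM dependencies use 26-connectivity; GLDM alpha = 0.

Model configurations reuse the same extraction over the four ROIs:
CT -> 420 columns, BED -> 420, CT+BED -> 840, and the composite
(CT, BED, and the five interaction matrices) -> 2940. An empty ROI yields
NaN cells and an exclusion report entry; imputation (training-column
median) happens only inside model fitting.

### Feature selection (`dosimix.selection`)

Stage 1: importance ranking by repeated stratified 5-fold cross-validation
(default 10 repeats) of four tree ensembles — Random Forest, Extra Trees,
AdaBoost, XGBoost. Each fit's native importances are min-max normalized to
[0, 1] before averaging (the four algorithms' raw scales are not
commensurate; raw averaging is available behind a switch). Ties break
lexicographically so the ranking is total and reproducible.

Stage 2: a greedy scan keeps a feature iff its |Pearson r| with every
previously kept feature is <= 0.5 on training data, stopping at k = 17.
Both stages see training data only. A `TwoStageFeatureSelector`
(scikit-learn `SelectorMixin`) wraps the two stages for pipeline use.

### Classification (`dosimix.ensemble`)

`BalancedRandomForestClassifier`: each tree trains on a class-balanced
bootstrap (minority-class count drawn from every class; with replacement
when `bootstrap=True`, plain undersampling otherwise). It follows the
scikit-learn estimator API and drops into `GridSearchCV`. The shipped
hyperparameter grid spans n_estimators {50,100,200,300}, max_depth
{2,3,5,7}, min_samples_split {2,4,6,8,10}, min_samples_leaf {1,2,3},
max_features {auto,sqrt,log2}, bootstrap {True,False}, criterion
{gini,entropy} — 2880 combinations, searched by stratified 5-fold CV with
ROC-AUC scoring ('auto' is accepted as the historical synonym of 'sqrt').

### Evaluation (`dosimix.evaluate`)

AUC by trapezoidal ROC integration; confusion metrics at probability
threshold 0.5; DeLong's paired AUC comparison via placement values with a
two-sided normal p (p = 1 flagged when the orderings are identical and the
difference variance vanishes); decision curves with
NB(pt) = TP/N - (FP/N) pt/(1-pt) against treat-all/treat-none; calibration
by equal-width probability bins plus the Brier score.

### Competing risks (`dosimix.competing_risk`)

Failure competes with death. `FineGrayFitter` maximizes the IPCW-weighted
partial likelihood of the subdistribution hazard (Geskus weights
G(t-)/G(T_i-) from the Kaplan-Meier censoring estimator keep
competing-event cases in later risk sets), Newton iterations to gradient
max-norm < 1e-8 (<= 100 iterations, step halving, divergence detection for
separation). Baseline subdistribution cumulative hazard by the weighted
Breslow estimator; CIF(t|x) = 1 - exp(-Lambda0(t) e^{x'beta}), held
constant beyond the last failure time. Covariates are standardized on
training data by default. Discrimination: a competing-risk-adapted
concordance (a pair is usable when the non-failing member is event-free
beyond the failure time or had the competing event); accuracy: IPCW Brier
curve and trapezoidal integrated Brier score. With no competing events and
no censoring, all weights are 1 and the estimator reduces to Cox partial
likelihood — asserted numerically against an independent Cox implementation.

## Synthetic phantoms (`dosimix.phantom`)

The generator emulates what the pipeline needs, not anatomy: a lung-like
background (Gaussian field, mean -750 HU, sd 60, correlated at 3 mm), a
spherical tumor (mean 0 HU, sd 30) whose sphere is the clinical GTV, a PTV
from a 5 mm dilation, and a dose grid at prescription (default 50 Gy in 5
fractions) inside the PTV with exponential falloff (default length 10 mm)
outside, optionally modulated by a multiplicative correlated ripple
(6 mm scale) standing in for plan/heterogeneity dose noise.

Cohorts jitter tumor radius (U(0.8, 1.2) x base), falloff (U(9, 12) mm),
and dose-ripple amplitude (U(0, 0.10)); the default cohort size and failure
fraction are 179 and 54/179. The failure label is Bernoulli with
logit = logit(failure fraction) + effect_size x z, where z is the
standardized mean JSD interaction value in the peritumoral ring — signal
planted *on an interaction feature* so that the composite model's
superiority over CT-only is a testable property. Event times are
exponential conditional on the outcome class (failures mean 20 months;
non-failures die of the competing cause with probability 0.35, mean 40
months, or are censored, mean 48 months); failure cases are not themselves
censored, a simplification that keeps classification labels and event codes
consistent.

The ripple-borne signal was chosen deliberately: planting it on dose
falloff leaks into the "CT-only" model because the ISO50 ROI's geometry
encodes falloff; the ripple moves ring-level patch statistics strongly
while perturbing ISO50 geometry only mildly. What the phantoms do *not*
emulate: real anatomy, breathing motion, scanner kernels, histology-driven
heterogeneity — so passing tests demonstrate pipeline correctness and
signal recovery, not clinical performance.

## Problem sizes used in the tests and the acceptance script

Structural counts run on three phantoms at the working 1 x 1 x 2 mm
resolution (64 x 64 x 32 voxels). The end-to-end comparison uses ten
cohorts of 70 cases at 20 x 20 x 12 voxels (2 x 2 x 2.5 mm), a 60/40
train/test split (28 held-out cases per seed — sized so a single-seed AUC
comparison has adequate power), selection with 2 CV repeats, and a fixed
200-tree depth-3 Balanced Random Forest in place of the 2880-point grid.
The full-scale defaults (179 cases, 10 repeats, full grid, 84/16 split)
remain the package defaults. Fine-Gray recovery uses n = 500 draws from the
classical subdistribution generative model with beta = 0.7.

## Known limitations

* Histogram binning for entropy/JSD (8 bins over min-max-normalized
  patches) is a convention, not a derived optimum; results depend on it.
* The 105-feature list is IBSI-aligned but not byte-identical to any
  specific external extractor's output; counts and closed-form cases are
  tested, exact parity with third-party tools is not claimed.
* The Fine-Gray standard errors are model-based (inverse observed
  information of the weighted likelihood), not robust/sandwich estimates.
* Single hold-out evaluation (as in routine use of the pipeline) gives
  noisy test AUCs at small n; the planted-signal experiment compensates
  with repeated seeds rather than nested CV.
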