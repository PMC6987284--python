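# Methods

This note documents the models, conventions and design choices behind
`focusradiomics`, in the spirit of a statistical software methods appendix:
what is computed, under which assumptions, with which defaults, and what
the synthetic experiments do and do not demonstrate.

## Synthetic DCE-MRI cohorts

**What is emulated.** The acquisition geometry of a clinical breast DCE
protocol: five T1-weighted volumes (one unenhanced, four enhanced) on a
60 s grid, 1 mm slices and 1×1 mm in-plane resolution, with one sub-5-mm
enhancing focus per case and a single binary lesion mask aligned to the
series.

**Kinetic model.** Lesion enhancement relative to baseline follows the
three-parameter closed form

    e(t) = A · (1 − exp(−k_in · t)) · exp(−k_out · t)

with amplitude `A` (fraction of baseline), wash-in rate `k_in` (1/min) and
wash-out rate `k_out` (1/min). `k_out = 0` yields a monotonically rising,
persistent curve. This is a deliberately minimal single-compartment-style
form: three interpretable parameters suffice to produce the
persistent-vs-wash-out dichotomy that distinguishes the classes. Class
defaults (baseline 100, jittered ±10% per case):

| class     | A   | k_in | k_out | behaviour at 1/2/3/4 min            |
|-----------|-----|------|-------|-------------------------------------|
| benign    | 0.8 | 0.7  | 0.0   | slow rise, still rising at 4 min    |
| malignant | 1.2 | 3.0  | 0.4   | peak before 1 min, then wash-out    |

Note the crossing pattern: malignant foci are *brighter* at T1 and
*dimmer* at T3–T4 than benign ones, so no single time-point separates the
classes — the discriminative signal is the temporal pattern, as intended.

**Geometry and texture.** The lesion is a randomly oriented ellipsoid with
per-axis diameters drawn from a per-class range (default 3.5–5 mm, the
"focus" regime); voxelisation is by the analytic inequality, which keeps
the digitised volume within discretisation error of (π/6)·d₁d₂d₃. Lesion
voxels are modulated by a multiplicative spatial texture field (smoothed
white noise, renormalised to exactly zero mean and unit SD inside the
mask) scaled by a per-class heterogeneity (default 0.05 benign / 0.15
malignant). Because the field has exactly zero masked mean, the noiseless
masked mean reproduces `baseline·(1+e(t))` to machine precision — the
generator's strongest self-check. The parenchyma background is smoothed
white noise (σ = 3 voxels) renormalised to unit SD and scaled to 8 signal
units around a mean of 60: flat enough to be "background", textured
enough that registration has structure to lock onto.

**Noise and motion.** Additive Gaussian noise (default σ = 2), independent
per volume. Rician noise would be the physically faithful choice, but at
the simulated SNR (≥ 30) the two are indistinguishable and Gaussian keeps
all moments analytic. Optional motion resamples every slice of T1–T4
under a random 2D affine (translation up to the configured amplitude,
rotation up to 2°, shear up to 0.02), recording the true pull-back
transforms for recovery experiments.

**What is *not* emulated.** Pharmacokinetic realism (no Tofts model, no
arterial input function), coil/bias fields, fat suppression, anatomy,
multi-lesion cases. Consequently, passing synthetic tests demonstrates
the *correctness of the algorithms* (registration recovers known motion,
features match their definitions, the selector finds planted signal) —
not clinical performance on real breast MRI.

**Randomness.** Everything flows from `CohortConfig.seed` through
`numpy.random.SeedSequence` spawning (one child stream per case), so
cohorts are bit-reproducible and per-case streams are independent of
generation order. No global RNG is touched.

## Registration

Slice-wise 2D affine, T1–T4 → T0, minimising the mean square intensity
difference. Both slices are standardised to zero mean/unit variance
first, so the systematic brightness difference between enhanced and
unenhanced images does not masquerade as geometry. T0 is the fixed
target. The optimiser is damped Gauss–Newton on the 6 affine parameters
over a 3-level image pyramid (Gaussian anti-aliasing + decimation;
translations rescaled between levels); the metric is evaluated on the
central region (12% margin) to exclude resampling borders, and a step is
only accepted if it lowers the objective, so the accepted MSE is
non-increasing. If the final fit is worse than the identity, the identity
is returned; constant slices return the identity with a `degenerate`
flag. Interpolation is bilinear throughout — at 1 mm resolution cubic
interpolation changes downstream texture negligibly while costing
substantially more.

Recovery accuracy is quoted as the distance, at the slice centre, between
the recovered transform and the inverse of the injected one (pure
parameter differences are not meaningful because a scale about the array
origin trades off against translation). On 20-case cohorts with 2 px
motion the median centre error is ≈ 0.1 px. The lesion mask is never
resampled: segmentation is defined on the registered series.

Registration is off by default in the pipeline because the synthetic
default is motion-free; it is enabled by a flag.

## Radiomic features (43 × 5 = 215)

* **Quantisation**: per ROI, per time-point, equal-width binning of the
  masked intensities into 32 grey levels (configurable);
  `level = min(floor((v−min)/(max−min)·n)+1, n)`. A constant ROI maps to
  level 1 rather than erroring, so unenhanced time-points always process.
  Min–max binning makes all texture features invariant to additive
  intensity shifts.
* **Intensity** (6): Max, Min, Mean, Sigma, Variance (population),
  IntegratedIntensity = sum × voxel volume (mm³).
* **Shape** (5): from the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of the covariance of
  masked voxel *physical* coordinates: axis lengths 4√λ
  (equivalent-ellipsoid convention), Elongation = √(λ₁/λ₂) ≥ 1,
  Eccentricity = √(1 − λ₃/λ₁), Volume = count × voxel volume. Shape is
  computed once from the single mask and replicated across the five
  time-points so each carries a complete 43-feature block. Masks with
  < 2 voxels report axes/eccentricity 0 with a warning.
* **GLCM** (6 statistics × mean/SD): symmetric co-occurrence at offset
  distance 1 along each of the 13 unique 26-neighbourhood directions,
  normalised after summing both orientations; Energy, Entropy (base-2,
  0·log 0 = 0), Inverse Difference Moment, Inertia, Cluster Shade,
  Cluster Prominence. Only masked voxel pairs count.
* **GLRLM** (10 statistics × mean/SD): maximal same-level runs along each
  direction, restricted to the mask (runs break at mask boundaries); the
  ten standard run-length emphases and non-uniformities.
* **Aggregation**: mean and *sample* SD (ddof = 1) over the directions
  that yield at least one pair/run; a direction with none is skipped; if
  only one direction is valid the SD is reported as 0.

These conventions are IBSI-informed but the target is the fixed 43-name
feature list, not certification. Every GLCM/GLRLM statistic is verified
against an independent brute-force pair/run enumeration written from the
definitions alone.

## TWIST-style selection

A chromosome = 1 bit per feature + 1 bit per case (group A/B). Fitness is
the mean of the two crossed 3-NN accuracies on the selected features.
Chromosomes where any group holds fewer than k+1 cases of either class
(crossed 3-NN ill-defined) score 0 — penalty, not repair, for
determinism. The GA is generational: tournament selection (size 2),
uniform crossover (p = 0.9) applied independently to the feature and
split segments, per-bit mutation (default 1/genome length), elitism 1,
population 100 × 200 generations by default (all configurable), feature
bits initialised on with probability 0.2. Elitism makes the best fitness
non-decreasing; a single seed reproduces the whole run.

**Margin tie-break.** Crossed accuracy saturates: on separable data many
distinct subsets reach fitness 1.0, after which pure accuracy gives
selection no gradient and additional informative features enter only by
drift. Chromosomes of equal accuracy are therefore ranked by the mean
vote margin — the average of sign(correct)·|P(+) − 0.5|·2 over test
cases — which rewards subsets whose neighbourhoods are consistently pure.
With the tie-break, planted-signal recovery (3 informative features at
2 SD among 50 noise features, n = 60) succeeds in 20/20 seeded runs
versus ~60% without it. The reported fitness remains the plain crossed
accuracy in [0, 1]. An optional per-feature parsimony penalty exists but
is off by default.

`split_balance_report` documents the homogeneity of the final split:
Mann–Whitney tests per selected feature between A and B with
Benjamini–Hochberg q-values (identical groups short-circuit to p = 1).

## 3-NN classifier

Euclidean distance on z-scored features (centre/scale learned from the
training group; constant features dropped with a warning) — z-scoring is
required because the 215 features span wildly different scales, and it
makes predictions invariant to positive rescaling of any raw feature.
P(+) is the positive fraction of the 3 nearest neighbours, stored as the
printed values {0, 0.33, 0.66, 1}; a case is positive iff P(+) > 0.5,
which for k = 3 is exactly the unweighted majority vote (verified against
an independent implementation). Exact distance ties break by lowest
training-case index, making predictions deterministic. No distance
weighting.

## Diagnostic reporting

Metrics from the per-arm and pooled (element-wise summed) confusion
matrices: sensitivity, specificity, accuracy, PPV, NPV, LR± — full
precision internally, displayed as half-up integer percent (LRs as
integers), matching clinical table convention. A metric with a zero
denominator is reported as undefined, never 0. Confidence intervals are
exact Clopper–Pearson from beta quantiles: the x = n case gives lower
bound (α/2)^(1/n) (e.g. 87% for 27/27, 91% for 37/37), which normal
approximations cannot reproduce; over 2000 simulated binomials per true p
the empirical coverage is ≥ 95% (exact intervals are conservative). ROC
curves sweep the four discrete P(+) values; the trapezoidal AUC equals
the tie-corrected rank statistic (concordant + ½·ties)/(n₊·n₋). The
summary AUC is the *mean of the two per-arm AUCs*, not a pooled-score
AUC, mirroring how crossed evaluations are conventionally tabulated.

## Pipeline

`run_all` executes simulate → (register) → extract → twist → evaluate,
persisting every intermediate artefact (NIfTI + JSON sidecars, CSV
tables, JSON/markdown reports) as an audit trail. Stage seeds derive from
the one global seed by stable hashing of stage names, so toggling a stage
never perturbs another stage's randomness; the same config reproduces the
same `report.json` byte for byte. `validate_inputs` checks a case
directory (5 volumes + mask, consistent shapes/spacings, nonempty mask)
and reports problems in a manifest instead of raising.

## Experiment scales

The test-suite experiments use deliberately small problem sizes chosen to
make their statistical point at interactive cost: texture oracles on 100
random ROIs up to 5×5×5; motion recovery on 20 cases of 8×48×48 voxels
(median error ≈ 0.1 px against a 0.3 px requirement); planted-feature
recovery over 20 seeded GA runs (population 60 × 80 generations); null
calibration over 20 seeded end-to-end runs of 10+10-case cohorts.

## Known limitations

* **Self-evaluated selection is optimistic under the null.** The GA
  maximises the crossed A↔B accuracy, and the final evaluation recomputes
  that same statistic on the same cases. Under a null cohort (identical
  class distributions) the best of many chance-level candidates is
  systematically above chance: measured ≈ 0.87 pooled "accuracy" (20
  seeds, 10+10 cases, population 30 × 20 generations) against the true
  0.5. The bias grows like SD·√(2 ln n_evals) and no desk-scale cohort
  removes it; only evaluation on data the selector never saw would. A
  fixed chromosome (no selection) under label permutation scores 0.5 as
  it should — the bias lives in the maximisation, not the classifier.
  Headline accuracies produced by this design should therefore be read as
  upper bounds; this caveat applies equally to the study design the
  pipeline reimplements.
* The registration target (T0 vs T1) is a convention choice here; T0 was
  chosen as the fixed target.
* Synthetic kinetics are a stand-in: no quantitative claim about real
  focus enhancement curves is made or needed — no reference result
  depends on their specific values.
* GLCM/GLRLM conventions (32 levels, distance 1, sample-SD aggregation)
  are reasonable defaults, not the only defensible ones; all are
  configurable and documented so results are comparable.
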