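# Methods

`roamlight` implements a complete multi-voxel pattern analysis (MVPA)
pipeline for two-group block-design fMRI — synthetic cohort generation,
block GLM, roaming-searchlight decoding, permutation group inference, and a
mass-univariate comparison arm — built so that every stage can be validated
against known ground truth.

## Signal and noise model of the synthetic cohort

Each subject's 4-D dataset follows

```
y_v(t) = b + sum_c w_{v,c} * (boxcar_c ⊗ h)(t) + d_v(t) + e_v(t)
```

per voxel `v`: a constant baseline `b = 100` (arbitrary raw units),
category-specific response weights `w_{v,c}`, the canonical double-gamma
haemodynamic response `h`, voxelwise cosine drift `d`, and stationary AR(1)
Gaussian noise `e`.

**Design.** 8 runs of 112 volumes at TR 3 s (336 s per run; the acquisition
this emulates quotes both 336 s and 114 volumes x 3 s, which disagree — we
keep the internally consistent 112 x 3.0 s and expose both knobs). Each run
contains one 16-s block per category (face, object, body, body part), 32
stimulus blocks per session. Category order rotates Latin-square style
across runs, with reversed rotations on the second half so all 8 runs have
distinct orders and each category occupies each serial position equally
often. Stimulus blocks are spread evenly through the run (rest intervals of
54.4 s by default, never below the 16-s minimum). The even spacing matters:
packing the four blocks back-to-back leaves the HRF-convolved regressors of
adjacent categories strongly overlapping after high-pass filtering, which
correlates the per-run beta noise of the two decoded categories
(r up to +0.25, varying by run) and biases null cross-validated decoding
accuracy measurably above chance (~51–52% in 17-subject null cohorts).
With even spacing the pair correlation is small and uniform (~−0.07) and
the null calibration test recovers 50% within Monte-Carlo error.

**Ground truth.** Informative regions are two 6-mm spheres (stand-ins for
lateral-occipital and fusiform face-selective cortex) inside an ellipsoidal
brain mask; overlapping ROI specifications are made disjoint (earlier
regions claim shared voxels). Within each ROI, each category's weight map is
`mean_amplitude + p_{v,c}` with a mean-centered Gaussian pattern
`p ~ N(0, pattern_sd²)`. Mean-centering enforces *amplitude matching
exactly*: every category evokes the same ROI-mean response, so a
mean-amplitude (univariate) contrast carries no signal by construction.

**The group effect.** "CP" subjects shrink their face and object patterns
toward the common mean by `cp_separability_factor` (default 0.3): the
multivoxel face-object contrast shrinks while the mean response is
untouched. Patterns are drawn *per subject* (same ROIs, same distribution,
same shrinkage; `subject_specific_patterns=True`). This choice is what makes
the univariate group comparison honest: a pattern shared by all subjects
would survive voxelwise group averaging and be visible to a univariate
t-test at single voxels, whereas independently drawn patterns cancel in the
group mean — emulating the between-subject variability of pattern
topography in real cohorts — while decoding accuracy remains spatially
aligned across subjects because the ROIs are shared. For positive controls,
`category_amplitude_offsets` adds a category-selective mean response
(e.g. a face bonus) scaled by `cp_amplitude_factor` in the CP group; that is
the only configuration in which the univariate arm has something to find.

**Calibration of the defaults** (`mean_amplitude=2`, `pattern_sd=0.5`,
`white_sd=1`, `drift_amplitude=1`, `ar1=0.3`): chosen once so that control
subjects decode face vs object clearly above chance but below ceiling
(~0.8–0.9 mean accuracy inside the ROIs) while CP subjects at factor 0.3
sit near chance. An earlier `pattern_sd` of 0.7 put controls at ceiling
(≈1.0), where a separability reduction is unmeasurable, and was corrected
to 0.5. Drift components are cosines with periods above the 128-s analysis
cutoff, so the high-pass filter removes them exactly; this is deliberate —
drift robustness is a property of the filter, not something the GLM should
be fighting.

**What the generator does not emulate:** head motion, physiological noise,
spatial normalization error (all subjects share one grid), susceptibility
dropout, stimulus-level (500-ms) event structure, and behavioral responses.
Passing tests therefore demonstrate the *statistical* machinery — not
robustness to registration or motion artifacts of real data.

## GLM

One regressor per (category, run): a boxcar over the block convolved with
the canonical double-gamma HRF (shape 6 peak, shape 16 undershoot, unit
rates, undershoot ratio 1/6, 32-s support, 0.1-s sampling), plus one
constant per run. Fixation is unmodeled baseline. A discrete-cosine basis
containing every component with period > 128 s (plus the constant) is
projected out of both data and regressors per run — algebraically identical
to including the basis as nuisance regressors — and betas come from
ordinary least squares. No prewhitening: with one beta per condition per run
entering a classifier, residual autocorrelation costs efficiency, not
validity. Volumes are smoothed before the GLM with a separable Gaussian
(4-mm FWHM, σ = FWHM/√(8 ln 2) per axis in voxel units, reflective
boundaries); a `double_smooth` flag applies the kernel twice to mimic the
reading that decoding ran on preprocessed images smoothed once more
(effective √32 ≈ 5.7 mm).

With zero noise the pipeline recovers the implanted weights to ~1e-14,
because the noiseless signal lies exactly in the span of the filtered
regressors; this exactness is asserted in the tests.

## Searchlight decoding

For each in-mask voxel, the spherical neighborhood (default radius 10 mm,
an ellipsoid in index space on the anisotropic 1.4 x 1.4 x 2.0 mm grid) is
intersected with the mask; centers retaining fewer than `min_sphere_voxels`
(default 2) voxels are NaN. The 16 per-(category, run) beta vectors feed a
soft-margin linear SVM (C = 1, no feature selection, no scaling by default;
per-fold z-scoring available behind `standardize`) under leave-one-run-out
cross-validation: 8 folds, each testing the two held-out vectors, fold
accuracy in {0, 0.5, 1}, mean over folds assigned to the center voxel.

Implementation: with a linear kernel the SVM depends on the sphere only
through its 16 x 16 Gram matrix, and a sphere Gram is a sum of voxelwise
products — so the Grams of *all* spheres are obtained at once by convolving
the 136 pairwise product volumes with the sphere indicator (zeroed non-mask
voxels make edge truncation automatic). The per-fold duals are solved by a
batched SMO solver (`roamlight.svm`) with maximal-violating-pair selection,
stopping tolerance 1e-6, exactly the LIBSVM C-SVC formulation. Tests assert
(a) prediction-level agreement with `sklearn.svm.SVC` across hundreds of
random problems and (b) voxel-for-voxel equality of `searchlight_map` with
a naive per-voxel loop around sklearn. Decision ties (a test point exactly
on the hyperplane) go to the lexicographically first category;
the event has measure zero but the rule makes runs bit-reproducible.
Results are independent of evaluation order by construction (pure array
arithmetic per fold).

Interpretive caveat: any sphere that reaches into an informative region
decodes above chance, so information maps smear effects outward by up to
one sphere radius, and the *peak* of a group-difference map localizes only
to within roughly that radius — over a plateau of near-equal information,
between-subject noise decides which voxel peaks. Cluster-level statements
("a significant cluster overlapping region X") are the robust currency;
peak coordinates inside small ROIs are not.

## Group inference

Voxelwise one-sample t (accuracy vs the 50% two-class chance level,
df = n−1) and two-sample t (controls minus CPs; pooled df = n_a+n_b−2, or
Welch with voxelwise Welch–Satterthwaite df — the univariate arm's
convention). Zero-variance voxels become NaN with a logged count. Tails are
one-sided for the directional hypotheses (accuracy > chance, controls >
CPs), configurable.

Familywise error is controlled by permutation rather than random-field
theory: sign-flipping subject maps about the null value (one-sample) or
shuffling group labels (two-sample), 1000 permutations by default. The
max-statistic null gives a voxel-FWE threshold; the max-cluster-extent null
at the cluster-forming threshold (voxelwise p = 0.001 one-sided by default,
consistent with a displayed t > 3.73 at df = 15; 18-connectivity, SPM's
convention) gives corrected cluster p-values
`(1 + #{perm max extent ≥ KE}) / (1 + n_perm)`, which includes the identity
permutation and is therefore never below `1/(1+n_perm)`. Calibration is
tested empirically: over 200 replicate null cohorts the fraction with any
cluster at corrected p ≤ 0.05 matches 0.05 within binomial error. Random-
field-theory thresholds were deliberately not reimplemented: they need the
original smoothness estimates, whereas permutation corrections are exact
under exchangeability and can be *verified* on synthetic cohorts.

Single-subject univariate maps (t across the 8 per-run face-minus-object
betas) use exhaustive sign-flip enumeration when 2^n_runs is small
(256 patterns at 8 runs) and Bonferroni below 6 runs.

## The sensitivity experiment

`sensitivity_experiment` runs both group comparisons on one cohort: the
decoding route (two-sample test on accuracy maps) and the univariate route
(Welch test on contrast images), each with cluster-level permutation
correction, and reports min corrected p and a detection flag per route.
Under the default pattern-separability effect the decoding route detects a
cluster overlapping a truth ROI while the univariate route detects nothing,
in the large majority of cohort seeds; under a null cohort neither detects;
under an amplitude effect both detect. All three regimes are exercised in
the test suite.

## Numerical and scale choices

- Problem sizes in the test suite are desk-scale by design: the full-grid
  (24 x 28 x 16) null-calibration cohort runs 17 subjects end to end; the
  recovery/sensitivity suites use 10–16-voxel-per-axis grids, 56 volumes
  per run, and 199–300 permutations, sizes at which every assertion is
  still a property of the method rather than of the grid.
- Sphere Gram assembly uses FFT convolution; the ~1e-13 relative error is
  far below the scale of any SVM decision value, and the oracle-equality
  test (exact arithmetic on the other side) passes at atol 1e-12.
- Seeds: a cohort's master seed derives per-subject seeds through
  `numpy.random.SeedSequence`; subject pattern draws and noise draws use
  separate salted streams. Identical configuration reproduces on-disk
  NIfTI bytes exactly.
- Degenerate inputs: empty masks, single-class labels, <2 runs, <2
  subjects per group, non-finite features and rank-deficient designs all
  raise with the offending component named; zero-variance voxels NaN.

## Known limitations

- The brain mask is an inscribed ellipsoid and spatial normalization is the
  identity; anatomical variability in region *location* (as opposed to
  pattern topography) is not modeled, so the univariate arm's blindness
  here isolates the pattern-vs-amplitude distinction only.
- OLS betas without prewhitening differ slightly from a generalized-least-
  squares implementation under strong autocorrelation.
- Leave-one-run-out with one sample per class per fold yields coarse
  (0/0.5/1) fold accuracies; per-voxel accuracy has high variance and maps
  should be interpreted at the group level.
- The permutation two-sample null assumes exchangeability of subjects under
  the null; group-specific variance differences are handled by the Welch
  option but heavy-tailed deviations are not modeled.
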