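# Methods

## Scope

`contour-agree` quantifies how reproducibly different readers delineate a
brain-tumor target volume across imaging sequences. Its ingredients are
(1) an automatic amino-acid-PET segmentation of the gross tumor volume
(GTV) by tumor-to-brain-ratio (TBR) thresholding, (2) pairwise spatial
agreement between readers' binary masks, and (3) the downstream report
statistics used in multi-reader agreement studies. Because clinical
images of this kind are rarely shareable, the package also contains a
synthetic study generator that reproduces the statistical structure the
analysis assumes; every validation claim below is made on that generator.

## TBR segmentation

A voxel belongs to the PET GTV when

    pet(v) / b  >=  t,        t = 1.6 by default,

where `b` is the mean uptake over a background volume of interest (VOI)
in normal contralateral brain. The VOI is the union of six spheres of
20–25 mm diameter (default 20 mm), rasterized by voxel-centre inclusion;
sphere placement is supplied by the operator (or placed programmatically
by the phantom generator) because the clinical procedure is manual. The
thresholded set is intersected with the voxels within a margin (default
30 mm) of a reference MRI GTV, measured as Euclidean distance between
voxel centres with the grid spacing as metric (anisotropy-aware, via a
sampled distance transform), and any operator-supplied physiological-
uptake mask (skin, vessels) is subtracted. Consequences of the
definition, all enforced by tests: the output is a subset of the margin
region, is monotone in both threshold and margin, and is invariant to
global rescaling of the PET image (TBR is a ratio). The threshold
comparison is inclusive (`>=`), so a lesion at exactly the threshold
ratio is segmented. An optional largest-26-connected-component filter
exists but is off by default — multifocal tumors are common in this
disease and connectivity filtering would silently discard foci.

## Agreement coefficients

For masks A, B on a common grid:

    Dice    DSC = 2|A∩B| / (|A|+|B|)
    Jaccard JSC = |A∩B| / |A∪B|
    Overlap OV  = |A∩B| / min(|A|,|B|)

with the identities JSC ≤ DSC ≤ OV and DSC = 2·JSC/(1+JSC). Coefficients
are computed for every unordered reader pair, per patient and sequence.
A comparison whose operand is absent or empty is recorded as MISSING,
not zero: a reader declining to delineate is an absent observation, OV
is undefined for an empty volume, and one consistent rule for all three
metrics keeps the valid-N bookkeeping coherent. Summaries report, per
(sequence, pair) and per sequence pooled: valid N, mean, median and an
unclipped two-sided t-interval for the mean (95% by default). Means are
the headline column; medians are emitted alongside because skewed
agreement distributions are common near the [0,1] boundaries.

## Report statistics

* **Spearman between reader pairs.** For two reader pairs, the per-patient
  metric series are rank-correlated (average ranks for ties, pairwise
  deletion of missing records, minimum 3 complete cases; a constant
  series leaves the correlation undefined and the row is omitted). The
  coefficient is dichotomized at 0.6: `rho >= 0.6` is "strong" (the
  boundary belongs to strong).
* **Friedman cross-comparison.** Blocks are (patient, reader-pair)
  observations complete across all compared sequences (listwise
  deletion, minimum 6 blocks). The omnibus is the Friedman chi-square on
  within-block ranks; a fully tied design returns statistic 0, p 1.
  Post-hoc: pairwise Wilcoxon signed-rank (exact p for ≤ 25 nonzero
  differences, normal approximation with continuity correction beyond),
  Bonferroni-multiplied by the number of pairwise comparisons and capped
  at 1. Mean differences are means of within-block differences A − B.
  Significance is flagged at α = 0.001 by default.
* **ICC.** Volumes (cc) per patient × reader enter the two-way
  random-effects, absolute-agreement, single-rater form ICC(2,1):
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`. The moment
  estimator is deliberately allowed to go negative (near-zero patient
  variance). The 95% CI is the standard F-based interval with
  Satterthwaite degrees of freedom; a zero-residual (perfect agreement)
  matrix collapses the interval onto the estimate. The implementation is
  cross-checked in the test suite against an independent reference
  implementation of the same form.
* **Bland–Altman.** Paired per-patient volumes from two sources give
  points ((v1+v2)/2, v1−v2), bias = mean difference, limits of agreement
  = bias ± 1.96·SD (sample SD). The default "volume of a patient on a
  sequence" is the mean over readers; a single-reader rule
  (`reader:<id>`) is available because published plots do not always say
  which was used.

Missing data policy across procedures: pairwise deletion where the
statistic is defined per pair (Spearman, Bland–Altman), listwise where a
balanced design is required (Friedman, ICC). No imputation anywhere.

## Synthetic studies

One phantom = an ellipsoidal "brain" of uniform uptake 1.0 in a 96³ grid
at 2 mm spacing (a 192 mm cube), an ellipsoidal tumor at a true TBR of
2.0, optional hot distractor spheres near the volume boundary standing
in for scalp/vessel uptake, Gaussian point-spread smoothing (6 mm FWHM,
a typical clinical PET resolution) and i.i.d. Gaussian noise (σ = 5% of
background). Per-sequence truth masks derive deterministically from the
tumor: the contrast core for T1-GD and PET, an 8 mm edema expansion for
T2-FLAIR, and 2–4 mm erosions for the functional maps (rCBV, K2, DWI,
ADC), whose truths can vanish for small tumors — which is exactly how
ADC non-delineations arise downstream. Background-VOI centres are placed
on an arc in the hemisphere opposite the tumor.

The observer model perturbs a truth mask by thresholding its signed
Euclidean boundary distance at `bias + severity·f(x)`, where `f` is a
smooth unit-variance Gaussian random field. Severity (mm) is the
per-sequence dial: 0 reproduces the truth exactly and expected Dice
decreases monotonically in severity (verified by a seeded Monte-Carlo
calibration test). Only connected components touching the truth are
kept — a reader deforms the lesion boundary but does not delineate
distant islands where the random field happens to peak. The field's
correlation length (6 mm) is deliberately shorter than a typical tumor
radius: contour disagreement is wiggly, not a near-uniform inflation,
so surface errors partly cancel in the delineated volume while still
costing Dice; this is what keeps volume ICCs for the reproducible
sequences high without forcing severities down.

Each reader carries a systematic over/under-contouring bias (SD
0.5 mm), and each patient a lognormal difficulty multiplier (log-SD
0.6, truncated at ±1.5 log-SD and centred to geometric mean 1 within a
study) shared by all readers and sequences — ill-defined lesions are
hard for everyone, which is what makes reader pairs correlate across
patients. Truncation stops one patient's tail draw from dominating the
outlier-sensitive volume statistics; centring is an identifiability
constraint (difficulty is a relative patient effect, the per-sequence
severities alone set the absolute scale), which keeps the study-level
agreement pattern stable across simulation seeds. Default severities
(PET 2.0, T1-GD 2.2, T2-FLAIR 3.2, K2 6.0, rCBV/DWI 6.5, ADC 12 mm)
and non-delineation probabilities (0–12%) are implementation constants
chosen so the default 30-patient study reproduces the qualitative
pattern reported for this kind of multi-sequence delineation study:
PET ≈ T1-GD ≳ FLAIR ≫ functional maps, ADC worst, with strong Dice
rank correlations for the morphological sequences. Severities below
half the voxel pitch cannot flip any voxel, so the "high agreement"
severities sit just above it. Random streams are split per (patient,
sequence, reader) with seed sequences, so enlarging a study never
perturbs existing draws, and every artifact is a pure function of
(spec, seed).

What the generator does **not** emulate: real MR/PET contrast and
texture, registration error between modalities, anatomy-driven reader
disagreement (e.g. ventricles, resection cavities), exam-level
missingness correlated across readers, and inter-scanner effects. Nor
is the volume ICC of the *functional* maps calibrated: in clinical
studies readers of a map like ADC delineate essentially unrelated
regions, collapsing the volume ICC toward zero, whereas this observer
model always perturbs a common truth, so patient size variation keeps
functional-map volume ICCs moderate. Passing tests therefore
demonstrate the correctness and calibration of the analysis machinery
on data with the assumed statistical structure — the Dice/Spearman
agreement pattern, not every volume statistic — and say nothing about
clinical performance on patient images.

## Numerical choices and degenerate inputs

* Grid compatibility: absolute 1e-5 tolerance on spacing/affine entries
  (float round-trip through NIfTI headers); any mismatch is an alignment
  error, signalling non-co-registered inputs.
* Distances are mm in world space; indices are 0-based; voxel volume is
  the spacing product; 1 cc = 1000 mm³.
* Two empty masks: every coefficient undefined → MISSING. Empty
  reference mask or empty background VOI: hard error (the procedure is
  meaningless without them).
* t / F quantiles come from scipy; CIs are unclipped.
* Degenerate ICC inputs (no variance at all) are flagged rather than
  reported as numbers.
* Problem sizes used by the validation suite: coefficients are checked
  against a set-counting oracle on 1000 random grids up to 32³; the
  structural-reproduction study is 30 patients × 3 readers × 7 sequences
  on the default 96³ grid; Friedman calibration uses 5000 null
  replicates (30 blocks × 3 sequences) and 1000 shift replicates; ICC
  recovery uses 5 replicates of 500 patients × 3 readers per true-ICC
  value, asserted on the replicate mean (a single draw's reader-variance
  term has only 2 df and is irreducibly noisy).

## Known limitations

* The background-VOI "crescent" arrangement is not enforced — six
  coincident spheres are accepted; geometry is the operator's
  responsibility, as in the manual clinical procedure.
* No image registration or resampling: masks must already share the
  grid of their reference volume.
* The Wilcoxon/Bonferroni post-hoc is one conventional choice among
  several; published cross-comparison tables rarely state theirs.
* ICC model choice (two-way random, absolute agreement, single rater) is
  fixed; other forms (consistency, average-rater) are out of scope.
* DICOM and RT-STRUCT are not read; conversion to NIfTI is expected
  upstream.
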