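# Methods

## Setting

Auto-segmentation QA compares a test contour Vy against a manual reference
Vx on a shared voxel grid, and asks two questions: is the geometric
deviation within the band of manual interobserver variability, and does it
matter dosimetrically?  This package implements that full evaluation chain
— metrics, interobserver normalization, worse-case counting, DVH endpoints,
paired statistics — and a synthetic phantom cohort that exercises every
stage.

All physical lengths are centimetres internally; NIfTI and DICOM headers
(mm) are converted at the I/O boundary.  Geometries are axis-aligned; the
origin addresses the *center* of voxel (0,0,0), and every point-in-polygon
and interpolation operation uses voxel centers.  Oblique direction cosines
are rejected rather than silently resampled.

## Geometric metrics

Overlap metrics are exact voxel-count ratios.  DSC is algebraically the
harmonic mean of precision and recall; this identity is asserted to 1e-12
in the tests rather than assumed.

Surface distances operate on boundary-voxel centers: an occupied voxel
with at least one unoccupied 6-neighbor (out-of-grid counts as unoccupied,
so structures touching the grid edge still close).  This definition is
deterministic and resolution-consistent; mesh-based (marching-cubes)
surfaces are out of scope.  Nearest-neighbor queries use a KD-tree and are
verified against an O(n²) all-pairs brute force on random small masks.

Conventions that genuinely admit alternatives, fixed for reproducibility:

- **HD** is the symmetric Hausdorff distance, max over both directed
  maxima.
- **HD95** *averages* the two directed 95th percentiles rather than taking
  their max — deliberately asymmetric with HD, following the symmetrized
  form in which HD95 is usually reported alongside a max-form HD.
- The 95th percentile uses linear interpolation between order statistics
  (numpy's default); a nearest-rank dialect is selectable via
  `percentile_mode` because published values rarely state their dialect.
- Empty masks raise `UndefinedMetricError` instead of returning zeros:
  silent sentinel values corrupt cohort means.

## Interobserver baseline and scoring

Pairwise metrics among multiple observers are pooled (mean and sample SD
over all organs, cases and pairs) into per-metric reference values R.  By
default every *ordered* pair contributes, which makes the pooled recall
and precision means coincide (each intersection is counted against both
volumes); a designated-reference mode is provided for studies that fix a
gold-standard observer, which is the only way pooled recall and precision
can differ.  The per-organ mean DSC is retained separately for the
worse-case rule.

The consolidated score maps a metric value T onto 0–100 via
`max(50 + 50(T−R)/(P−R), 0)` with P the perfect value (DSC 1, distances 0).
An upper clamp at 100 guards T beyond P, which cannot occur for valid
inputs.  The generalized score is the unweighted mean of the DSC, HD95 and
MSD scores over all patient records of an organ/method (per-record scoring,
then pooling).

Worse-case counting uses strict inequality (DSC strictly below the organ's
interobserver mean; ties are not-worse) and reports percentages rounded
half-up to one decimal (18/29 → 62.1%), matching the usual printed style.

## Dosimetry

DVHs are voxel-sampled (a voxel is fully in or out by its center) and
tabulated on uniform bins, default width 0.01 Gy.  Dx% endpoints are read
off the cumulative curve by linear interpolation (a nearest-bin mode exists
for cross-checks against planning systems); on a pure step curve the
interpolation error is bounded by one bin width.  Relative endpoint
differences are reported in percent and require a strictly positive manual
reference dose; a zero reference raises instead of dividing.  Fractional
voxel occupancy is not modeled — DVH accuracy converges with grid
resolution, which is configurable.

The boundary-gradient diagnostic samples the central-difference gradient
magnitude at surface voxel centers (one-sided at the grid edge, with a
warning) and reports Gy/mm, the scale on which penumbra steepness is
quoted clinically.

## Statistics

The paired t statistic (t = mean(d)·√n/sd(d), df = n−1, two-sided) and the
2×2 Pearson chi-square (optional Yates continuity correction, default off,
since reported tables rarely state the convention) are computed from their
closed forms; scipy supplies only the distribution tails.  scipy's own
`ttest_rel` and `chi2_contingency` act as independent oracles in the test
suite.  Zero-variance differences and zero table marginals raise degenerate
errors rather than producing p-values.  Comparisons between two methods on
the same cases are paired; comparisons against the interobserver records
(different cases, different pair structure) use a Welch two-sample test.
No multiple-testing correction is applied; each test is flagged at
p < 0.05 as is conventional in this literature.

## Synthetic phantom cohort

The generator emulates the statistical structure of a masticatory-muscle
auto-segmentation study, not its imagery:

- **Anatomy**: four mirrored ellipsoid pairs (M, T, MP, LP; cm-scale,
  elongated) on a 64×64×40 grid of 0.1×0.1×0.25 cm voxels, a typical
  head-and-neck CT resolution.  Mirroring is an exact array reflection, so
  left/right pairs have identical voxel counts.  Per-case anatomical
  variation applies mild size scaling (SD 5%) and center jitter (SD 0.8 mm).
- **Contour perturbations**: whole-voxel rigid shifts (so distance metrics
  have exact expected values; sub-voxel shifts round), signed
  6-connectivity dilation/erosion, and independent boundary-voxel flips
  with probability p = min(1, sd/mean-spacing), which adds roughly `sd` of
  surface displacement.  This is the simplest model that lands the metrics
  in the manual-variability range (DSC ≈ 0.82–0.90, MSD ≈ 0.05–0.11 cm); it
  is a stand-in, not a claim about how real observers disagree — real
  contour differences are spatially correlated and anatomy-driven, so
  passing tests here validate the *evaluation chain*, not any segmentation
  algorithm.
- **Observers**: three, with shifts up to 0.08 cm and boundary noise
  0.02–0.04 cm, the magnitudes that reproduce the pooled interobserver
  bands above (measured pooled MSD ≈ 0.057 cm, DSC ≈ 0.86).
- **Methods**: `dlas` perturbs at the interobserver magnitude (shift
  0.08 cm, noise 0.03 cm) and `abas` strictly more (0.15 cm, 0.05 cm),
  reproducing the reported ordering — the deep-learning-style method on
  par with manual variability, the atlas-style method behind on every
  metric.
- **Dose fields**: uniform plateaus, linear ramps, and logistic penumbras
  parameterized by plateau (default 66 Gy, a typical head-and-neck
  prescription) and peak gradient (default 5 Gy/mm, matching the >4 Gy/mm
  regime of a jaw penumbra).  A logistic whose *peak* gradient is exactly
  4 Gy/mm cannot move a point dose by 10 Gy over 2.5 mm (the slope decays
  away from the inflection), so the steep-penumbra scenario uses 5 Gy/mm;
  the linear ramp at 4 Gy/mm gives exactly 10 Gy per 2.5 mm and is covered
  separately in tests.

Everything is reproducible bit-for-bit given the seed; per-case and
per-contour random streams are derived from the master seed in a fixed
order.

## Study sizes

The shipped analysis uses 29 evaluation cases (the size of a typical
held-out validation cohort in this setting), 5 multi-observer cases with 3
observers for the baseline (240 ordered pairs over 8 organs), and 8
structures per case.  These sizes make every driver and the full test
suite run in well under a minute while leaving the paired tests amply
powered for the built-in effect sizes.

## Known limitations

- Voxel-center rasterization and voxel-sampled DVHs ignore partial-volume
  effects; both converge with resolution but differ from planning systems
  that use fractional occupancy.
- The perturbation model cannot emulate systematic, spatially coherent
  observer bias (e.g. consistent cranial over-contouring).
- Only axis-aligned geometries are supported; oblique acquisitions must be
  resampled upstream.
- The designated-reference interobserver mode is implemented, but no
  default reference observer is chosen; with ordered pairs the pooled
  recall and precision baselines necessarily coincide.
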