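# Methods

This note documents the models, defaults, numerical choices and limitations
behind `normmap`. It complements the README, which shows what the package
does; here is *why* it does it that way.

## Normative atrophy mapping

A patient's gray-matter (GM) volume map is compared voxel-wise against an
age- and sex-specific normal template:

- **Matching.** Eligible healthy subjects share the patient's sex and satisfy
  |age_subject − age_patient| ≤ w with w = 2 years, bounds inclusive. Ages
  are integer years throughout (cohort demographics in this field are
  reported in integer years); fractional ages in input tables are floored
  with a warning.
- **Template.** Voxel-wise mean μ(v) and SD σ(v) over the matched volumes.
  The SD uses the sample (n−1) denominator by default. This matters at the
  smallest template sizes (n = 3, where the n vs n−1 choice changes σ by
  ~22 %); the population convention is available via `ddof=0` since upstream
  tools do not document their choice. Templates require ≥ 2 subjects and
  unique subject ids — a subject contributes at most once per template.
  Volumes are canonically ordered by subject id before accumulation so the
  template is a function of the subject *set*; two draws of the same
  subjects give bit-identical templates regardless of draw order.
- **Z-map.** z(v) = (x(v) − μ(v)) / σ(v) where σ(v) > ε, with ε = 1e−6 in
  the (arbitrary) GM units. Voxels at or below ε — empty background, or
  degenerate template voxels — are flagged invalid and carry z = 0 rather
  than an infinity; all downstream spatial statistics respect the validity
  mask. Z is invariant under common positive rescaling or shifting of all
  input volumes.

## The consistency experiment

For template size n, the draw → template → z-map chain is repeated R times
with uniform without-replacement draws from the matched pool (subjects may
recur across repeats, never within one). The per-voxel sample SD of z across
the R repeats, averaged over the analysis support, is
SD̄_spatial(n); the curve of SD̄_spatial over n = n_min…n_max is the
experiment's object of study.

Defaults mirror the reference protocol: n_min = 3 (below three subjects the
variance is degenerate), n_max = 100, R = 100, and a patient is eligible
only when the matched pool holds ≥ 100 subjects (min_pool). All four are
configurable; the tests and the acceptance script run scaled-down versions
(16³–24³ grids, n_max 10–40, R 8–30, pools of 19–120) chosen so each check
completes in seconds while leaving the estimated quantities well away from
their decision thresholds.

Design choices that the protocol leaves open:

- **Analysis support.** The spatial mean needs a support definition. Default:
  voxels where the full-pool template mean exceeds 5 % of its maximum (a
  crude brain/background separation for modulated GM maps), intersected with
  the voxels valid in *every* repeat at that n. The intersection rule avoids
  averaging SDs computed over different repeat subsets; an explicit mask
  file can replace the threshold rule. The same support (derived from the
  full pool, not the per-repeat templates) is used at every n so curve
  points are comparable.
- **Fresh draws per n.** Random subsets are drawn independently at each
  template size rather than grown incrementally; the protocol's description
  ("random selection of n eligible subjects", repeated R times) is agnostic
  and fresh draws keep the per-n estimates independent.
- **Randomness.** Counter-based substreams: the RNG for each (patient, n,
  repeat) cell is seeded by a named key — CRC-32 of the patient id, n and
  the repeat index — spawned from one experiment seed. Adding a patient or
  restricting the n-range never perturbs other cells' draws, and the whole
  experiment is bit-reproducible: identical (inputs, config, seed) give
  byte-identical curve CSVs. Curve CSVs serialize floats with 17 significant
  digits so read-back is exact.
- **Degenerate case.** When n equals the pool size every repeat draws the
  same set; with canonical template ordering and an SD computed on
  first-repeat-shifted values (an algebraic no-op that removes cancellation
  error), SD̄_spatial is then *exactly* zero, which the tests assert as an
  identity, not approximately.

## Knee detection

The knee of the decreasing SD̄_spatial curve is found by the Kneedle
construction: fit a cubic smoothing spline to (n, SD̄_spatial), min–max
normalize both axes to [0, 1]², and take the observed n maximizing the
vertical distance between the smoothed curve and the straight chord joining
the first and last normalized points.

- **Smoothing.** Default is automatic: the spline's regularization parameter
  is chosen by generalized cross-validation. `smoothing=0` gives the
  interpolating spline (fitted values equal the data at the samples);
  positive values use the classic residual-budget formulation. The
  acceptance checks validate the detector against a brute-force
  chord-distance maximizer at smoothing 0, where no spline parameter can
  influence the outcome.
- **Distance.** Vertical distance to the chord (the Kneedle difference
  curve) is the default; a perpendicular point-to-chord variant is exposed
  behind a flag and rarely moves the argmax on normalized axes. Decreasing
  curves are handled directly — for a convex decreasing curve the chord lies
  above the curve, and the signed difference chord − curve is maximized.
- **Output contract.** The knee is always one of the observed n values (no
  sub-sample interpolation); ties break toward smaller n; when the maximal
  distance is ≤ 0.01 on normalized axes (e.g. a straight line) no knee is
  declared (`found=False`) rather than reporting an arbitrary point. Flat
  curves (zero y-range) likewise yield `found=False`. The result is
  invariant under affine rescaling of either axis.

The experiment summary reports the per-patient knees' maximum (the headline
"minimum cohort size"), mean ± SD, median and IQR.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on, not
anatomy:

- **Signal model.** Voxel value = μ0 + β·(age − age_ref) + δ·1[male] +
  noise, clipped at 0. Defaults: μ0 = 10 a.u., β = −0.05 a.u./yr (≈ 0.5 %
  of baseline per year, the order of healthy adult GM decline), δ = −0.5
  a.u. age_ref is the midpoint of the cohort's age range so μ0 stays
  interpretable as the mid-cohort female mean. Ages are uniform integers
  over the range — unlike real cohort age pyramids — because uniform ages
  guarantee matched pools at every age in tests; sex is Bernoulli with
  female fraction 0.58, matching the composition typical of pooled healthy
  cohorts (the CLI accepts any ratio).
- **Noise model.** Between-subject variation is a stationary Gaussian random
  field: white noise convolved with a Gaussian kernel of FWHM 4 mm
  (matching common VBM smoothing kernels) under periodic boundary
  conditions, rescaled by the exact variance-reduction factor of the kernel
  (the root of the summed squared impulse response) so the marginal SD
  equals σ_b = 1 a.u. regardless of FWHM. Periodic convolution keeps the
  field exactly stationary, so the rescaling is exact rather than
  edge-dependent.
- **Atrophy model.** Multiplicative GM reduction by (1 − severity) inside an
  ellipsoidal region; the default left/right region masks are
  mirror-symmetric about the mid-sagittal plane, disjoint, and placed
  infero-laterally as a mesiotemporal stand-in. With template SD σ and
  regional mean μ, the expected z inside the lesion approaches −s·μ/σ for
  large templates, which is what the parameter-recovery checks exploit
  (severities 0.1/0.2/0.3 recover strictly ordered mean-z magnitudes).

What the generator does **not** model: realistic cortical geometry, partial
volume effects, scanner/site/protocol effects, age-pyramid demographics,
non-stationary or multi-scale covariance, global covariates (TIV). Passing
tests therefore demonstrate the correctness and stability of the *pipeline*,
not the transferability of any specific knee value to real data: knee
locations depend on the noise structure, and real multi-scanner cohorts are
noisier than this generator.

## Reader-study statistics

- **Diagnosis rule.** "Bihemispheric score ≥ 2" is ambiguous between
  either-hemisphere, both-hemispheres and summed readings; the default is
  max(left, right) ≥ 2 and the alternatives are selectable. Published
  marginal rating tables cannot disambiguate the rule, so it is exposed
  rather than hidden.
- **Metrics.** Accuracy, sensitivity, specificity, PPV and NPV are integer
  percentages with half-up rounding (the convention consistent with printed
  values alongside fractions such as 37/42); a metric whose denominator is
  zero is reported as absent, never as 0.
- **Agreement.** Cohen's κ (scikit-learn) on categorical or binary labels,
  undefined (absent) when both raters share a single category; ICC(2,1)
  (pingouin's two-way random-effects, absolute-agreement, single-measure
  variant) with ICC(1,1)/ICC(3,1) selectable; Cochran's Q (statsmodels)
  with Q = 0, p = 1 on variation-free data; exact binomial McNemar
  (statsmodels) rather than the chi-square approximation, appropriate at
  the small discordant counts typical of reader studies, with Bonferroni
  adjustment (p × number of pairs, capped at 1) across pairwise
  comparisons. Each wrapper is validated in the tests against
  closed-form/ANOVA hand computations, including the identity of Q at k = 2
  with the uncorrected McNemar chi-square.

## Known limitations

- All volumes must share one grid; there is no resampling or registration —
  mismatches are rejected, by design.
- The brain-mask heuristic (5 % of template-mean maximum) is adequate for
  modulated GM maps with empty background but should be replaced by an
  explicit mask for real data with nonzero background intensity.
- Knee location depends on n_max: the chord endpoint moves with the scanned
  range. Comparisons of knee values are meaningful only at a fixed n-range,
  which is why the experiment config pins it.
- The experiment is embarrassingly parallel over patients but runs serially;
  large real-data runs would want process-level parallelism.
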