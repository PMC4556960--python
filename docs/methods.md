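# Methods

## The measure

Functional connectivity density (FCD) is a voxel-wise hub measure for
resting-state BOLD data.  For voxel *i* with time series *x\_i*, and Pearson
correlations *r(i, j)* to every other in-brain voxel *j*,

    totalFCD(i) = Σ_j r(i, j)   over j ≠ i with r(i, j) > r₀,

a *weighted* degree (sum of suprathreshold correlation values, not a count),
with r₀ = 0.25 by default.  Local FCD (lFCD) restricts the sum to voxels
within 3 mm of the seed — on the 3 mm isotropic analysis grid that sphere
contains exactly seven voxels, the seed plus its six face neighbours, and the
seed's own r = 1 is always excluded — while distant FCD (dFCD) keeps only
voxels farther than 25 mm.  The 3–25 mm band belongs to neither map; the
implementation always carries its sum as an explicit `gap` map so the exact
decomposition `local + gap + distant = total` can be asserted at any time.
Negative correlations never contribute (they would break non-negativity of a
density), and all distances are Euclidean between voxel centers in mm.
Each subject's maps are divided by their own in-mask mean ("global mean
connectivity density"), so values are expressed relative to the subject's
average connectivity; per-map divisors are the default, with a shared
total-map divisor available (`normalize_fcd(per_map=False)`), which is the
variant that preserves the decomposition after scaling.

The all-pairs correlation is computed in voxel blocks (exact correlations
via unit-norm rows and a block matrix product); the full N×N matrix is never
materialized and results are bit-for-bit independent of the block size.  A
deliberately naive all-pairs implementation (`naive_fcd`) is kept as a
cross-check and agrees elementwise to 1e-10 on kilovoxel grids.

## Preprocessing

Fixed order: discard the first 10 volumes → per-voxel linear detrend (least
squares) → ideal frequency-domain bandpass 0.01–0.08 Hz (boxcar on the DFT;
bins with low ≤ f ≤ high pass, everything else including DC is zeroed; a
zero-phase Butterworth was considered but the ideal filter has an exactly
testable contract) → nuisance regression (OLS residuals on intercept, six
rigid-body motion parameters, CSF mean, white-matter mean and, by default,
the whole-brain mean).  Nuisance means are computed from the post-bandpass
data over the supplied masks.  Voxels outside the brain mask are never
modified and never contribute to nuisance means.  Motion quality control:
a subject is excluded if any |translation| > 1.0 mm or |rotation| > 1.0°
(strict inequalities), and motion spikes are counted as volumes whose
framewise displacement — sum of absolute backward differences of the six
parameters, rotations converted to arc length on a 50 mm sphere — exceeds a
threshold (default 0.5 mm).

Global-signal regression is on by default (the procedure this pipeline
emulates used it) but is exposed as a flag because it is genuinely
contested, and because on desk-scale synthetic grids it is actively harmful:
when planted hub regions make up ~10% of the "brain", the global mean
contains a large share of the planted signal and regressing it out removes
planted correlations in a group-dependent way (see "recovery scenario").

## Synthetic cohorts

No raw data are distributed with the study this pipeline operationalizes, so
every stage is validated against a seeded generator whose planted structure
has closed-form expectations.

Each voxel's series is a unit-variance Gaussian mixture

    v(t) = Σ_k √c_k · z_k(t) + √(1 − Σ_k c_k) · η(t),

where the z_k are shared band-limited latent signals, η is private noise,
and the couplings c_k ∈ [0, 1] satisfy Σc ≤ 1 per voxel.  Consequences that
make this model a good oracle:

* two voxels sharing latent k with couplings c and c′ have correlation
  exactly √(c·c′) — a coupling *is* the planted correlation between two
  equally coupled voxels (`expected_correlation` returns the closed form);
* variance is pinned at one, so a group-specific multiplier on one coupling
  cannot leak into other correlations through variance inflation;
* latents *and* noise are band-limited strictly inside the analysis passband
  (default 0.015–0.075 Hz at TR = 2 s), so the bandpass stage is
  variance-neutral and preserves planted correlations.

Hubs are seed voxels with a region (default radius 3 mm, i.e. the seed's
face-neighbour sphere; configurable) whose members share the hub's local
latent.  Hub pairs additionally share *pair* latents carrying the distant
coupling; pair latents are assigned to region members by the parity of
i+j+k (a 3D checkerboard).  Because face neighbours always differ in parity,
distant coupling never contributes to any ≤3 mm correlation: local and
distant effects are orthogonal by construction.  A pair whose seeds are not
farther apart than 25 mm is rejected when a distant effect is requested —
the planted correlation would fall into the excluded 3–25 mm band.

Group effects are multipliers on these couplings: both patient groups share
a local-coupling multiplier; only the MHE group rescales distant couplings,
upward for "subcortical" pairs and downward for "cortical" pairs, mirroring
the qualitative finding pattern (shared cortical local deficits in
cirrhosis; a thalamus/caudate-style distant increase specific to MHE).
The magnitudes are free parameters of the generator — the source study
reports no effect sizes in FCD units.

Phenotypes are drawn from normal distributions whose defaults are the
published cohort summaries (controls: age 47.43 ± 10.09 y, education
10.97 ± 3.18 y, 72/103 male, NCT-A 44.06 ± 10.66 s, DST 46.83 ± 12.51;
patients: age 47.99 ± 10.27, education 10.45 ± 3.11, 81/103 male, NCT-A
54.38 ± 20.02, DST 35.52 ± 11.80, ammonia 53.34 ± 34.34 µmol/L).  Both
patient groups draw from the pooled patient distributions, since only
pooled summaries are published.  Motion traces are Gaussian random walks
(SD 0.02 mm / 0.02° per step) with occasional spikes (rate 0.01/volume,
0.4 mm).  The MHE classification rule — abnormal on at least one test,
strictly beyond two control SDs in the impaired direction (NCT-A high, DST
low) — is implemented as a standalone operation.

All randomness flows from one root seed through spawned per-subject
streams; identical (configuration, seed) reproduces outputs at byte level.
Cohorts expose BOLD volumes through a lazy accessor that regenerates each
subject deterministically, so cohort size is not memory-bound.

What the generator does **not** emulate: hemodynamic response functions,
physiological (cardiac/respiratory) noise, scanner drift beyond a linear
trend, spatial autocorrelation of the noise background, registration error,
or any anatomy.  Passing tests therefore demonstrate that the pipeline's
statistics behave as designed on data satisfying its assumptions — not that
the original biological findings are correct.

## Group statistics

Covariate adjustment (age, sex coded 0/1, education) is pre-residualization:
per voxel, subject values are OLS-regressed on the centered covariates and
the residuals (plus grand mean) carry forward; the c consumed degrees of
freedom are charged to the error term (ANOVA df = (k−1, N−k−c); post-hoc
pooled t df = n₁+n₂−2−c).  This is simpler than a full GLM and is slightly
conservative at the voxel level (residualizing on random covariates also
shrinks the between-group sum of squares); the cluster-level null below
includes the same step, so cluster inference remains calibrated.

Cluster-extent correction is Monte-Carlo: simulate null fields on the mask,
threshold at the voxel-level p (default 0.05, the most literal reading of
the stated "P < 0.05"), record the maximum connected-component size
(connectivity 18 by default; 6/26 configurable), and declare the extent
threshold as the smallest k whose null exceedance probability is ≤ α.
Three null-field models are provided, in increasing order of fidelity:

* **z-field** (classic): smooth unit Gaussian noise to the applied kernel
  (8 mm FWHM), re-standardize in-mask, threshold at the upper voxel-p
  quantile.  This is the traditional recipe.
* **statistic-field**: simulate one smoothed, in-mask-centered Gaussian
  noise map per subject, residualize the same number of random covariates,
  run the same ANOVA, and threshold its p map.  This corrects the z-field
  null's main bias for low-df statistic maps: an F field with ~18 error df
  decorrelates spatially faster than the smoothed Gaussian fields it is
  built from (lag-1 autocorrelation ≈ 0.59 vs 0.78 in our conditions), so
  z-field extent thresholds overshoot; at study-scale df the two converge.
* **map-pool** (pipeline default): as statistic-field, but each iteration
  draws its subjects from a pool of *actual null FCD maps* — maps computed
  by the identical conditioning/FCD/normalization/smoothing chain from
  connectivity-free BOLD noise on the same grid.  Gaussian subject fields
  remain measurably mismatched to FCD maps (a thresholded sum of sample
  correlations is skewed and spatially rougher than smoothed Gaussian
  noise, and the local map carries intrinsic neighbour correlation), which
  left residual mis-calibration; resampling genuine null maps matches the
  subject-field distribution exactly and allows a per-map-type extent
  threshold.  The pool (default 200 maps) costs a few seconds and is far
  cheaper than the replicate experiments it calibrates.

Measured family-wise error of the full pipeline at the reference null
conditions is computed by `fcdpipe.calibration.null_fwer` and reported by
the acceptance script rather than quoted here.  Smoothness for the
Gaussian-field nulls is the applied 8 mm kernel; estimating residual
smoothness from data is out of scope.  Smoothing everywhere is masked
Gaussian smoothing (kernel σ = FWHM/√(8 ln 2) per axis) renormalized by the
smoothed mask, so edge voxels are not attenuated; the identical operator is
used on data maps and inside the null simulations.  Cluster peaks are the
largest |statistic| voxel (sign-restricted for directional t contrasts),
ties broken by lowest linear voxel index for determinism.

One-sample t maps (per-group hub pattern), the three-group ANOVA per map
type, and post-hoc pooled-t contrasts restricted to the ANOVA-significant
voxels complete the inference stage.  Post-hoc maps are thresholded on
their two-sided p and split by sign; the extent threshold from the ANOVA
null is reused for them (slightly conservative: the restricted search
region is smaller than the mask the null was simulated on).

## Regional correlations

Mean FCD over each ANOVA-surviving cluster is correlated with clinical
scores within each patient group separately, by partial Spearman: midrank
transform of both variables, OLS removal of the covariates from both rank
vectors, Pearson correlation of the residuals, two-sided p from the t
approximation on n−2−c df (an exact permutation p is available for n ≤ 8).
Region-wise multiplicity is controlled by a Bonferroni cutoff α/n_regions,
where n_regions counts the regions with detected FCD alterations; the
reporting rule distinguishes "significant before correction" (p < α) from
"significant after correction" (p < α/n_regions).

## Validation experiments

`fcdpipe.calibration` runs the two whole-pipeline experiments.

**Null calibration** (`null_fwer`): 3 groups × 8 subjects, 12×12×12 grid at
3 mm, 100 volumes, all multipliers 1 (group labels exchangeable), voxel
p = 0.05, α = 0.05, 1000 Monte-Carlo iterations, 500 replicate cohorts.
The fraction of replicates with at least one surviving cluster estimates
the family-wise error of the full chain (simulate → preprocess → FCD →
normalize → smooth → covariate-adjusted ANOVA → extent correction).  The
cluster null is computed once and shared across replicates — it depends on
the mask, smoothness and thresholds, never on the data.  The FCD stage of
the experiments runs in single precision (correlations accurate to ~1e-6,
irrelevant at Monte-Carlo resolution); all exactness tests use the default
double-precision path.

**Pattern recovery** (`pattern_recovery`): the documented planted-effect
scenario is 3 groups × 12 subjects, 12³ grid, 200 volumes, hub regions of
6 mm radius, control local coupling 0.5 at two uncoupled face-center hubs,
patient local multiplier 0.4, distant coupling 0.35 on one subcortical and
one cortical diagonal pair, MHE distant multipliers 2.0 (subcortical) and
0.4 (cortical), global-signal regression off.  A replicate succeeds when
all six events hold: surviving control>non-HE and control>MHE local
clusters overlapping the planted local regions; no surviving MHE vs non-HE
local cluster; surviving MHE>control and MHE>non-HE distant clusters
overlapping the subcortical regions; and no surviving non-HE>control
distant cluster there.  Two scenario choices deserve explanation:

* *Global-signal regression off.*  With planted regions occupying ~10% of a
  12³ grid, the global mean is signal-laden; regressing it out removed up
  to 85% of patient-group planted local FCD and did so group-dependently
  (the MHE group's stronger distant latents load the global mean more).
  This is the small-brain limit of the well-documented global-signal
  artifact, not a property of the inference machinery being tested.
* *Paired hubs carry no local latent.*  If a region carries both a local
  latent and strong pair latents, the sampling noise of the pair-latent
  correlations is regionally coherent and its amplitude scales with the
  distant coupling — which differs between MHE and non-HE — producing
  group-heteroscedastic local-FCD noise and spurious MHE vs non-HE local
  clusters.  Separating the two effect types keeps the planted patterns
  orthogonal, and matches the anatomy of the emulated finding (local
  deficits in sensorimotor/visual regions; distant changes in
  thalamus/caudate).

Scenario sample sizes and volume counts were chosen as the smallest
configuration in which the planted effects are comfortably detectable by
the corrected inference on one CPU; they are stated here as the package's
reference conditions.

## Numerical choices and degenerate inputs

* Correlations are computed from unit-norm centered rows; `r > r₀` is a
  strict comparison; the self-correlation is removed by subtracting the
  known r = 1 contribution rather than editing the matrix diagonal.
* Distance-class comparisons carry a 1e-9 mm² tolerance so exact-boundary
  face neighbours classify identically in the blocked and naive paths.
* Zero-variance in-mask voxels are a hard error in FCD (correlation
  undefined); zero-variance voxels in one-sample t produce ±inf t with a
  warning; empty post-hoc restriction masks warn and return an empty map.
* A rank-deficient nuisance design aborts with the names of the collinear
  columns.
* Tiny negative rounding residues in the derived gap/distant maps are
  clipped at zero to preserve map non-negativity.

## Known limitations

* The education comparison printed in the emulated study's cohort table
  (p = 0.82) is not reproducible from its printed summaries (a pooled or
  Welch t on 10.97 ± 3.18 vs 10.45 ± 3.11 at n = 103 per group gives
  p ≈ 0.24); the table builder reports what it computes.
* The map-pool null calibrates against connectivity-free subjects; data
  with planted hubs additionally carry regionally coherent between-subject
  fluctuations at hub regions that no noise-pool null reproduces.
* Post-hoc contrasts reuse the per-map ANOVA extent threshold rather than
  a t-field-specific null (conservative: the post-hoc search region is
  restricted to the ANOVA-significant voxels).
* The generator's noise is spatially white; real BOLD noise is spatially
  correlated, so absolute cluster sizes on real data would differ.
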