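# Methods

## Study design being modelled

The package analyses a cross-sectional two-group cohort: mutation carriers
who will all develop dementia, and non-carrier family controls, each indexed
by estimated years to symptom onset (EYO; negative values precede the
parental age of onset).  The measurements are per-subject mean-diffusivity
(MD) maps already projected onto a shared white-matter skeleton (skeleton
construction and registration are upstream of this package and out of its
scope), a labelled tract atlas on the same grid, binary white-matter
hyperintensity (WMH) masks, fluid/PET biomarkers, grey-matter density maps
and per-tract streamline bundles.

## Voxel-wise model and inference

Per skeleton voxel, ordinary least squares of
`MD ~ 1 + EYO + carrier + EYO x carrier + sex + education` with the t
statistic of the interaction as the test statistic: a positive interaction
means MD rises faster with EYO in carriers.  Coding: carrier 1/0, sex
1 = female / 0 = male.  Voxels with zero residual variance carry no evidence
and are set to t = 0 with a logged warning rather than NaN.

Family-wise error is controlled non-parametrically.  Nuisance covariates are
handled by the Freedman–Lane scheme: fit the reduced (nuisance-only) model,
permute its residual rows, add back the nuisance fit, refit the full model.
Each permuted one-sided t-map is TFCE-enhanced,

    enhanced(v) = sum_h extent(v, h)^E * h^H * dh,

and the maximum enhanced statistic over the mask forms the null.  Corrected
p-values count the proportion of null maxima at least as large as the
voxel's observed enhanced statistic, with the observed statistic included in
its own null, so p >= 1/n_perm.  Defaults: H = 2, E = 0.5, 26-connectivity,
dh = max-statistic/100, 500 permutations (configurable down for speed).
These are the standard constants of the enhancement method; permutation is
unrestricted (no exchangeability blocks for family structure).  The
calibration of this machinery is verified empirically: on complete-null
synthetic cohorts (40 subjects, 16x16x8 grid, 100 permutations, 200
repetitions) the familywise rejection rate at alpha = 0.05 falls inside the
exact binomial 95% band.

A relaxed voxel-based criterion (uncorrected one-sided p < 0.01) exists for
thin tracts where cluster-based enhancement is insensitive; in the pipeline
it backs the a-priori hippocampal cingulum when the corrected map leaves its
ROI empty.  Whether the relaxed threshold is applied to the t-map or p-map is
equivalent here since dof is constant over voxels.

## PSMD

The peak-width of skeletonized mean diffusivity is the 95th minus the 5th
percentile of the MD values inside the custom white-matter mask (the
skeleton minus regions prone to CSF partial-volume effects such as the
fornix).  Percentiles use linear interpolation between closest ranks
(numpy's default); the original published tool's interpolation convention is
not documented, and conventions differ at O(1/n), so the choice is fixed and
stated here.  The empirical distribution is used directly — no histogram
binning, which would only coarsen the percentiles.  Non-finite values inside
the mask raise an error instead of being dropped silently, because they
indicate upstream failures.  At least 20 masked voxels are required.

## Tract ROIs and earliest-abnormality ordering

Tract ROIs are atlas ∩ FWE-significant voxels.  Tracts whose significant
fraction falls below 2% of their voxel count are excluded (the observed
exclusion band in the motivating analyses was 0.8–1.6%, so 2% is a
conservative round default); a-priori tracts override the exclusion.

Per measure (tract-average MD, PSMD), outliers are removed per group by the
upper Tukey rule, value > median + 1.5 IQR.  Upper tail only by default:
MD pathology manifests as an increase, and a symmetric rule would trim the
very subjects carrying signal in the lower tail of controls; a two-sided
variant is available.

The cleaned values are fitted by Huber M-estimation (IRLS, tuning constant
1.345 for 95% Gaussian efficiency, MAD scale, sandwich covariance — the
iteration is delegated to statsmodels' RLM with convergence on the maximum
coefficient change).  The carrier-minus-non-carrier difference at EYO e is

    diff(e) = beta_mut + e * beta_int,

additive covariates cancelling in the difference; its variance follows by
the delta method from the coefficient covariance,
`var(e) = var_mut + e^2 var_int + 2 e cov`, with normal quantiles for the
95% CI (a subject-resampling bootstrap was considered; the delta method is
the default because the CI enters a grid search where the closed form keeps
the estimator deterministic and cheap, and the two agree to first order at
these sample sizes).  A grid point (EYO −25 … +10, step 5) is *abnormal*
when the CI excludes zero **and** the point estimate lies in the
pathological direction — increase for MD/PSMD, decrease for volumes.  The
direction condition is part of the estimator: without it, any significantly
*negative* difference at extreme negative EYO (an artefact of extrapolating
the linear difference line) would count as abnormality.  Results are
reported as half-open intervals (previous grid value, detected value].

### Known bias of the earliest-detection estimator

The ordering fits a *linear* model to group trajectories that are convex
(flat before onset, rising after).  The least-squares line through a ramp
with onset at −10 over uniform EYO in [−25, 10] crosses zero at EYO ≈ −16.9
(closed form), so as noise → 0 the earliest CI-excluding-zero grid point
converges to −15: one grid step *before* the true onset.  At realistic noise
the detection point is noise-dependent and typically lands at −10/−5.  In
validation, demand onset recovery to within one grid step (which holds in
~98–100% of seeded runs at the default settings); exact recovery of the
onset grid point is not a property this estimator can guarantee — planted
recovery at the strict window {−10, −5} plateaus near 80–85% over the whole
noise range, because suppressing the early-bias detection at −15
necessarily also suppresses detection at −10.

## Biomarker trajectories and the cascade

Hippocampal volume is first adjusted for intracranial volume by the
regression approach: the slope of volume on ICV is estimated among
non-carriers (whose volumes are disease-free) and removed from everyone.

Each measure is modelled as a polynomial in EYO with a group offset and an
order-matched carrier-interaction polynomial.  Starting from linear terms,
base and interaction terms of the next order are added jointly while the
AIC keeps decreasing; the last improving model is kept.  Fitting is by the
same Huber M-estimation as the tract analysis; AIC is computed from the
Gaussian quasi-likelihood of the robust fit's residuals (AIC under
M-estimation is not uniquely defined; a plain least-squares variant is the
obvious alternative and behaves identically here).  Note the intrinsic
selection error of AIC: an unnecessary order adds two parameters, so its
false-inclusion probability is P(chi2_2 > 4) ≈ 13.5% asymptotically —
order-recovery simulations should be read against that ceiling (~86%), not
against 100%.

Fitted curves (not a scatter smoother) are evaluated on the EYO grid and
z-standardized against the non-carrier mean/SD, sign-flipped for measures
whose pathological direction is a decrease (CSF Aβ1-42, hippocampal
volume), so all cascade curves rise with abnormality on one axis.

PSMD↔biomarker associations are robust regressions of z-standardized PSMD
on each z-standardized biomarker within carriers, with sex and education as
covariates; p-values are Wald tests from the robust covariance.

## Projection zones

The direction of a streamline's terminal section is the normalized mean of
finite-difference tangents over its last 5 points at spacing 1 (the counts
are unspecified in the motivating description beyond "regularly spaced
points"; 5 points smooth digitization noise without bending the estimate
around curvature).  The fibre is extended from its endpoint along that
direction in 0.5-voxel steps up to 10 voxels; grey-matter voxels traversed,
plus their 1-voxel surrounding neighbourhood intersected with the GM mask,
form the streamline's contribution, and per-tract zones are the union over
the bundle.  An empty zone (fibre never reaches GM) is valid data, not an
error.  GM volume in a zone is the sum of density times voxel volume.
Tract-MD → GM-volume associations are per-tract robust regressions
(volume ~ MD + sex + education, both standardized) with Benjamini–Hochberg
adjustment across tracts.

## WMH analyses

Lesion frequency maps are voxel-wise means of per-subject binary masks per
group.  The sensitivity analysis re-estimates the interaction coefficient
with tract MD averaged separately inside and outside WMH voxels; a side
with fewer than 5 voxels is reported missing rather than zero (a mean over
fewer voxels is dominated by single-voxel noise), and subjects without a
WMH mask would be treated as lesion-free with a log note.  At desk scale
the inside/outside split uses the full atlas tract mask — the
significant-voxel ROI on a 32x32x16 grid is too small to partition by
lesion status — so in practice only tracts in the posterior/periventricular
WMH belt yield enough lesioned voxels for the inside estimate, which is
itself the anatomically plausible regime for WMH confounding.

## Synthetic cohort generator

The generator emulates the data *structure* the analysis assumes, not MR
physics.  Defaults are the study conditions: 64 carriers, 45 non-carriers,
EYO uniform on [−25, 10] (the real cohort's EYO dispersion is wide,
SD ≈ 11; the exact within-group distribution is unreported, so uniform is a
modelling choice), grid 32x32x16 with 15% skeleton voxels, baseline MD
7e-4 mm²/s.

Ten box-shaped "tracts" tile the volume and double as atlas labels and
planted-effect regions; carriers receive a piecewise-linear ramp
`slope * max(0, EYO − onset)` per region (an unambiguous true onset; a
bounded sigmoid is available), with onsets staggered −10 → 0 and slopes
0.8–2e-6 mm²/s per year.  The base slope 2e-6 is chosen to be of the same
order as published presymptomatic MD interaction coefficients (~1.7e-6 for
PSMD).  Noise has two components: iid per-voxel Gaussian (SD 3e-5, optional
Gaussian smoothing of the field to give TFCE spatially correlated noise)
and a per-subject global offset (SD 1e-5) representing biological
between-subject variability, which voxel-averaging cannot remove and which
therefore sets the floor for tract-level precision.  These levels put the
tract-mean noise-to-effect ratio near the regime where the earliest-
detection estimator operates best (see the bias discussion above).  Sex and
education enter additively with configurable coefficients (default 0).
Symptomatic status (CDR > 0) is deterministic: carriers past their
estimated onset.

WMH masks are voxel-wise Bernoulli draws with probability increasing
quadratically toward posterior coordinates, peaking at mid-axial
(periventricular) slices, and scaled up in carriers approaching onset;
frequency maps of generated masks converge to these probabilities (law of
large numbers check at n = 500 in the tests).  Biomarkers are flat in
non-carriers with monotone carrier departures whose onsets encode the
amyloid → tau → microglia/white-matter → atrophy ordering; hippocampal
volume is coupled to ICV so the adjustment step has real work to do.  GM
density maps carry a planted negative coupling between each tract's MD
effect and density in a patch of the GM slab facing that tract's streamline
bundle.  Streamline bundles are straight and gently curved fibres
terminating one voxel short of the GM slab.

Identical config and seed give bit-identical outputs; all draws come from
one `numpy` Generator in fixed order.

What the generator does **not** emulate — and hence what passing tests do
not certify for real data: registration/projection error, scanner and site
effects, spatially structured (non-box) anatomy, longitudinal visits,
family covariance structure, heavy-tailed or skewed MD noise, and any
coupling between WMH voxels and MD values (the WMH sensitivity analysis
therefore tests the *machinery*, with the planted-uniform-effect case as
its positive control).

## Numerical choices and degenerate inputs

- Percentiles and quartiles everywhere use numpy's linear interpolation.
- TFCE integrates thresholds dh, 2dh, … ≤ max with a relative tolerance of
  1e-12 on the last step to absorb float accumulation.
- Permutation p-values are lower-bounded at 1/n_perm by construction.
- Robust fits raise on rank deficiency, non-convergence (no silent
  fallback), and groups smaller than 4 in the Tukey filter.
- Zero-IQR groups in the Tukey filter remove nothing (no value exceeds the
  median); constant responses fit with zero slope.
- Empty tract ROIs, empty projection zones and missing WMH sides are
  explicit "missing" results, never zeros.
- Voxel coordinates are 0-based with integer voxel centres; world
  coordinates come from the NIfTI affine; the JSON manifest is sorted-keys
  and content-only, so identical runs are byte-identical.

## Problem sizes used in validation

Unit and property tests run on grids from 4³ to 16x16x8 with 20–60
subjects.  The headline validation uses: 1000 random vectors for the PSMD
oracle; 100 random 6³ maps for the TFCE oracle; 200 complete-null cohorts
(n = 40, 16x16x8, 100 permutations) for FWE calibration; 100 seeded
full-size cohorts (64/45) for planted-onset recovery; 100 simulations at
n = 300 per polynomial order for AIC recovery; and two full default
pipeline runs (109 subjects, 32x32x16, 500 permutations) for end-to-end
determinism.
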