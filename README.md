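# mdcascade

Presymptomatic white-matter diffusion analysis for two-group mutation-carrier
cohorts observed across **estimated years to symptom onset (EYO)** — the study
design of autosomal-dominant Alzheimer's disease cohorts, where every mutation
carrier will develop dementia and the parental age of onset anchors a
per-subject disease clock.

The package asks, on skeletonized mean-diffusivity (MD) maps: *where* and —
more importantly — *when* does white-matter microstructure start to diverge
between carriers and non-carriers, and where does that divergence sit inside
the amyloid → tau → neurodegeneration biomarker cascade?

It is aimed at neuroimaging methodologists: every stage runs end-to-end on a
fully synthetic cohort generator with planted ground truth, so each estimator
can be validated (calibration, planted-onset recovery, oracle agreement)
before being pointed at real data.

## What it computes

- **Voxel-wise inference** — per-voxel GLM
  `MD ~ EYO x carrier + EYO + carrier + sex + education`, with family-wise
  error control by Freedman–Lane permutation of reduced-model residuals and
  threshold-free cluster enhancement (TFCE),
  `enhanced(v) = Σ_h extent(v,h)^E · h^H · dh` (H = 2, E = 0.5,
  26-connectivity), using the permutation distribution of the image-wise
  maximum enhanced statistic.
- **PSMD** — the peak-width of skeletonized mean diffusivity, the 95th minus
  5th percentile of the skeleton MD distribution inside a custom white-matter
  mask: a one-number global marker of heterogeneous diffusivity increase.
- **Earliest-abnormality ordering** — per tract (atlas ∩ significant voxels,
  with a small-fraction exclusion rule and an a-priori override for the
  hippocampal cingulum) and for PSMD: per-group Tukey outlier removal
  (values > median + 1.5·IQR), robust Huber M-estimation of the interaction
  model, then the carrier-minus-non-carrier difference
  `diff(e) = β_mut + e·β_int` traced over the grid EYO = −25 … +10 in 5-year
  steps; the earliest grid point whose delta-method 95% CI excludes zero in
  the pathological direction is reported as the half-open interval
  (previous, detected].
- **Biomarker cascade curves** — CSF Aβ1-42, total tau, P-tau181, soluble
  TREM2, precuneus PIB-PET, ICV-adjusted hippocampal volume, plus tract MD
  and PSMD, each fitted as a group-specific EYO polynomial grown by forward
  term addition with AIC stopping, standardized against non-carriers for
  co-plotting; robust PSMD↔biomarker association regressions.
- **Grey-matter projection zones** — tract terminal directions from a series
  of tangents at regularly spaced terminal points, extended into the GM mask;
  GM volume per zone regressed on tract MD with Benjamini–Hochberg FDR.
- **WMH sensitivity** — voxel-wise lesion frequency maps per group, and the
  interaction coefficient re-estimated with MD averaged inside versus outside
  white-matter hyperintensities.

## Worked example

```python
from mdcascade import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=5), "out")
ordering = manifest["stages"]["ordering"]
for measure, e in sorted(ordering["earliest_abnormal"].items()):
    b = ordering["interaction_b"][measure]
    print(f"{measure:22s} earliest abnormal EYO = {e}   interaction B = {b:.3g}")
vox = manifest["stages"]["voxelwise"]
print(f"FWE-significant voxels: {vox['n_sig_voxels_fwe']} (peak t = {vox['peak_t']:.2f})")
assoc = manifest["stages"]["trajectories"]["psmd_association_B"]
print("PSMD ~ CSF abeta42 association B =", round(assoc["csf_abeta42"], 3))
```

prints

```
cingulum_hippocampal   earliest abnormal EYO = 5.0   interaction B = 1.24e-06
forceps_major          earliest abnormal EYO = -10.0   interaction B = 2.2e-06
psmd                   earliest abnormal EYO = -5.0   interaction B = 1.61e-07
FWE-significant voxels: 5 (peak t = 4.42)
PSMD ~ CSF abeta42 association B = -0.481
```

Reading this: on the default synthetic cohort (64 carriers / 45 non-carriers,
EYO −25…+10, a planted MD ramp starting at EYO −10 in the forceps major and
later onsets elsewhere), the forceps major becomes detectably abnormal in the
interval (−15, −10] — a decade before estimated symptom onset — the global
PSMD marker follows at (−10, −5], and the thin a-priori hippocampal cingulum
(analysed under the relaxed voxel-based criterion) only after onset.  Higher
PSMD is associated with lower CSF Aβ1-42 in carriers (standardized B ≈ −0.48).
The interaction B for forceps major (2.2 × 10⁻⁶ mm²/s per EYO year) recovers
the planted slope of 2 × 10⁻⁶.

The same pipeline is available from the shell:

```bash
mdcascade run-all --out out --seed 5 --nperm 500
mdcascade simulate --out cohort --seed 1       # volumes + tables only
mdcascade psmd --md cohort/md --mask cohort/skeleton_mask.nii.gz --out psmd.csv
mdcascade ordering --tracts tracts.csv --psmd psmd.csv --subjects subjects.csv \
    --grid -25:10:5 --out ordering.csv
```

## Layout

| Module | Contents |
| --- | --- |
| `mdcascade.synthetic` | cohort generator with planted effects + ground truth |
| `mdcascade.skeleton` | skeleton volumes, custom masking, PSMD |
| `mdcascade.voxelwise` | design matrices, GLM t-maps, TFCE, permutation FWE |
| `mdcascade.tracts` | tract ROIs, Tukey filter, robust fits, EYO ordering |
| `mdcascade.trajectories` | ICV adjustment, AIC polynomial curves, associations |
| `mdcascade.projection` | streamline terminal directions, GM projection zones |
| `mdcascade.wmh` | lesion frequency maps, inside/outside-WMH comparison |
| `mdcascade.pipeline` / `cli` / `io` | orchestration, CLI, readers/writers |

See `docs/methods.md` for the statistical model, parameter defaults and known
limitations.
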