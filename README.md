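# ntpipe

Intrinsic neural timescale (INT) analysis for resting-state fMRI: voxelwise
timescale mapping from the BOLD autocorrelation function, network and ROI
summarization, group inference with permutation cluster correction, and
non-parametric bootstrap mediation linking grey-matter volume, local INT,
default-mode-network (DMN) INT and cognition — together with a synthetic
AR(1) cohort generator that plants all of that structure as ground truth.

It is written for researchers who study temporal integration hierarchies in
the brain — in particular the finding that the DMN's intrinsic timescale is
shortened in Alzheimer's disease, that the shortening concentrates in
inferior parietal regions (angular and supramarginal gyri), and that the
causal-style chain *smaller local GMV → shorter local INT → shorter DMN
INT → lower MMSE* survives a mediation analysis while its reversal does
not.  The package reproduces that analysis machinery end to end on
synthetic cohorts with known generative timescales, so every stage can be
validated against a planted truth.

## The statistic

For each voxel, with `ρ̂(k)` the biased sample autocorrelation of the
preprocessed series at lag *k* (one bin per TR):

```
INT = TR · Σ_{k=1}^{m} ρ̂(k),      m = first lag at which ρ̂ ≤ 0, minus 1
```

i.e. TR times the area under the initial positive segment of the ACF.  For
a stationary AR(1) voxel with coefficient φ the population value is
`TR·φ/(1−φ)` seconds.  Maps are smoothed with a mask-renormalized Gaussian
kernel (FWHM 8 mm by default).  Group tests are pooled-variance Student
t's with `η² = t²/(t²+df)`; correlations and mediation indirect effects
`ab = a·b` are tested by subject-resampling bootstrap (percentile CI,
two-tailed sign-crossing p); voxelwise comparisons use a per-voxel
`[intercept, group, age, sex]` model with cluster-level FWE by max-cluster
permutation.  `docs/methods.md` has the full account.

## Worked example

```python
from ntpipe import CohortSpec, simulate_cohort, two_sample_t, run_model_suite
from ntpipe.pipeline import cohort_int_maps, cohort_summary
from ntpipe.roi import parcel_mean

cohort = simulate_cohort(CohortSpec(seed=7))      # 30 CN + 30 AD, planted chain
maps = cohort_int_maps(cohort)                    # preprocess + INT per subject
summary = cohort_summary(cohort, maps)            # subject x network table

cn = summary[summary.group == "CN"]["DMN_int"]
ad = summary[summary.group == "AD"]["DMN_int"]
test = two_sample_t(cn, ad)
print(f"DMN INT  CN mean = {cn.mean():.2f} s   AD mean = {ad.mean():.2f} s")
print(f"two-sample t({test.df}) = {test.t:.2f}, p = {test.p:.2e}, eta2 = {test.eta2:.2f}")

summary["AG_int"] = [parcel_mean(maps[s], cohort.atlas, "AG") for s in summary["subject"]]
suite = run_model_suite(summary, roi_names=["AG"], network_names=(), n_boot=10_000, seed=7)
fwd = suite["AG:gmv->int->dmn"].result            # planted chain
rev = suite["AG:int->gmv->dmn"].result            # reversed sensitivity model
print(f"GMV->INT->DMN : ab = {fwd.ab:.3f}  CI [{fwd.ci_low:.3f}, {fwd.ci_high:.3f}]  p = {fwd.p:.4f}")
print(f"INT->GMV->DMN : ab = {rev.ab:.3f}  CI [{rev.ci_low:.3f}, {rev.ci_high:.3f}]  p = {rev.p:.4f}")
```

prints

```
DMN INT  CN mean = 3.16 s   AD mean = 2.65 s
two-sample t(58) = 8.90, p = 1.95e-12, eta2 = 0.58
GMV->INT->DMN : ab = 0.075  CI [0.035, 0.119]  p = 0.0002
INT->GMV->DMN : ab = 0.036  CI [-0.217, 0.280]  p = 0.7624
```

The cognitively normal group shows the longer DMN timescale (the planted
deficit is recovered with a large effect size), the anatomical mediation
chain GMV → AG INT → DMN INT is significant with a confidence interval
excluding zero, and the reversed model — AG INT driving GMV — is null,
exactly the asymmetry the generator plants.  Note the estimated timescales
are compressed relative to the generative ones (band-pass filtering
reshapes the ACF); ordering and mediation structure, not absolute values,
are the estimands at this scale.

## Command line

```
ntpipe simulate   --config cohort.json --out DIR --seed 11
ntpipe preprocess --bold bold.nii.gz --confounds conf.tsv --discard 5 --band 0.01 0.1 --out clean.nii.gz
ntpipe intmap     --bold clean.nii.gz --mask atlas.nii.gz --fwhm 8 --out int.nii.gz
ntpipe mediate    --table summary.tsv --rois AG,SMG --n-boot 10000 --seed 11
ntpipe run        --config pipeline.json --out DIR
```

`ntpipe run` executes every stage from a single JSON config (one top-level
seed reproduces everything byte for byte) and writes all intermediates:
per-subject NIfTIs, QC/summary/cluster/mediation/cognition tables, a
`report.json`, and a manifest with the config hash and per-stage status.

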