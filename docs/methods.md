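# Methods

This note documents the models, algorithms and numerical choices behind
`lffcouple`, in the order data flow through the pipeline, followed by
the synthetic cohort's generative model and the package's known
limitations.

## Preprocessing

Each subject's 4D run is processed in a fixed order: nuisance
regression → linear detrend → band-pass.

**Nuisance regression.** Per voxel, ordinary least squares on an
intercept, the six realignment parameters, and aCompCor components: the
leading temporal principal components (default 5) of the demeaned
WM ∪ CSF voxel pool, scaled to unit variance. The default is a single
PCA over the combined pool; a per-tissue variant (separate PCAs for WM
and CSF) is available via `separate_tissues=True` — the combined pool
was chosen because the physiological signal model is shared between the
compartments, and both variants are exposed because the field uses
both. Rank-deficient designs lose their collinear columns with a logged
warning rather than aborting.

**Detrend.** Removal of the per-voxel best-fit line (mean + slope).
The order is linear because the synthetic drift is linear and no
higher-order drift source exists in the model.

**Band-pass.** An ideal frequency-domain filter: FFT each voxel, zero
every bin outside the band (and DC), inverse FFT. Band membership of
discrete bins is half-open `[f_low, f_high)` except the top band, which
closes at `f_high`; with slow-5 = [0.01, 0.027) Hz open-topped and
slow-4 = [0.027, 0.073] Hz closed, the two sub-bands partition the full
band's bin set exactly, so `slow5 + slow4 = full` voxel-wise — an
invariant the test suite asserts. The ideal filter (rather than an IIR
design) makes the filter's bin set and the ALFF bin set literally
identical.

All three steps are linear projections; idempotence and residual
orthogonality are tested properties.

## Voxel-wise measures

**Global FC.** `FC_i = (1/(V−1)) Σ_{j≠i} atanh(clip(r_ij, ±(1−ε)))`
with `ε = 1e-7`, `r_ij` the Pearson correlation of band-filtered
series, and V the brain-mask voxel count (the mask includes all
tissues; a GM-only denominator is available by passing a GM mask). The
V×V computation is chunked; an O(V²) brute-force double loop pins its
correctness to 1e-10. The Fisher clip only matters for degenerate
synthetic inputs (identical series); real-data correlations never reach
±1.

**ALFF.** Mean over the band's bins of the square-rooted one-sided
periodogram `P(b) = |X_b|²/T` (plain squared-modulus DFT, no taper).
It is computed once from the detrended wide-band series and binned per
band, which under the ideal filter is numerically identical to
computing it from each filtered series. A definitional DFT
implementation serves as the 1e-10 oracle.

**Map smoothing.** Before group modeling, each subject's FC and ALFF
map is smoothed with a masked Gaussian kernel (default FWHM 3 voxels;
the smoothed field is renormalized by the smoothed mask indicator so
out-of-mask NaN neither leaks in nor biases edges). This is the
pipeline's counterpart of the acquisition-space smoothing that
volume-based fMRI pipelines apply before statistics (8 mm FWHM on
2–3 mm voxels ≈ 3 voxel FWHM): band-limited series at 216 volumes carry
only ~56 effective spectral degrees of freedom, so single-voxel FC
estimates are noisy, and pooling neighbors is what makes the
across-subject signal per voxel usable. Raw (unsmoothed) maps are kept
alongside and used for the ROI/GM summaries.

**Spatial z-scoring.** Maps entering the GLM are standardized to
in-mask mean 0, SD 1 (population SD). This matches the ALFF z-scoring
convention and puts FC on the same footing. Two consequences are worth
stating. First, a z-scored map is a *relative* measure: a map-wide
multiplicative subject factor cancels exactly, so only regionally
heterogeneous subject effects survive — which is why the generator
plants its factors regionally (below). Second, a regional subject
effect shifts the in-mask mean/SD and therefore reappears with opposite
sign everywhere else in the z-map; significant coupling clusters can
accordingly extend beyond the voxels where the effect physically lives.
Raw Fisher-z FC and raw ALFF variants are exposed for analyses (group
means, ROI summaries) where absolute levels are the quantity of
interest.

## Second-level model

Default (`pooled_interaction`): one GLM over all subjects per voxel
with group intercepts, group-specific ALFF slopes, and the four
standardized covariates — 10 columns for three groups of 10, residual
df = 20, voxel threshold |t| > 3.15 at p < 0.005. The alternative
(`per_group`) fits each group separately (6 columns, df = 4, threshold
|t| > 4.6), with Welch/Satterthwaite between-group contrasts. The
pooled variant is the default because per-group fits at n = 10 with
four covariates leave too few residual df for voxel-level thresholds to
be usable; both are first-class because the "right" reconstruction of a
second-level coupling model from group sizes alone is genuinely
underdetermined. Degenerate voxels (numerically exact fits, e.g. a
constant response) return slope 0, t 0 by convention; voxels where any
subject lacks finite data are dropped from the analysis mask with a
logged count.

Between-group contrasts use the fitted slope covariance
(`var1 + var2 − 2·cov12`) at the pooled df and are evaluated inside a
restriction mask — by convention the control group's corrected-significant
coupling mask, mirroring the practice of testing group differences only
where the effect exists in controls. Contrast tests are two-tailed by
default at a configurable voxel p.

ROI summaries average a map over an ROI per subject and compare groups
with one-tailed two-sample t-tests in the control > patient direction,
the directional hypothesis of a degeneration study.

## Cluster-extent correction

`simulate_cluster_threshold` re-implements the Monte Carlo logic of
AFNI's AlphaSim: fill the analysis mask with iid standard normal noise,
smooth to the target smoothness, re-standardize inside the mask (so the
voxel-level quantile stays nominal after smoothing), threshold
two-tailed at the voxel p's z-quantile, and record the maximum
connected-cluster size; `k_min` is the smallest extent whose exceedance
probability is ≤ α. Defaults: faces (6-neighbor) connectivity,
configurable to 18 or 26; 10000 iterations in the standalone tool, 500–
1000 inside the pipeline where the threshold is recomputed per run.
Familywise calibration (applying `k_min` to fresh null fields) and
monotonicity of `k_min` in smoothness are asserted by the test suite.
A fixed published cluster extent is deliberately **not** a target: the
number depends on the exact mask and smoothness, neither of which is
reproducible here; the calibration properties are the meaningful check.

The null field's smoothness is estimated from the across-subject
residual maps (subject z-maps minus their group mean) with an
AFNI-style first-difference variance-ratio estimator: per axis,
`rho = 1 − var(diff)/(2·var)` and
`FWHM = sqrt(2 ln 2)·d / sqrt(−ln rho)` (the kernel FWHM whose Gaussian
autocorrelation has lag-1 correlation `rho`). A flag-selectable
alternative is to fix the smoothness at the applied map-smoothing
kernel; estimation from residuals is the default because the planted
signal itself adds smoothness beyond the kernel.

## The synthetic cohort generator

The generator emulates a three-group dementia study: 10 subjects per
group, 216 usable volumes at TR 2.08 s, a 20³ voxel grid holding a
cuboid brain (outer CSF sheet, 4-voxel GM shell, WM core), four 5×5×4
GM network regions, per-group covariates drawn from the reference
cohort's printed means/SDs (truncated normals at ±4 SD; gender
Bernoulli at the printed proportions, coded M=1/F=0 downstream).

Latent subject factors per subject *i*:

- synchronization `W_i ~ N(sync_mean[g], 0.18)`, clipped to [0.05, 0.95];
- amplitude `A_i = amp_mean[g] + 0.3·(ρ_g·z_W + sqrt(1−ρ_g²)·z⊥)`,
  floored at 0.1, so that `corr(A, W) = ρ_g` exactly in expectation
  (Cholesky construction).

Defaults: `ρ = 0.8 / 0 / 0` and `sync_mean = 0.6 / 0.45 / 0.4` for
controls / MCI-like / AD-like, with identical `amp_mean = 1` — patients
lose synchronization, not amplitude.

A GM voxel of a **coupled** network k (2 of the 4 networks by default)
carries

```
x_v(t) = A_i · a_v · [ sqrt(1−g0²)·( W_i·s_k(t) + sqrt(1−W_i²)·n_v(t) ) + g0·gs(t) ]
```

with `s_k` the network's latent signal, `n_v` voxel-private noise, `gs`
a whole-GM coherence signal with fixed weight `g0` (per group 0.30 /
0.29 / 0.285 — the small per-group reduction calibrates the GM-average
FC group differences to the reference study's reported effect sizes,
t ≈ 2.8 / 2.2 at n = 10), and `a_v ~ U(0.8, 1.2)` a fixed anatomical
gain. The bracketed composite has unit variance whatever `W_i`, which
is what makes amplitude and synchronization separable by construction:
doubling `A_i` doubles in-band ALFF exactly, while `W_i` moves only the
correlation structure. The **uncoupled** networks use the group means
instead of `(W_i, A_i)` — constant within group, so they anchor the
spatial z-transform (a subject factor applied to *all* GM would be
cancelled by z-scoring) while still expressing group-level FC
reduction. Background GM carries only private noise plus the global
term; WM/CSF voxels carry three shared low-frequency confound signals
with fixed random loadings (scale `confound_sd = 1`); every brain voxel
receives broadband white noise (SD 0.2) and a random linear drift
(SD 0.5 over the run); motion parameters are smoothed random walks.

All latent signals are band-limited (0.01–0.073 Hz) unit-variance
series, and — this is the generator's definition of the model's
independence assumptions — exactly orthogonalized in-sample: the
network signals and the global signal against each other and against
the subject's motion and confound columns, and every voxel noise
against all of the above. With ~56 spectral dof, chance sample
correlations among nominally independent band-limited processes are of
order 0.13; left in place they dominate the across-subject variance of
network-mean FC and make the nuisance regression remove a randomly
varying share of the neuronal signal. Orthogonalization enforces the
declared independence exactly rather than only in expectation.

Free parameters the emulated study does not pin down (`sync_sd`,
`amp_sd`, `noise_sd`, `confound_sd`, `g0`, network size) were fixed
once at design time from subject-level power/realism analyses and are
not tuned per experiment.

**What the generator does not emulate:** hemodynamic response shape,
spatial autocorrelation of real fMRI noise (voxel noises are
independent; map smoothness comes only from the explicit smoothing
step), scanner artifacts, registration/segmentation error, and any
anatomical realism beyond tissue compartments. Tests passing on this
generator therefore certify the *statistical machinery* — oracle
correctness, error calibration, parameter recovery under the planted
model — not performance on real acquisitions.

## Statistical power at the study's size

With 10 subjects per group, the sampling spread of a latent correlation
of 0.8 is large (Fisher SE ≈ 0.38 on the z scale), and the pooled
model's control-slope t statistic has expectation near the voxel
threshold 3.15 itself: a subject-level Monte Carlo with *perfect*
measurement puts the per-cohort probability of exceeding it near 0.5,
and the full pipeline operates close to that ceiling. Corrected
detection of the control group's coupling in any single cohort is
therefore genuinely borderline — as it was for the study design being
emulated, which reported the effect from one cohort. The replication
rates over independent cohorts (control detection, patient absence, and
the FC-driven ROI uncoupling) are computed by
`lffcouple.validation.headline_replication` and reported by
`scripts/acceptance.py`; the ROI-level pattern (FC reduced, ALFF
preserved) replicates at a much higher rate than whole-map corrected
detection, because it does not pay the multiple-comparison cost.

## Numerical conventions

- Fisher z clip `ε = 1e-7`; self-pairs excluded from global FC.
- Band-edge bins: half-open intervals, top band closed (see above);
  bin/edge comparisons use a 1e-9 relative tolerance.
- Spatial z-scoring and covariate standardization use the population
  (ddof = 0) SD; group summaries and SEs use the sample (ddof = 1) SD.
- Exact-fit voxels (residual sum of squares ≤ 1e-12 of the response
  energy) report slope 0, t 0.
- Statistic maps store NaN outside the mask; 4D data store zeros
  outside the brain. Maps are written as 32-bit float NIfTI-1.
- TR is carried in the NIfTI header (pixdim[4]); an explicit TR
  argument overrides the header with a logged warning.
- The smoothness estimator floors the lag-1 correlation at 1e-6, so
  white noise yields a small sub-voxel FWHM rather than NaN.
- Determinism: every stochastic routine takes a seed or Generator; the
  same cohort spec reproduces bit-identical data, and a pipeline run's
  manifest records every seed and threshold needed to reproduce it.

## Known limitations

- Power, not correctness, limits single-cohort detection at n = 10 (see
  above); analyses of the generator at larger n recover the planted
  coupling with high per-voxel fidelity.
- The per-group model's df = 4 makes its voxel thresholds severe; it is
  provided for completeness and transparency, not recommended at this n.
- Cluster inference assumes stationary Gaussian null smoothness inside
  the mask; the estimator returns one FWHM per axis but the null
  simulation uses their isotropic mean.
- The CLI covers the pipeline's common paths; programmatic use is the
  primary interface.
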