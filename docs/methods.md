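# Methods

## Scope and design

`threshcheck` compares five multiple-comparison correction conditions for
one-sample (group-level) task-fMRI inference by their *consistency* under
injected spatially-autocorrelated noise.  All five run on a shared core —
one-sample t maps, 3D connected components, sign-flip permutation nulls —
so that differences between conditions reflect the correction logic, not
implementation accidents.  Everything is deterministic given the seeds in
the run manifest.

## Group model and permutation inference

Per voxel, t = x̄/(s/√n) with the (n−1)-denominator s; df = n − 1.  A
pseudo-t with mask-normalized Gaussian variance smoothing is available
(`var_smooth_fwhm_mm`); the default is 0 mm — the permutation tool's own
default — so the two SnPM-style conditions run on the plain t map.  We
found variance smoothing combined with a fixed Student-t forming threshold
makes the permutation cluster condition nearly insensitive to injected
noise (its statistic rescales coherently while the cutoff stays put),
which distorts a consistency comparison; leaving it off also keeps all
five conditions on the same statistic.  Degenerate voxels (s = 0, mean ≠ 0)
receive a ±10⁶ sentinel.

Sign-flip nulls enumerate all 2ⁿ flips when 2ⁿ ≤ `n_permutations`
(n ≤ 12 at the 5000-permutation default), otherwise identity plus
`n_permutations` − 1 random flips.  The identity flip is always included,
so corrected p values #{null ≥ observed}/P are never zero and FWE control
is exact under the permutation distribution.  Survival means corrected
p ≤ α; the ⌈(1−α)P⌉-th smallest null maximum is reported as the critical
value.  Inference is one-sided (positive tail) throughout, matching
directional task contrasts; connectivity is 18 (faces + edges) for every
cluster operation so the conditions stay comparable — both are
configurable.

## TFCE

The discrete transform sums e(h,v)^0.5 · h² · Δh over `tfce_n_steps` equal
height slabs up to the map maximum (per-map Δh).  At 100 steps the
single-voxel and two-voxel closed forms (h³/3 and √2·h³/3) are reproduced
within 2%.  TFCE runs on the t map (the convention of the permutation tool
that popularized it) with FWE from the max-TFCE permutation null.

## Monte-Carlo cluster-size thresholds

The simulation-based conditions estimate the noise model from the
dataset's own residuals (subject image minus group mean, correlations
pooled over subjects — the analogue of averaging smoothness over residual
sub-bricks): the Gaussian variant constrains the ACF fit to a = 1 and
converts the fitted width to an equivalent smoothing-kernel FWHM
(FWHM = b·√(4 ln 2), since smoothing white noise with kernel σ gives a
Gaussian ACF of width √2·σ); the ACF variant uses the full mixed fit.
Null fields are simulated on the mask's bounding box and masked.  White
noise for the Gaussian variant is smoothed with periodic (wrap)
boundaries: reflective smoothing inflates edge variance, and a global
variance normalization would then deflate the mask interior and bias k*
low.  k* is the smallest extent whose Monte-Carlo exceedance probability
is ≤ α.

## Spatial autocorrelation model and noise generation

ρ(r) = a·exp(−r²/2b²) + (1−a)·exp(−r/c), r in mm.  Estimation: the
residual field is standardized in-mask, the empirical correlation is
computed at every integer-lag offset within `r_max_mm` (12 mm default),
binned by mm distance, and fitted by bounded weighted least squares
(a ∈ [0,1], b, c ∈ (0.1, 50) mm) with a 3×3×3 multi-start grid; SSE ties
break toward the smallest a because the mixture has identifiability ridges
when either component vanishes.

Correlated noise is generated cube-by-cube: the grid's bounding box is
tiled with non-overlapping cubes (default 12³ voxels; edge cubes truncated
with their own covariance), each cube's correlation matrix is
Cholesky-factorized (smallest doubling jitter if needed) and applied to
standard normal draws.  Cubes are mutually independent — the correlation
across a cube boundary is exactly zero.  This tiling artifact is
deliberate: it reproduces how memory-bounded noise generation is done in
practice, and the covariance of a whole brain (or of a 30³ cube, tens of
GB) is out of desk-scale reach; the cube size is capped at 4096 voxels by
default and configurable.  Consequences worth knowing: the *empirical* ACF
of a cube-tiled field is attenuated relative to the model (a fraction
lag/cube-edge of pairs straddle boundaries), so round-trip parameter
recovery tests use an independent spectral (FFT) generator for clean
oracle fields, and the test of the cube generator itself checks
within-cube correlations.

Injection scales each subject's unit-variance field by
`magnitude_fraction` × mean |contrast| over that subject's in-mask voxels
("mean contrast strength" read as the sign-robust absolute mean; the
noise's standard deviation, not amplitude, is set to it) and draws an
independent field per subject from child seeds.  All-zero images are
skipped with a warning.

## Synthetic datasets

`simulate_dataset` builds subject images as smoothed activation template +
smoothed, variance-renormalized Gaussian noise (separable kernel,
reflective boundaries, 4σ truncation; σ = FWHM/√(8 ln 2)).  The template is
smoothed with the same kernel as the noise because acquired images pass
through spatial smoothing as a whole — hard-edged spheres would give every
cluster voxel the same t and no marginal shoulders.  Renormalizing the
smoothed noise to the nominal sd keeps effect sizes interpretable:
expected core t ≈ amplitude/(sd/√n).

Two presets emulate group studies of higher-order cognition at desk scale:
`moral` (16 subjects, 40×48×34 at 2 mm) and `wm` (15 subjects, 30×32×26 at
3 mm), both smoothed at 8 mm FWHM inside an ellipsoidal brain-like mask
(full-size grids behind `full_size=True`).  Each preset's activation set
was calibrated once so that the *published profile* of these methods
emerges from their mechanics — a tiny focal cluster; two mid foci whose
cores (expected t ≈ 4.8) hover near the voxel-wise FWE critical value and
whose suprathreshold extents hover near typical cluster-size thresholds;
and one broad moderate field (expected t ≈ 4.0, at the p < 0.001 forming
threshold) spanning ~1000+ voxels.  On such data voxel-wise FWE keeps only
noise-located peaks (few, unstable), extent thresholding keeps the field's
percolating suprathreshold patches, and TFCE accumulates support across
the whole field (most, stable) — the survivor ordering
voxel ≪ cluster < TFCE with TFCE ≈ 2× the cluster methods.  What passing
tests on these presets shows is that the evaluation framework reproduces
the characteristic behavior of the five corrections on data with this
structure; it does not certify any method's validity on real data, where
effect structure, physiological noise and temporal autocorrelation are
unknown.

## Evaluation design

For each preset: threshold the original dataset with all five conditions
(reference maps); for each of 10 repetitions inject fresh noise (ACF fitted
from the original residuals, reused across repetitions) and re-threshold;
score false-alarm = |noisy∧¬orig|/|noisy| and hit = |noisy∧orig|/|orig|
against each method's own reference.  Undefined rates (empty denominators)
are recorded as missing and excluded from the ANOVA with a warning, rather
than imputed.  Two choices isolate the injected noise as the manipulated
factor: per-method permutation seeds are identical between the original
and every noisy run, and the Monte-Carlo k* calibrations are computed once
on the original data and reused (`reuse_mc_thresholds`, default on; set it
off to re-calibrate per repetition).

Methods are compared per metric with a one-way fixed-effects ANOVA
(F = MS_between/MS_within, df = (4, 45) in the 5×10 design; F defined as 0
when both mean squares vanish) and Scheffé's criterion for all pairwise
contrasts — (Δmean)²/(MS_w(1/nᵢ+1/nⱼ)) vs (k−1)·F_crit(k−1, df_w, α) —
rendered as compact letters: methods sorted by mean, every maximal run of
mutually non-significant neighbors shares a letter.  Both are implemented
from their closed forms so the letters are reproducible and testable
against independent oracles.

## Problem sizes and tolerances

Suite and acceptance runs use reduced sizes chosen as this package's own
desk-scale defaults: 150 permutations / 800 Monte-Carlo iterations / 25
TFCE steps for the consistency studies (3 master seeds × 10 repetitions ×
both presets), 500 permutations / 2000 iterations / 40 seeded runs for the
null calibration of family-wise error, 100 TFCE steps wherever closed
forms are checked.  The configuration defaults remain the field's
conventional 5000 permutations / 10⁴ iterations / 100 steps.  Fit
tolerances (25% median recovery error; 5% noise-scaling error; 2% TFCE
discretization) reflect what the estimation problems support at these
sizes.

## Known limitations

- No temporal autocorrelation, physiological or motion artifacts — only
  random spatially-correlated noise.
- Cube-independent noise (see above); larger cubes reduce but never remove
  the boundary artifact.
- One-sample designs only; no covariates, two-sample contrasts or F tests.
- FDR-style inference and parametric random-field corrections are out of
  scope.
- The presets are statistical emulations, not anatomical phantoms:
  spherical clusters, ellipsoidal mask, stationary noise.
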