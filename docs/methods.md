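# Methods

## Study design being emulated

The pipeline targets a repeated-measures postsurgical pain design: each
subject is scanned in five sessions — two presurgical baselines, one
postsurgical session after each of two extractions (left and right side,
order pseudorandomized per subject and balanced across the group), and a
pain-free follow-up — with six ASL perfusion scans per session and a VAS
pain/alertness rating (0–100) before each scan. Three comparisons are
supported: presurgery vs postsurgery (all sides pooled), left vs right
postsurgery (laterality), and follow-up vs postsurgery per side.

## Synthetic cohort generator

Per scan the volume is

    v = baseline_cbf · g_s + 1{postsurgery} · effect_scale · T + ε

with `g_s ~ lognormal(0, subject_global_sd)` fixed per subject (multiplicative
global perfusion variability — the reason for median scaling),
`ε ~ N(0, scan_noise_sd²)` i.i.d. per voxel and scan, and `T` the pattern
template: a sum of isotropic Gaussian bumps with peak value = amplitude,
placed at grid fractions approximating bilateral thalamus, anterior/posterior
insula and anterior cingulate (positive amplitudes, perfusion increase after
surgery) against occipital and posterior parietal cortex (negative
amplitudes). Noise is spatially white at generation; spatial correlation
enters through the pipeline's own smoothing step, the simplest model
consistent with the preprocessing chain. The brain mask is a centred
ellipsoid whose semi-axes are 1.05× the half-extents, covering ≈60% of the
grid — arbitrary but deterministic.

VAS pain is Gaussian around `presurgery_mean` (default 15) plus a
side-specific delta (defaults 52.41 left, 50.779 right — the emulated group
mean differences) in the postsurgical state, sd 7, clipped to [0, 100]; the
presurgery mean and sd were chosen so that clipping bias is negligible
(≪ 0.1 on the 0–100 scale) and the realized post-minus-pre differences match
the configured deltas. VAS alertness has no condition effect.

Defaults: 20 subjects, 6 scans/session, 24×32×24 grid at 3 mm isotropic (a
desk-scale stand-in for a full acquisition matrix; everything is
configurable), `baseline_cbf` 60 (ml/100g/min-like units),
`subject_global_sd` 0.15, `scan_noise_sd` 10.

### Effect-size calibration

No quantitative postsurgical rCBF effect size is available to copy, so the
generator is calibrated through a defined contrast-to-noise ratio rather
than tuned per experiment: `pattern_cnr` = (peak |smoothed template| ×
effect_scale, in median-1000 units for a nominal subject) / (per-voxel sd of
smoothed scan noise after averaging one session's scans, same units). The
noise attenuation factor of smoothing is computed from the discrete kernel
actually applied. The default `effect_scale` = 1.65 yields a session-average
CNR of ≈1.5 under the default noise settings; `effect_scale_for_cnr` inverts
the (linear) relation for any target.

## Preprocessing

Fixed order: Gaussian smoothing → global median scaling (→ optional
averaging → featurization). Smoothing uses per-axis sigma
`(fwhm_mm / voxel_size) / (2√(2 ln 2))` with reflective boundaries, which
preserve constant images. Median scaling multiplies each volume by
`target / median`, with the median taken over in-mask voxels by default
(background zeros would dominate a whole-volume median; a switch selects the
whole-volume variant). Scaling is per scan, before any averaging. Feature
rows follow the input record order; columns are the C-order linear scan of
the mask, making the voxel↔column mapping deterministic and invertible.

## GP classifier

Linear covariance `k(x,x') = s⟨x,x'⟩/d + b` on features centred by the
training-fold mean; the 1/d normalisation makes hyperparameter scales
independent of the voxel count, and centring lets the bias term `b` absorb
class offsets (a linear-kernel GP is translation-sensitive). All computations
are dual: only the n×n kernel is formed (n ≤ a few dozen here, d ≈ 10⁴).

EP details: sites are swept in fixed ascending order; a site update that
would drive a precision negative is damped by 0.5 and clipped at 0; the
posterior is refreshed by rank-1 updates within a sweep and recomputed from
a Cholesky factorisation of `B = I + S^{1/2} K S^{1/2}` at the end of each
sweep. Convergence: max absolute site-parameter change < 1e-4, cap 60 sweeps
(warning on non-convergence). Jitter `1e-8 × mean(diag K)` is added for PSD
safety. The EP log marginal likelihood uses the numerically robust
cavity-parameter form, valid at zero site precisions. The implementation is
validated against dense-quadrature oracles (1-D and tensor-grid 2-D) for
posterior moments, evidence and predictive probabilities, to 1e-3.

Hyperparameters are optimised by bounded L-BFGS-B (numerical gradients) on
the negative EP evidence from the fixed start (0, 0), box [−10, 10]²; the
optimiser's result is accepted only if it does not degrade the evidence at
the start, making `fit` deterministic and monotone. Class coding:
postsurgery = +1 everywhere; report layers convert to "probability of the
comparison state" as 1 − p where that orientation is conventional.

## Evaluation

LOOCV is at the subject level: a fold holds out *all* samples of one
subject and refits (including the hyperparameter search) on the rest.
Sample granularity is configurable: `condition` (default for the all-scans
analysis — each subject contributes one averaged presurgical and one
averaged postsurgical image, matching a one-prediction-per-subject-per-class
reading of that analysis), `session` (used for the scan-reduction and
follow-up comparisons), or `scan`.

Confusion rates use threshold 0.5 with ties counted as errors for either
class (conservative). AUC is the Mann–Whitney rank statistic (ties ½),
cross-checked against scikit-learn in tests.

The permutation test flips each subject's labels as a block with
probability ½ — free relabeling would break the repeated-measures pairing —
and reruns the full LOOCV per permutation. The p-value uses the plus-one
estimator `(1 + #{null ≥ observed}) / (1 + n_perm)`, whose floor at 1,000
permutations is ≈ 0.001; the naive proportion could return an improper 0.
By default permutation replicates repeat the hyperparameter search; a config
flag freezes hyperparameters at the fixed start inside the test (both the
observed statistic's null comparison and the null replicates then share that
setting via precomputed fold kernels, a fast path verified in tests to
reproduce the generic path exactly). Note that with 12 subjects a random
block-flip pattern coincides with the identity or the global inversion with
probability 2⁻¹¹ per draw; on a perfectly separable cohort such a draw would
tie the observed statistic, so minimum-p checks use enough subjects to make
this negligible.

Holm's step-down adjustment is applied across all tests produced by one
scan-reduction run (all n and both sides form one family); implementation
`adj_(k) = max_{j≤k} min(1, (m−j+1) p_(j))`, cross-checked against
statsmodels.

The scan-reduction experiment keeps acquisition indices 1..n (dropping from
the end, i.e. reverse acquisition order), averages the kept scans into one
image per subject-session for both training and testing, and reruns
LOOCV + permutation per n.

## Discriminative maps

The g-map is the posterior mean in voxel space: dual coefficients
`a = K⁻¹μ` (Cholesky solve on the jittered kernel), `g = X_cᵀa`, scattered
onto the grid; out-of-mask voxels are NaN, never zero, and the map is never
thresholded. The exported sign convention (default: negative favours the
postsurgical class, matching the usual display convention for these maps) is
recorded in a JSON sidecar together with the hyperparameters. By default the
map is computed from a model fit on all data; per-fold maps are available by
calling `compute_gmap` on fold models.

## Problem sizes and determinism

Simulation-based checks run at desk scale: 12-subject cohorts on the
24×32×24 grid for calibration and signal-recovery checks (20 replicate
cohorts for the chance-level average; 100 replicates with 99 permutations
for the type-I-error check; 10 replicates for the scan-count monotonicity
check), chosen so the full suite runs in minutes on one CPU while keeping
Monte-Carlo error well inside the asserted bounds. Every stochastic step
draws from `numpy.random.default_rng` seeded from a single configured seed;
identical configurations reproduce identical reports (manifests hash the
config and all artifacts).

## Known limitations

The generator does not simulate MRI physics, motion, anatomical structure,
or spatially correlated physiological noise; passing tests demonstrate the
correctness and calibration of the *analysis* under its own statistical
assumptions, not performance on real perfusion data. The laterality
comparison is null by construction (left and right postsurgery share one
template), so only its chance-level behaviour is testable. EP results carry
a ~1e-6 dependence on sample order through the sweep schedule; tests assert
order invariance only up to the convergence tolerance.
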