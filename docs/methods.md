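# Methods

## Signal models and voxel-wise fitting

The package models the trace-weighted DWI magnitude signal of a voxel with
the diffusion kurtosis expansion `S(b) = S0·exp(−b·MD + b²·MD²·MK/6)` and,
separately, the mono-exponential model `S(b) = S0·exp(−b·ADC)`. The kurtosis
expansion is a truncated cumulant series: it is a valid, monotonically
decaying signal model only up to roughly `b ≤ 3/(MD·MK)`; for the tumor
parameter ranges used here that bound sits at or above the maximum acquired
b of 2000 s/mm², and the forward model's monotonicity over the acquisition
range is asserted in the test suite.

Fitting is nonlinear least squares **on the signal**, not the log-signal,
with each b value's residual weighted by √NEX (the variance of an NEX-fold
magnitude average scales as 1/NEX; log-domain fitting would additionally
distort the noise). Initial values come from ordinary least squares of
`ln S` on `(b, b²)` mapped to `(MD, MK)` — deterministic, no random
restarts, and exact on noiseless data. Bounds: `MD ∈ [1e-5, 5e-3] mm²/s`,
`MK ∈ [0, 3]`, `S0 > 0`, covering the physiologic tissue range. The
trust-region solver runs with cost tolerance 1e-10 and a 200-evaluation cap;
voxels hitting the cap are flagged (not discarded), and all-zero or
non-finite voxels are marked unfittable and left missing in the maps rather
than aborting a volume. Noiseless forward-model input is recovered to better
than 1e-6 relative error, which the suite checks over 200 random parameter
draws.

The mono-exponential ADC fit is restricted to `b ≤ 1000 s/mm²` by default —
the conventional clinical ADC range; at higher b the kurtosis-induced upward
curvature of the log-signal contaminates the slope. The b-range is a config
option (`fit.adc_b_max`). The source protocol does not state which b values
feed the ADC map; this default is our choice, and its effect (full-range
fitting lowers ADC on kurtotic signal) is demonstrated in a test. Acquired
signals are assumed to be trace-weighted magnitudes already — no
direction-resolved modelling, eddy/motion correction or bias-field handling.

Diffusivities are held in mm²/s internally; report output is rescaled to the
conventional 10⁻³ mm²/s.

## Synthetic cohorts and phantoms

Real patient data for this analysis are private, so the generator fabricates
study-shaped inputs whose defaults **are** the published study conditions:
group sizes 67 NMIBC / 34 MIBC (staging) and 70 high- / 31 low-grade
(grading); per-group (mean, SD) for all ten MD and MK histogram markers plus
mean ADC taken from the published group tables; the 13 b-value scheme
b(NEX) = 0(1), 50(1), 80(1), 100(1), 150(1), 200(1), 300(2), 500(2), 800(2),
1000(4), 1300(4), 1700(6), 2000(6) s/mm²; 4 mm slices on a 64×64×16 grid
with 3.125 mm in-plane spacing; ellipsoidal lesions of at least 10 mm
diameter (the study's inclusion rule; default semi-axes 10×10×8 mm, a
typical 2 cm tumor).

Patient-level markers are drawn as independent truncated normals per marker
(the source reports only marginal mean ± SD; no covariance is available).
Truncation at physical lower bounds (0 for diffusivities, percentile-type MK
markers, inhomogeneity, entropy) uses rejection sampling. An optional shared
latent severity (`latent_rho`) induces cross-marker correlation with signs
taken from the direction of the group-mean differences; this is what makes
marker-combination AUCs meaningful, and the pipeline defaults use
`latent_rho = 0.6` in the example configs. Two oddities of the published
tables are kept verbatim and flagged: the NMIBC MD 75th and 90th percentiles
are printed identically (2.75 ± 0.33), almost certainly a typo; and the MK
5th-percentile and MK-inhomogeneity rows print SDs so large relative to
their means (e.g. 0.38 ± 0.50) that a nonnegative quantity cannot actually
be normal with those moments — for those markers truncation necessarily
shifts the sampled mean upward, and the "<1% truncation bias" property is
asserted only for markers whose printed moments are consistent with
nonnegativity.

Image-level phantoms place a smooth Gaussian-random-field MD/MK ground truth
inside the lesion (Gaussian-filtered white noise standardized within the
mask, correlation length 6 mm, spatial coefficient of variation 0.25 —
chosen to match the published intra-tumor MD inhomogeneity of ≈0.3), or an
optional two-compartment split for bimodality checks. The DWI signal is the
DKI forward model plus **Rician** noise: independent complex Gaussian noise
per excitation, magnitude, then NEX-averaging — matching scanner averaging;
σ = 2 at S0 = 100 (SNR 50 at b = 0, a realistic pelvic EPI level). σ = 0
reproduces the forward model bit-exactly. The zero-signal Rician mean
σ√(π/2) and the √NEX noise reduction are verified by simulation.

VI-RADS reader scores are drawn from per-class distributions over 1–5
calibrated so the score ≥ 3 rule has sensitivity 0.85 and specificity 0.88 —
the published reader operating point; the second reader copies the first
with probability 0.78 and otherwise moves one point, giving an ICC near the
published 0.87. The generator reproduces the threshold operating point by
construction but not the published VI-RADS AUC of 0.89 (a 5-point score's
AUC depends on the full score distributions, which are not published); the
simulated VI-RADS AUC is higher.

What passing closed-loop tests show, and what they do not: the pipeline
recovers the generator's patient- and group-level statistics through
fit → texture → inference, so the implementation is self-consistent and
correctly propagates the published group structure. They cannot validate
claims about real bladder tumors — real lesions are not ellipsoids with
Gaussian random-field parameter maps, real marker joint distributions are
unknown, and partial-volume, motion and susceptibility effects are not
simulated.

## Histogram features

Ten first-order statistics of the in-VOI voxel values per map: mean;
5th/25th/50th/75th/90th percentiles (linear interpolation at 0-based rank
`(n−1)·q/100`); inhomogeneity; skewness; kurtosis; entropy. Conventions the
source leaves unstated are fixed as: inhomogeneity = coefficient of
variation SD/mean (the common "inhomogeneity" in histogram-analysis
software; `(p75−p25)/p50` available via config); skewness and kurtosis are
population (n-denominator) standardized moments with kurtosis reported as
*excess* kurtosis — the published tables contain negative MD-kurtosis
values, which only excess kurtosis can produce; entropy is Shannon entropy
in bits over a 64-bin equal-width histogram spanning the VOI's own
[min, max] (published entropies of ≈3.7–3.9 bits are consistent with this
scale, but whether the original software used a fixed or data-driven bin
range is unknown — bin count is a config option, not ground truth).
Degenerate inputs are contracts, not crashes: constant samples give entropy
0 and NaN shape moments; zero mean with nonzero SD gives NaN inhomogeneity.

## Inference layer

* **Mann–Whitney U** (two-sided), midranks for ties. For combined n ≤ 16 the
  p-value is an exact permutation enumeration over all group assignments
  (valid under ties); otherwise the tie-corrected normal approximation.
* **ROC**: empirical AUC with ties counting ½, which equals U/(n₁n₂)
  exactly — asserted as an identity test. Marker orientation is
  auto-detected (AUC ≥ 0.5) by default, matching the biology: lower MD/ADC
  and higher MK indicate invasive/high-grade tumors; an override is
  available. The 95% CI uses DeLong's paired variance estimate, transformed
  to the logit scale so the interval respects [0, 1]; measured coverage at
  the study's 67/34 design is ≈96% versus ≈94% for the plain Wald interval.
* **Youden cutoff**: exhaustive scan over midpoints between adjacent
  distinct scores, ties broken toward higher specificity.
* **DeLong comparison** of correlated AUCs from the structural components;
  degenerate zero-variance comparisons (marker vs itself or a monotone
  transform) return p = 1.
* **ICC(2,1)**: two-way random effects, absolute agreement, single
  measures, from the ANOVA mean squares; this variant is an explicit choice
  (the source does not specify one) and is cross-checked against an
  independent implementation in the tests. Bands: >0.80 excellent,
  0.61–0.80 good, 0.41–0.60 moderate, 0.21–0.40 general, ≤0.20 poor.
* **Combinations**: unpenalized in-sample logistic regression on
  standardized markers; the combined score is the linear predictor. This
  mirrors the apparent original analysis (no train/test split) and
  therefore reports optimistic in-sample AUCs. Perfect separation is
  flagged and the standardized coefficient vector rescaled to a finite cap,
  preserving the score ordering. VI-RADS enters combinations as a numeric
  1–5 covariate.
* **VI-RADS threshold**: score ≥ 3 predicts muscle invasion; AUC treats the
  ordinal score as the rating.
* No multiple-testing correction is applied (α = 0.05 throughout),
  mirroring the original analysis; markers enter the ROC tables when their
  group comparison is significant.

`binormal_auc` provides the closed-form oracle
`Φ(|μ₊−μ₋|/√(σ₊²+σ₋²))` used to anchor simulation checks, e.g. 0.8404 for
ADC staging and 0.7734 for MKmean grading at the published group moments.

## Pipeline and problem sizes

Stages `simulate → fit → features → analyze` communicate only through files
(NIfTI volumes/maps, TSV scheme, CSV tables, JSON manifests); every output
carries the config hash and seed, seeds are spawned per patient from a root
`SeedSequence`, and a repeated run is bit-identical apart from timestamps.
The fit stage skips cleanly when its outputs already match the config hash,
and per-patient failures are collected into the run summary rather than
aborting.

Default problem sizes were chosen to make full studies cheap to rerun: the
64×64×16 grid with a 10×10×8 mm lesion yields ≈90 VOI voxels per patient, so
a 101-patient closed-loop study (two model fits per voxel) completes in
about a minute on one core; replicated-cohort AUC experiments use 500
replicates, at which the replicate-mean AUC has a Monte-Carlo SE below
0.002.

## Known limitations

* Independent-marker sampling understates (and `latent_rho` only crudely
  models) the true joint distribution of correlated histogram markers.
* Phantom ADC is the b ≤ 1000 mono-exponential summary of a DKI-generated
  signal, not an independent tissue property; cohort-level ADC statistics
  use the sampled patient summaries instead.
* The reader-score model matches the published threshold operating point
  and ICC, not the full ordinal distribution or its AUC.
* In-sample combination AUCs are optimistic by construction; a
  cross-validated variant is not provided.
* No IVIM or tensor modelling, no second-order (GLCM-type) texture, no
  IBSI-compliance claims.
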