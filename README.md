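# dkitex

Whole-tumor diffusion kurtosis (DKI) texture analysis for staging and grading
bladder cancer.

Multi-b-value diffusion-weighted MRI of bladder tumors is summarised by two
voxel-wise signal models. The diffusion kurtosis model

```
S(b) = S0 · exp(−b·MD + b²·MD²·MK/6)
```

yields the kurtosis-corrected diffusivity MD (mm²/s) and the dimensionless
mean kurtosis MK, which measures how far water displacement departs from a
Gaussian profile (higher MK ↔ denser, more heterogeneous tissue). The
mono-exponential model `S(b) = S0 · exp(−b·ADC)` yields the conventional
apparent diffusion coefficient. Maps are fitted voxel-by-voxel inside a
whole-lesion VOI by NEX-weighted nonlinear least squares on the signal, the
VOI histogram of each map is reduced to ten first-order statistics (mean;
5th/25th/50th/75th/90th percentiles; inhomogeneity; skewness; kurtosis;
entropy), and the resulting per-patient markers feed an inference layer:
Mann–Whitney group comparisons, ROC analysis with DeLong 95% CIs and
Youden-index cutoffs, DeLong comparison of correlated AUCs, two-reader
ICC(2,1) agreement, ordinal VI-RADS threshold classification (score ≥ 3 →
muscle-invasive), and in-sample logistic marker combinations.

The package is aimed at quantitative-imaging researchers who want a tested,
reproducible reference implementation of this pipeline. Because the clinical
cohort it models is not public, a synthetic generator fabricates
study-shaped data at both levels: per-patient marker summaries drawn from
the published per-group means/SDs at the published group sizes (67
non-muscle-invasive vs 34 muscle-invasive for staging; 70 high- vs 31
low-grade for grading), and image-level ellipsoidal lesion phantoms with
smooth MD/MK ground-truth fields, the 13 b-value acquisition scheme
(b = 0…2000 s/mm², per-b NEX), and Rician magnitude noise.

## Worked example

Fit the DKI model to a noiseless forward signal at the muscle-invasive
group-mean parameters, then compare the closed-form and simulated AUC of ADC
for discriminating muscle-invasive tumors:

```python
import dkitex as dk
from dkitex.stats import binormal_auc, mean_binormal_empirical_auc

scheme = dk.BValueScheme.default()            # 13 b values, 0..2000 s/mm²
signal = dk.dki_forward(dk.DKIParams(s0=100, md=1.42e-3, mk=0.81), scheme.b)
params, diag = dk.fit_dki_voxel(signal, scheme)
print(params.md * 1e3, params.mk)             # 1.42 0.81  (exact recovery)

# ADC staging marker: NMIBC 1.65±0.42, MIBC 1.13±0.31 (×10⁻³ mm²/s)
print(binormal_auc(1.13, 0.31, 1.65, 0.42))   # 0.8404  closed form
print(mean_binormal_empirical_auc(1.13, 0.31, 34, 1.65, 0.42, 67,
                                  direction="lower", n_rep=500, seed=1))
# 0.8396  -- mean empirical AUC over 500 simulated 67/34 cohorts
```

The fitted `1.42 / 0.81` shows the fitter inverting its forward model
exactly; the two AUCs agree because the empirical AUC is an unbiased
estimate of P(ADC_MIBC < ADC_NMIBC).

End-to-end runs are driven by a YAML config (see `examples/stage_run.yaml`):

```sh
dkitex all --config examples/stage_run.yaml --out results/stage_run --seed 29
```

which simulates a 101-patient staging cohort of lesion phantoms, fits
DKI/ADC maps, extracts the feature table, and writes comparison and ROC
tables (`report/report.txt`, `report/report.json`, CSVs) plus reader-ICC,
VI-RADS and combination summaries.

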