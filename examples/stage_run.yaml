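# Staging cohort at the published study conditions: 67 NMIBC / 34 MIBC
# patients, image-level lesion phantoms, default grid and Rician noise.
seed: 29
simulate:
  endpoint: stage
  phantoms: true
  latent_rho: 0.6        # shared latent severity -> correlated markers
  phantom:
    shape: [64, 64, 16]
    spacing: [3.125, 3.125, 4.0]   # mm; 4 mm slices
    semi_axes_mm: [10, 10, 8]
    field_cv: 0.25
    sigma: 2.0           # per-excitation noise, S0 = 100
fit:
  adc_b_max: 1000
texture:
  nbins: 64
  inhomogeneity: cv
stats:
  endpoints: [stage, grade]
  combination: [md_p75, md_p90, mk_p90]
  virads_threshold: 3
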