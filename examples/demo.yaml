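# Demo: two inflammatory-biomarker exposures with an upstream->downstream
# causal chain (exposure1 -> exposure2, theta = 0.5), a null direct effect
# for exposure1 and a protective direct effect (log-OR -0.08, OR ~ 0.92)
# for exposure2, on a binary outcome with a 4.37% case fraction.
seed: 11

scenario:
  n_snps: 120
  beta_causal: [0.0, -0.08]
  chain_theta: 0.5
  gamma_sd: 0.05
  n_exposure: [8296, 48164]
  n_outcome: 153560
  outcome_case_fraction: 0.0437
  outcome_scale: lmm          # outcome emitted on the 0/1 scale, converted
  ld_blocks: [[3, 0.8], [3, 0.8]]

thresholds:
  p_significant: 5.0e-8
  clump_r2: 0.001
  clump_window_kb: 10000
  maf_min: 0.01
  palindrome_policy: infer
  eaf_tolerance: 0.08

n_boot: 1000
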