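# Beta-defensin-cluster-style condition: modal copy number 4 with a broad
# integer CN distribution, 366 normalized high-quality samples, 127 bp qPCR
# target amplicon vs 443 bp PRT amplicons, measured absolute efficiency gap
# 7.36% to the reference.
n_samples: 366
cn_distribution: {2: 0.04, 3: 0.24, 4: 0.37, 5: 0.23, 6: 0.09, 7: 0.02, 8: 0.01}
input_model: {kind: normalized, ng: 5.0}
degradation_model: {kind: intact}
ct_noise_sd: 0.08
area_noise_cv: 0.02
pcr_cycles: 30
detection_threshold: 1.0e+10
n_replicates_qpcr: 3
n_replicates_prt: 1
poisson_template: true
seed: 1
modal_cn: 4
calling: {sigma0: 0.1, cv: 0.05, k_max: 10}
assays:
  qpcr_target: {name: DEFB4, efficiency: 1.00, amplicon_length: 127}
  qpcr_reference: {name: RNaseP, efficiency: 1.0736, amplicon_length: 87}
  prt: {name: DEFB4-PRT, efficiency: 0.95, amplicon_length: 443, paralog_length: 443, reference_copies: 2}
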