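# Same assays as normalized_intact, but input DNA drawn lognormally with
# arithmetic mean 13.28 ng/reaction and a spread covering roughly 2-120 ng,
# as in a non-normalized sample set. The 5.95% efficiency gap then drifts
# dCt with input and biases called copy numbers.
n_samples: 400
cn_distribution: {2: 1.0}
input_model: {kind: lognormal, mean_ng: 13.28, sigma_log: 0.7}
degradation_model: {kind: intact}
ct_noise_sd: 0.08
area_noise_cv: 0.02
pcr_cycles: 26
detection_threshold: 1.0e+10
n_replicates_qpcr: 3
n_replicates_prt: 1
poisson_template: true
seed: 1
modal_cn: 2
calling: {sigma0: 0.1, cv: 0.05, k_max: 10}
assays:
  qpcr_target: {name: PRELID1, efficiency: 1.0823, amplicon_length: 107}
  qpcr_reference: {name: RNaseP, efficiency: 1.1418, amplicon_length: 87}
  prt: {name: PRELID1-PRT, efficiency: 0.95, amplicon_length: 299, paralog_length: 299, reference_copies: 2}
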