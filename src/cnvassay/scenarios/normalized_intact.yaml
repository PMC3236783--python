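# PRELID1-style duplex qPCR + single-primer-pair PRT on normalized (5 ng),
# intact genomic DNA. The reference (RNase P) carries the measured 5.95%
# absolute efficiency gap on the high side, the direction consistent with the
# observed positive input-amount bias of called copy numbers.
n_samples: 400
cn_distribution: {2: 1.0}
input_model: {kind: normalized, ng: 5.0}
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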