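# Small demonstration run: 18 subjects across two studies, default
# CPMG echo train, Rician noise, log-logistic fits only.
seed: 7
cohort:
  group_sizes: [8, 6, 4]
  study_counts: {HC: [4, 4], MCI: [3, 3], AD: [2, 2]}
phantom:
  echo_preset: cpmg10
  noise_model: rician
  noise_sd: 0.02
caps: [30, 200]
families: loglogistic
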