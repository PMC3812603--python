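# Demo experiment: synthetic 24-subject cohort, both kernels, cost sweep.
synth:
  seed: 7
  n_subjects: 24
  seconds_per_state: 42
eval:
  k: 5
  seed: 7
  kernels: [polykernel, normalized_polykernel]
  costs: [1, 10, 50]
  group_field: group
  p_inattentive: 0.1
svm:
  degree: 2
  standardize: true
out_dir: eegattn_demo_run
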