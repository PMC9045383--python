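# Demo pipeline configuration: the default synthetic study design.
# Run with:  microdyn run-all --config configs/demo.yaml
outdir: results/demo
seed: 0
cohort:
  n_subjects: 4
  n_timepoints_per_phase: [5, 8, 5]
  n_otus: 200
  shared_weight_inside: 0.5
abundant_threshold: 0.90
n_pcs: 25
network_min_abundance: 0.01
network_min_rho: 0.5
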