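# Demo pipeline config: overrides of the built-in defaults.
# Run with:  endowm run --config configs/demo.yaml --out runs/demo
seed: 7
voxelwise:
  n_perm: 500
  alpha: 0.05
connectivity:
  n_subjects: 6
cohort:
  n: 36
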