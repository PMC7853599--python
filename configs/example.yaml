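# A reduced scenario for quick interactive runs:
#   stemtherm run-all --config configs/example.yaml --outdir results/demo
scenario:
  genotype:
    n_genotypes: 60
  grid_rows: 16
  grid_ranges: 20
  seed: 1
spatial_correct: false
gdd_base: 0.0
k_flat: 3
tol_mm: 5.0
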