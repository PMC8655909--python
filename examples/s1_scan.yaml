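# Adsorption scan of the structured S1 hairpin on a Debye-Hueckel wall.
# Run with:  rnadsorb run examples/s1_scan.yaml
fragment:
  label: S1
  structured: true
wall:
  kind: debye_huckel
  eps_surf: [0.44, 0.89, 1.33, 1.78]
  eps_r: 1.0
  lambda_r: 0.1
  lambda_d: 1.0
windows:
  spring: 50.0
  n_equil: 500
  n_prod: 2500
  sample_stride: 10
edwards:
  enabled: true
  kuhn_length: 1.2
seed: 1
outdir: s1_scan_out
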