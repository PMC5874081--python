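# Demo meta-analysis on synthetic inputs: a planted-enrichment DEG list
# tested against two annotation tracks, calibrated against a Monte-Carlo
# null, plus a phenotype interaction test. Runs in well under two minutes.
seed: 1
alpha: 0.05
universe:
  size: 27416
tracks:
  - label: high_H2AZ
    size: 4081
  - label: low_H2AZ
    size: 4081
deg_lists:
  - label: deg_mutant
    size: 800
    theta: 3.0
    track: high_H2AZ
  - label: deg_other
    size: 800
    theta: 3.0
    track: high_H2AZ
concordance: 0.9
comparisons:
  - a: deg_mutant
    b: high_H2AZ
  - a: deg_mutant
    b: low_H2AZ
  - a: deg_mutant
    b: deg_other
null:
  K: 2000
  size_range: [500, 2000]
phenotypes:
  generate:
    n_per_cell: 15
    beta_interaction: -3.0
    sigma: 0.5
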