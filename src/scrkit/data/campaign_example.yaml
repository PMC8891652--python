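# Example FACS enrichment scenario: a mostly-mediocre library with a few
# improved variants, gated 2% then 1% then 1% as in a three-round campaign.
variants:
  - {id: parent_like, efficiency: 0.55, abundance: 0.90}
  - {id: improved_a, efficiency: 0.85, abundance: 0.05}
  - {id: improved_b, efficiency: 0.95, abundance: 0.04}
  - {id: near_reference, efficiency: 1.00, abundance: 0.01}
params:
  cells_per_round: 1000000
  gate_fractions: [0.02, 0.01, 0.01]
  amplification: 25.0
  noise_cv: 0.3
  seed: 7
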