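# Knockdown x hormone replicate experiment: 60% of the responsive genes are
# dampened to 40% of their hormone effect in the knockdown conditions.
de:
  n_genes: 1200
  n_replicates: 3
  n_responsive: 800
  dampened_fraction: 0.6
  dampening_factor: 0.4
  residual_sd: 0.1
  seed: 11
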