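# Selection-driven ("bacteria-like") fixture: 6 patches, 51 samples, 200 taxa.
# Alpha diversity declines with patch area; assembly is deterministic-dominated.
seed: 42
n_null: 99
n_permutations: 100
network_profile: bacteria-like
simulate:
  regime: selection
  n_taxa: 200
  reads_per_sample: 2000
  m: 0.3
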