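# Dispersal-limited ("fungi-like") fixture: 6 patches, 51 samples, 200 taxa.
# Within-patch beta diversity rises with patch area; assembly is stochastic.
seed: 42
n_null: 99
n_permutations: 100
network_profile: fungi-like
simulate:
  regime: dispersal_limited
  n_taxa: 200
  reads_per_sample: 2000
  m: 0.1
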