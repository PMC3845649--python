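# Donor-vs-pathogen contrast: one 19-kb tandem triplication.
# Run with:  strainforge run --config examples/scenario_cs_vs_pop.yaml --outdir out/
scenario: cs_vs_pop
seed: 7
options:
  depth: 35
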