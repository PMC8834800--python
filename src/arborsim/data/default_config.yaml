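# Default run configuration: the full nine-scenario street-tree study.
# Species parameters default to the bundled table (Zelkova serrata 66.6,
# Prunus yedoensis 45.3, Pinus densiflora 24.2, other 35.7 g/tree/year).
mode: flat
target_ratio: 0.7
output_dir: results
scenarios:
  - Baseline
  - Rep_only_Zelko
  - Rep_only_Prun
  - Rep_only_Pinus
  - Rep_only_Mix
  - Plant_more_Zelko
  - Plant_more_Prun
  - Plant_more_Pinus
  - Plant_more_Mix
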