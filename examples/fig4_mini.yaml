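# Small end-to-end recipe: fit the model on a radius-12 dome over a few
# seeds, categorise the accepted sets and export per-category central-axis
# expression profiles (axis_profiles.tsv) plus the full results table.
template:
  kind: 2d
  radius: 12
seeds: [0, 1, 2, 3]
out_dir: results/fig4-mini
categorize: true
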