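promoter_halfwidth: 2500
flank: 200
target_window: 500000
jaccard_min: 0.1
edge_alpha: 0.001
diff_alpha: 0.05
diff_log2fe: 1.0
de_log2fc: 0.5
tf_log2fc: 1.0
mcl_inflation: 2.0
loess_span: 0.25
seed: 1
stitch_gap: 0
density_epsilon: 0.0001
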