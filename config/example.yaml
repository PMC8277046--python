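cell_line: BT-474-like
cells_per_pct: 800.0
fraction: 0.75
g_min: 0.1
g_star: 1.0
glucose_levels_mm:
- 0.1
- 0.5
- 1.0
- 2.0
- 5.0
- 10.0
n_draws: 400
n_rounds: 5
n_starts: 4
out_dir: runs
replicates: 2
seed: 7
theta: 100.0
tiers_pct:
- 23.8
- 51.7
weighting: gls
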