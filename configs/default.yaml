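# Default end-to-end run: synthetic confounded cohort at registry scale.
out_dir: results/run_default
seed: 1
k_folds: 5
learner: gbt
effect_modifiers: [bmi]
tree_min_leaf: 50
tree_max_depth: 3
policy_thresholds: [0.0, 0.2, 0.5]
max_missing_fraction: 0.5
sim:
  n_patients: 1235
  seed: 1
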