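# Example end-to-end run configuration for `tbal run-all --config ...`.
# A small cohort that completes in a couple of minutes on one CPU; scale
# n_patients / hidden_size / max_epochs up for real experiments.
workdir: runs/demo
seed: 7
sim:
  n_patients: 200
  n_numeric_vars: 8
  n_categorical_vars: 2
  causal_vars: [num_00, num_01, num_02]
  effect_sizes: [2.0, 1.6, 1.2]
  target_mortality: 0.085
task:
  kind: dynamic          # or: kind: static, trigger_h: 12, horizon_h: 24
model:
  hidden_size: 16
  attention_dim: 16
  max_context_h: 24.0
  dropout: 0.3
train:
  max_epochs: 10
  patience: 4
  triggers_per_stay: 6
  early_stop_metric: auroc
  input_dropout: 0.3
eval:
  n_boot: 200
  stride_h: 4.0
attribution:
  m_steps: 32
  stride_h: 8.0
  max_stays: 40
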