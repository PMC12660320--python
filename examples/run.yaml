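# Example pipeline configuration (field paths mirror RunConfig):
#   revlearn run --config examples/run.yaml --seed 42 --out results/
task:
  block_lengths: [100, 100, 60, 60]
  p_high: 0.70
  p_low: 0.30
  reversal_period: 25
cohort:
  n_subjects: 8           # raise to 26 for a study-scale cohort
  conditions: [NAcc, dACC, Sham]
  base_params:
    model_id: RW2
    alpha_pos: 0.35
    alpha_neg: 0.35
    beta: 5.0
  condition_effects:
    NAcc:
      alpha_pos: 0.15     # NAcc-like: higher learning rate after reward
  lost_rate: 0.02
grid:
  alpha_steps: 9          # coarser than the default 17 for a quick run
  beta_steps: 10
models: [RW1, RW2]
fit_granularity: session
likelihood_mode: observed
analyses:
  winstay: true
  blockwise: true
  learning_curve: true
  model_comparison: true
seed: 42
log_level: INFO
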