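generator:
  n_subjects: 16
  n_trials: 3
  subject_sd: 0.05
  trial_sd: 0.1
  seed: 1
  effects:
    - channel: knee_sagittal_angle
      window: [15, 25]
      amplitude: 2.0
      shape: boxcar
tasks: [all, knee]
k: 8
seed: 1
hyperparams:
  preprocess: center
  learning_rate: 0.3
  l2: 0.01
  init_scale: 0.1
  max_epochs: 1500
  patience: 50
rs_threshold: 0.7
early_window: [1, 22]
alpha: 0.05
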