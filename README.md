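# landing-xlr

Explainable classification of lower-limb landing waveform patterns.

The package implements a complete, reproducible pipeline for a paired
(before/after fatigue) landing study design:

1. **`synth`** — generate synthetic two-class landing datasets: 18 waveform
   channels (ankle/knee/hip x sagittal/frontal/transversal x angle/moment),
   101 time-normalized nodes per trial, subject-level random effects shared
   across the paired conditions, smooth trial noise, and configurable
   phase-localized class-difference templates (boxcar or raised cosine).
2. **`tasks`** — build the nine channel-subset classification tasks
   (all / kinematics / kinetics / per-joint / per-plane), subject-grouped
   eight-fold cross-validation with a rotating train(6)/validation(1)/test(1)
   scheme, and the Zero-R majority-class baseline.
3. **`mlp`** — a transparent dense network (tanh hidden layer, linear
   two-unit output) trained by full-batch gradient descent with early
   stopping on the validation fold; every weight, pre-activation and
   activation is exposed via a full forward trace.
4. **`lrp`** — layer-wise relevance propagation with the proportional
   z-rule: the decomposed class score is redistributed layer by layer down
   to the channel x node input grid, with an epsilon-stabilized denominator
   and exact layer-wise conservation (leakage reported per trial).
5. **`relevance`** — post-processing: rectified averaging over correctly
   classified test trials, three passes of the 25/50/25 smoothing kernel,
   min-max scaling to [0, 1], contribution shares per channel / joint /
   plane / 1%-phase bin, and extraction of highly relevant variables
   (relevance score > 0.7).
6. **`spm`** — statistical evaluation: 101-node paired-t trajectories, a
   random-field-theory family-wise threshold at the estimated residual
   smoothness (with a sign-flip permutation threshold as a nonparametric
   cross-check), Rosenthal t→r effect-size trajectories with 0.5/0.8
   banding, and a quantified concordance report between high-relevance runs
   and supra-threshold SPM clusters.
7. **`pipeline` / `cli`** — orchestration of the full run from a single
   YAML/JSON configuration with per-stage seeding and a JSON run report.

## CLI

```sh
# generate a dataset
landing-xlr synth --config examples/run.yaml --out data.csv

# build a task matrix / fold plan
landing-xlr tasks --data data.csv --task knee --folds 8 --seed 7

# cross-validated training
landing-xlr train --data data.csv --task all --preprocess center --seed 7

# per-channel paired SPM
landing-xlr spm --data data.csv --alpha 0.05

# full pipeline (synth -> train -> explain -> aggregate -> spm -> report)
landing-xlr run --config examples/run.yaml --out runs/demo
```

A run configuration is a YAML/JSON mapping; all keys are optional except
the generator block, e.g.:

```yaml
generator:
  n_subjects: 16
  n_trials: 3
  subject_sd: 0.05
  trial_sd: 0.1
  seed: 1
  effects:
    - {channel: knee_sagittal_angle, window: [15, 25], amplitude: 2.0, shape: boxcar}
tasks: [all, knee]
k: 8
seed: 1
hyperparams: {preprocess: center, learning_rate: 0.3, l2: 0.01, init_scale: 0.1}
rs_threshold: 0.7
early_window: [1, 22]
alpha: 0.05
```

`landing-xlr run` writes `dataset.csv` and `report.json` into the output
directory; the report contains per-task cross-validation accuracies with
Zero-R baselines, contribution tables, high-relevance runs, per-channel SPM
summaries, and the relevance/SPM concordance block.

## Data format

Datasets are wide CSV tables: `subject`, `class`, then
`<joint>_<plane>_<quantity>_<node>` columns in joint-major channel order
for nodes 0..100, with a JSON sidecar recording the generator provenance.
All values round-trip bit-exactly through write/read.
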