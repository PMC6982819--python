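# comgait

Lower-limb kinetics and kinematics from a single sacrum-worn
accelerometer. The package implements a complete, self-contained
pipeline:

1. **`comgait.slip_model`** — a compliant walking model (leg spring +
   off-centered rolling "curvy" foot). Provides the nonlinear stance
   simulation (fixed-step RK4 with bisection event location) and the
   affine maps that express ground reaction forces, ankle torque and
   segment angles as weighted sums of the body CoM position — the
   motivation for using CoM kinematics as network inputs.
2. **`comgait.synthetic_data`** — generation of sacrum-acceleration
   walking trials with ground-truth gait events and a matched 11-channel
   label track (2 GRFs, 3 joint torques, 6 segment angles), built by
   stitching stance simulations with double-support load-transfer ramps.
   Includes a seeded sensor-noise model (white noise, bias, bias drift)
   and lossless CSV trial I/O.
3. **`comgait.preprocessing`** — zero-phase Butterworth filtering,
   heel-strike / toe-off / CoM-apex detection from the acceleration
   signal, stance segmentation, drift-removed integration, the
   gait-speed offset regression, and assembly of per-stance 7×200
   feature blocks `(t, x, y, vx, vy, ax, ay)`.
4. **`comgait.inverse_dynamics`** — planar bottom-up Newton–Euler
   recursion (foot → shank → thigh) used to produce joint-torque labels.
5. **`comgait.predictor`** — a 7–20–11 feed-forward network (sigmoid
   hidden layer, linear output, Adam, plain-JSON weight serialization)
   and a leave-one-subject-out evaluation harness with NRMSE / MAE /
   Pearson reporting, input-row ablations and speed-restricted training.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes a `tests/test_acceptance.py` with one test per
acceptance criterion; the leave-one-subject-out criterion trains
14 networks and takes ~10 minutes on one CPU.

## CLI

```sh
comgait simulate --config cfg.yaml --seed 1 --out runs/trial
comgait events   --trial runs/trial --out runs/events
comgait features --trial runs/trial --out runs/features
comgait train    --config cfg.yaml --seed 1 --out runs/train
comgait evaluate --config cfg.yaml --seed 1 --out runs/eval
comgait report   --metrics runs/eval/metrics.csv --out runs/report
```

All stages write a `config.resolved.yaml` next to their artifacts; every
artifact is reproducible from that file and the seed. Exit codes:
`2` missing input, `3` invalid configuration.

A minimal config (all keys optional, defaults shown in
`comgait/config.py`):

```yaml
seed: 0
speed: 1.42
n_steps: 31
cohort: {n_subjects: 7, n_steps: 31, segments_per_trial: 30}
train: {epochs: 300, batch_size: 1024, learning_rate: 0.001}
filter: {hs_cutoff_hz: 40, to_cutoff_hz: 10}
resample: {points: 200}
```

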