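# gaitclass

Classification of hospitalized patients' walking-independence level (WA =
walking acquired vs NA = not acquired, NA positive) from eight body-worn
inertial sensors recorded during the 10-m walk test (10MWT) and the Timed
Up-and-Go test (TUG).

The package implements the full pipeline as reusable, tested components:

- **`gaitclass.synthetic`** — synthetic cohort generator (the patient data are
  not publicly available): harmonic walking signals with ankle impact
  transients at each initial contact, TUG recordings with sit-to-stand /
  turn / stand-to-sit angular-velocity bursts, ground-truth event indices,
  CSV + YAML-manifest export.
- **`gaitclass.segmentation`** — 1 Hz zero-phase high-pass on acceleration,
  initial-contact detection from the differenced combined ankle
  acceleration, TUG sub-phase segmentation from the lumbar pitch/yaw rates
  (0.1 relative threshold around each burst anchor), walking-interval
  extraction (10MWT drops the first and last gait cycle), and left
  gait-cycle slicing (one window per consecutive pair of left initial
  contacts).
- **`gaitclass.dataset`** — per-trial, per-axis-group normalization to [0, 1]
  with baseline 0.5; padding to a fixed length (default 276) with 0.5;
  uniform-noise augmentation (x5 by default); sensor masking with the
  constant 0.5; leakage-free leave-one-subject-out fold assembly with label
  balancing.
- **`gaitclass.model`** — Transformer encoder classifier (linear embedding,
  sinusoidal positional encoding, 5 post-norm attention/feed-forward blocks
  at d_model 48, flatten to 13248 features, FC softmax head) implemented on
  NumPy with hand-written backpropagation and Adam, so it trains on a plain
  CPU with no deep-learning framework.
- **`gaitclass.evaluation`** — leave-one-subject-out cross-validation with
  cycle-pooled confusion matrices, accuracy/sensitivity/specificity, and the
  sensor-ablation sweep (full set, each leave-one-sensor-out subset, and the
  named 5/3/2-sensor subsets); CSV/PNG reporting.

## CLI

```bash
gaitclass simulate --n-wa 7 --n-na 5 --seed 0 --desk-scale --out cohort/
gaitclass segment --manifest cohort/manifest.yaml --out windows.h5
gaitclass train-loocv --windows windows.h5 --seed 0 --out results/
gaitclass ablate --windows windows.h5 --sweep named --seed 0 --out ablation/
```

`train-loocv`/`ablate` accept `--config config.yaml` with `model:` and
`train:` sections mirroring `ModelConfig` / `TrainConfig` (defaults: 130
epochs, batch 64, learning rate 1e-5, d_model 48, 5 blocks).

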