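# exitrec

Real-time recognition of bed and chair exits from batteryless wearable
RFID sensor streams. The package implements the full pipeline:

- **`exitrec.io`** — domain types (sensor observations, activity labels,
  interval annotations, room/antenna layouts) and CSV readers/writers.
- **`exitrec.simulate`** — a synthetic trial generator: scripted activity
  sequences, posture-dependent accelerations, inverse-fourth-power
  backscatter RSSI with log-normal multipath, and occlusion-driven
  irregular read arrival, with exact interval ground truth.
- **`exitrec.features`** — per-observation features: instantaneous values,
  4-second contextual-window statistics, and inter-segment differences,
  with an extra feature family gated per room configuration.
- **`exitrec.crf`** — a linear-chain CRF trained with a dynamically
  class-weighted log-likelihood (to counter severe class imbalance) and
  exact online filtered-marginal inference via the forward sum-product
  recursion (numba-accelerated, O(K²) per observation).
- **`exitrec.recognize`** — the streaming recognizer: a 1-second score
  function over marginals assigns activities; a finite-state machine over
  consecutive assignments emits bed/chair-exit alerts with a 1.75-second
  same-kind suppression window.
- **`exitrec.evaluate`** — event-level alarm scoring (TP/FP/FN with a
  5-second matching window), recall/precision/F-score, delay statistics,
  and a rotating 6/2/2 ten-fold cross-validation harness with
  hyperparameter selection.

## CLI

A single entry point with subcommands:

```sh
exitrec simulate  --room room2 --seed 0 --n-trials 10 --out-dir trials/
exitrec featurize --room room2 trials/trial000.stream.csv --out features.csv
exitrec train     --room room2 --tau 1 --vartheta 3e-4 trials/ --out model.json
exitrec recognize --model model.json trials/trial001.stream.csv \
                  --alerts-out alerts.csv --labels-out labels.csv
exitrec evaluate  --alerts alerts.csv \
                  --annotations trials/trial001.annotations.csv --out metrics.json
exitrec crossval  --room room2 trials/ --out report.json
```

Trials are plain CSV pairs (`<stem>.stream.csv` with header
`t,a_v,a_l,a_f,rssi,antenna_id,phase,channel,participant_id,gender`, and
`<stem>.annotations.csv` with `start,end,label`).

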