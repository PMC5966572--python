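# tremordiff

Tremor-accelerometry analysis pipeline for differentiating Parkinsonian (PD)
from essential tremor (ET) under two postural conditions, with a synthetic
cohort generator standing in for patient recordings.

The pipeline covers:

- **Synthetic cohorts** (`tremordiff.synthetic`) — labeled 3-axis, 1000-Hz
  acceleration recordings per subject and posture (arm-stretching P1 in five
  trials, arm-rested P2 in one 5-minute trial). Each subject's tremor is an
  amplitude-modulated stack of quadratically phase-coupled harmonics (so the
  bispectrum is non-degenerate) plus sub-1-Hz drift, 50-Hz mains and sensor
  noise; intensity and fundamental-frequency distributions are calibrated per
  (subgroup, posture) so post-pipeline feature statistics match configurable
  group targets.
- **Preprocessing** (`tremordiff.preprocess`) — 30-s non-overlapping windows
  cut within trials, cascaded zero-phase notch filters at 50 Hz and
  harmonics, a zero-phase order-2 Butterworth 1–20 Hz bandpass, decimation to
  100 Hz, and reduction of the three axes to the first principal direction.
- **Features** (`tremordiff.features`) — per-segment mean absolute value
  (analyzed as ln-MAV) and dominant frequency from two estimators: a
  Hanning-windowed Welch PSD and the diagonal slice of the bispectrum
  computed via the indirect (third-order cumulant + Hanning lag window)
  method.
- **Differentiation statistics** (`tremordiff.diffstats`) — the
  discrimination coefficient α = |mean_A − mean_B| / (SD_A + SD_B) against
  the 0.7 level, single-feature binary logistic regression (hand-rolled
  IRLS with separation detection), ROC/AUC, and the Youden-optimal cut-off
  mapped back to feature units (ET is the positive class).
- **Orchestration** (`tremordiff.pipeline`, `tremordiff.cli`) — full
  experiment runs over all (feature × posture × group-pair) cells and a
  recording-length sweep (5–300 s) of the dominant-frequency discrimination
  coefficient.

## CLI

```sh
# full synthetic experiment (13/13/12/12 subjects, 300-s recordings)
tremordiff run --out results/run --seed 1

# stage by stage
tremordiff simulate --out data/cohort --seed 1
tremordiff features --recordings data/cohort --out results/features.csv
tremordiff analyze --features results/features.csv --out results/report
tremordiff sweep --recordings data/cohort --out results/sweep.csv
```

All commands accept `--config config.yaml` (see
`tremordiff.pipeline.ExperimentConfig.to_yaml` for the schema). Recordings
are stored as `time_s,ax,ay,az` CSV files with JSON metadata sidecars.

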