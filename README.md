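# ecogvad

Frame-wise **speech-event detection from ECoG** ("neural voice-activity
detection"): band-wise Hilbert-envelope features, a linear frame detector
with Haufe-style activation-pattern interpretation, surrogate labeling for
imagined speech, multi-electrode stacking, trial-wise permutation
statistics, and cross-mode / cross-subject model transfer — exercised end
to end on a paradigm-structured synthetic ECoG generator with known ground
truth.

## What it does

1. **Synthetic ECoG** (`ecogvad.synthetic`) — a cued-sentence paradigm
   (1 s task cue, jittered 2 s preparation, go cue, a few seconds of
   speech) rendered as multichannel band-limited noise whose per-band
   amplitude is modulated during speech. Modulation sign/magnitude depends
   on electrode region (motor / temporal / other) and speech mode
   (performed / perceived / imagined); imagined trials expose no
   behavioral timing. Optional 50 Hz line noise and cue-locked bursts.
2. **Preprocessing** (`ecogvad.preprocessing`) — amplitude-artifact
   screening (1 mV), per-grid common average reference, zero-phase notch,
   then per band (delta 0.5–4 … high-gamma 70–120 Hz): 4th-order
   zero-phase Butterworth band-pass, Hilbert envelope, 0.25 Hz zero-phase
   low-pass. Features per frame: each band's envelope at −125/0/+125 ms →
   21 columns (band-major, lag-minor), z-scored on training folds only.
3. **Labeling** (`ecogvad.labeling`) — ±1 frame labels from speech
   windows, per-trial class balancing with silence drawn adjacent to the
   window, surrogate imagined-speech timing from the consensus of
   performed trials (trial-averaged label > 0.9 speech, < 0.1 silence,
   ≤ 500 ms of end-of-trial silence), the 4 s cue-centered passive
   dataset, and the <50 % passive-accuracy exclusion rule.
4. **Detection** (`ecogvad.detector`) — OLS regression to ±1 targets,
   thresholded at 0 (non-negative → speech), leave-one-trial-out CV with
   per-trial accuracies, fold-averaged activation patterns
   (`Cov(X)·w / Var(output)`, normalized to max |·| = 1), and a cached
   LOTO engine for fast permutation testing.
5. **Ensemble** (`ecogvad.ensemble`) — electrodes ranked by the maximum
   |band-averaged feature–label correlation| (training folds only), a
   second-level regressor over single-electrode outputs, and recursive
   Wilcoxon-based selection of the electrode count.
6. **Transfer** (`ecogvad.transfer`) — train on one mode/subject, test on
   another (each dataset z-scored by its own statistics; low-band-only
   variant supported), plus a pooled multi-subject CV with one held-out
   trial per subject per fold.
7. **Statistics** (`ecogvad.stats`) — trial-wise permutation tests (labels
   of a random half of trials reversed; p = (N+1)/(n_perm+1)), one-sided
   Wilcoxon signed-rank and rank-sum comparisons.

## CLI

```sh
ecogvad simulate --config cfg.yaml --seed 1 --out out/        # synthetic recording + events
ecogvad features --recording out/recording.h5 --trials out/trials.tsv --out frames.h5
ecogvad label    --recording out/recording.h5 --trials out/trials.tsv \
                 --mode imagined --passive --out frames.h5
ecogvad detect   --features frames.h5 --electrode M1 --mode performed --bands full
ecogvad ensemble --features frames.h5 --mode performed --max-electrodes 5
ecogvad transfer --train frames.h5:M1/performed --test frames.h5:M1/imagined
ecogvad permtest --features frames.h5 --electrode M1 --mode performed --n-perm 10000 --seed 1
ecogvad run      --config demo.yaml --seed 1 --out results/pipeline
```

`ecogvad run` executes the whole chain on synthetic data and writes
per-electrode accuracy tables, accuracy-vs-electrode-count curves,
band-subset comparisons, activation-pattern matrices, cross-mode transfer
matrices and a permutation test as TSV/JSON, each stamped with the config
hash and seed (bit-identical on rerun).

Recordings are stored in an HDF5 container (`/signals` + channel/grid
metadata); events in BIDS-iEEG-flavored TSV. EDF reading is available when
`pyedflib` is installed.

## Layout

```
src/ecogvad/
  bands.py           frequency-band definitions and subsets
  datatypes.py       EcogRecording, EnvelopeTensor, FrameDataset, models
  filters.py         zero-phase Butterworth helpers
  synthetic.py       paradigm + signal generator (ground truth kept hidden)
  preprocessing.py   CAR, notch, envelopes, frame features, z-scoring
  labeling.py        speech windows, balancing, surrogate timing, passive set
  detector.py        OLS detector, LOTO CV, activation patterns
  ensemble.py        ranking, stacking, electrode-count selection
  transfer.py        cross-mode/subject transfer, pooled model
  stats.py           permutation tests, Wilcoxon comparisons
  io.py              HDF5 container, TSV tables, optional EDF
  pipeline.py        end-to-end orchestration
  cli.py             click-based CLI (`ecogvad`)
tests/               unit + property tests, test_acceptance.py
scripts/acceptance.py
```
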