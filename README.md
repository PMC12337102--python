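# specd

Streaming speech-event decoding from multichannel neural feature streams:
a causal 5-class detector that turns continuous probabilities into discrete
speech events, a verification gate that accepts only confident attempted
speech (rejecting reading/listening), and a closed-vocabulary word
classifier — together with a seeded synthetic sensorimotor-ECoG simulator
and an offline neural-analysis suite (electrode responsiveness, gradient
electrode contributions, multitaper band power, longform activation tests).

Since real clinical recordings of this kind are access-restricted, the
simulator is a first-class component: it generates sessions with known
ground truth (electrode classes, task-evoked gains, word tuning, band
modulation, true attempt times) against which every downstream stage is
trained and scored.

## Layout

| module | role |
| --- | --- |
| `specd.features` | common-average reference, HGA (70–150 Hz envelope) and LFS (1–100 Hz) extraction at 200 Hz, sliding/trial z-scores, artifact scan |
| `specd.simulate` | seeded synthetic sessions: electrode grids, task schedules (isolated-target, self-paced online, longform, rest), evoked responses, theta/beta modulation |
| `specd.detect` | frame labels, 3-layer LSTM detector, causal probability traces, time-threshold event extraction, recognition latency |
| `specd.verify` | event windows around detected onsets (4 s, 33.3 Hz), conv+GRU verifier ensembles, threshold sweeps, context-length curves |
| `specd.classify` | conv+GRU word-classifier ensembles, time-window retraining with electrode-set ablations, cross-task transfer |
| `specd.evaluate` | event matching (0.5 s tolerance), TPR/FPR, pseudo-blocks, stratified 10-fold CV, Fisher exact / Holm–Bonferroni / permutation correlations |
| `specd.mapping` | rank-sum responsiveness maps, shared-electrode sets, gradient contributions, multitaper theta/beta power, longform activation |
| `specd.nets` | NumPy LSTM/GRU/conv networks with exact input gradients (no deep-learning framework required) |
| `specd.session` | session container (HDF5 round-trip), trial records, events, window extraction |

## CLI

```bash
specd simulate --config sim.yaml --seed 7 --out session.h5
specd features --in raw.h5 --out session.h5 --lfs-low 1.0
specd detect train --session session.h5 --model detector.pkl
specd detect run --session session.h5 --model detector.pkl --out events.json
specd evaluate --events events.json --truth session.h5 --report report.json
specd map responsiveness --session session.h5 --task speech --out maps.json
```

`sim.yaml` mirrors `specd.simulate.SimConfig` fields (electrode count,
class fractions, schedule, trial counts, SNR, …).

## Notes

- Everything is seeded; training is bit-reproducible on CPU.
- Model hyperparameter defaults (hidden 64, 10-member ensembles, 30 epochs)
  suit real-sized problems; tests use smaller settings for speed.
- Session files are HDF5 (`/hga`, `/lfs`, `/labels`, `/trials`, `/events`,
  `/electrodes`) and round-trip bit-exactly at float32 storage precision.
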