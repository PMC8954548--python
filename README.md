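# squigglecall

A joint raw + event nanopore basecalling pipeline, built end to end:

- **`simdata`** — reduced-complexity reference generation from a restricted
  6-mer vocabulary, a seeded pore-model squiggle simulator (~8 raw samples
  per base, Gaussian noise, per-base ground-truth alignment), and the
  restricted linguistic-complexity metric.
- **`events`** — raw-signal segmentation via sliding-window Welch
  t-statistics with non-maximum suppression, and the 5-feature event vector
  (mean, stdv, length, delta-mean, mean squared).
- **`samples`** — greedy event-window sample construction (`rawmax`=200,
  `eventmax`=30, `eventoffset` stride), shuffling/splitting, six
  train-split-only standardizers, a 7-token vocabulary
  (PAD/START/END/A/C/G/T), and padded/masked batching (batch 128).
- **`nn`** — a twin-encoder attention seq2seq model: two stacked BiLSTM
  encoders (raw and event, concatenated on the step axis in joint mode),
  multiplicative attention with padding masks, a single-layer LSTM decoder
  with an attentional output layer, masked cross-entropy, scheduled-sampling
  teacher forcing (ratio 0.5), global-norm gradient clipping (< 1), and
  greedy/beam decoding.  Implemented on a small tape-based NumPy autograd
  (`nn/autograd.py`) with fused, hand-derived LSTM and attention backward
  passes — no deep-learning framework is required.
- **`assembly`** — Needleman–Wunsch global alignment, overlap-aware merging
  of per-sample predictions into whole reads, exact-match (subset) accuracy,
  alignment-identity read accuracy with aligned-block-length weighting, and
  an accuracy-table summarizer (beam-width and model-variant gains).
- **`io_formats`** — fast5 (single- and multi-read HDF5 dialects, with pA
  calibration when metadata is present), FASTA, truth-alignment TSV
  (0-based half-open, validated to partition the signal), and an HDF5
  dataset cache.
- **`cli`** — stage orchestration with per-stage manifests.

## CLI

```sh
# simulate a reduced-complexity dataset (fast5 + FASTA + truth TSV)
squigglecall simulate --num-basic 12 --length 75000 --n-reads 10 \
    --seed 1 --out-dir runs/sim

# detect events, window, split, standardize, cache
squigglecall prepare --in-dir runs/sim --out-dir runs/prep --eventoffset 1

# train a model variant: raw | event | joint
squigglecall train --data-dir runs/prep --out-dir runs/model \
    --mode joint --epochs 100

# basecall fast5 reads to FASTA (beam width 1 = greedy)
squigglecall basecall --checkpoint runs/model/checkpoint.npz \
    --fast5 runs/sim/signals.fast5 --out runs/calls.fasta --beam-width 5

# score calls against references (per-read identity + weighted mean)
squigglecall evaluate --calls runs/calls.fasta \
    --references runs/sim/references.fasta --out runs/report.json
```

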