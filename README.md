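# emglens

Tools for analysing what convolutional networks learn from surface EMG
(sEMG) gesture windows, and how the learned features relate to classical
handcrafted features:

- **signal_io** — recording/window data model, causal Butterworth band-pass
  filtering (20–495 Hz, 4th order), sliding-window segmentation
  (151 samples, stride 51) and cycle-based train/val/test splits.
- **handcrafted** — a 56-method / 79-feature bank of per-channel window
  features in five functional groups (amplitude/power, frequency,
  non-linear complexity, time-series modelling, unique).
- **convnet** — a channel-independent 6-block ConvNet (1×26 kernels, 64
  maps, batch norm, leaky ReLU, dropout; 543,629 trainable parameters)
  with an 11-class gesture head and a 2-output domain head, implemented in
  pure NumPy with hand-written, finite-difference-verified backprop.
  Batch-norm scale/shift are shared weights; running statistics are kept
  in per-participant banks.
- **adann** — training loops: standard aggregate training and a
  multi-domain adversarial procedure (every participant serves as source
  each epoch, paired target batches from a random other participant,
  gradient reversal into the shared trunk, per-participant BN statistics),
  plus AdaBN evaluation on unseen participants and a Wilcoxon/Cohen's-d
  comparison utility.
- **interpret** — Guided Grad-CAM saliency (guided backpropagation ×
  broadcast Grad-CAM) and a Gaussian-noise probe.
- **mapper_tda** — a Mapper topological-data-analysis pipeline over
  feature point clouds (PCA to 99% variance → 2-D t-SNE lens → 5×5 cover
  at 65% overlap → Ward partial clustering → graph assembly), with
  scenarios A (handcrafted), B (learned) and C (hybrid).
- **downstream_eval** — single-feature / group LDA evaluation and a
  frozen-network regression probe from block activations to handcrafted
  feature values.
- **synthetic** — a multi-domain synthetic sEMG generator (gesture-specific
  channel-activation bumps on band-limited noise; per-participant channel
  rotation, gains and noise floors) so the whole stack is testable without
  any recorded data.

## CLI

```bash
emglens simulate --out data/ --participants 8 --gestures 5 --seed 0
emglens features --manifest data/manifest.json --out features.csv
emglens train --manifest data/manifest.json --method adann --checkpoint model.npz
emglens saliency --checkpoint model.npz --input window.csv --gesture 3 --out sal.csv
emglens mapper --manifest data/manifest.json --scenario A --out graph.json
emglens eval-lda --manifest data/manifest.json --feature MAV
emglens regress --manifest data/manifest.json --checkpoint model.npz --block 2 --feature MAV
```

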