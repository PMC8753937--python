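# noisyseg

Noise-tolerant segmentation of curvilinear (vessel-like) structures that
**jointly trains a segmenter and corrects its noisy pixel-wise labels**.
While a small U-Net-style network trains on noisy binary masks, a per-pixel
*memory bank* tracks the historical best and worst predictions of each
training cycle relative to that cycle's supervision map.  Training uses a
*temporal memory loss* (self-supervision toward the historical best plus a
λ-weighted term toward the current labels), and at the end of every cycle
the labels are moved by a confidence-weighted blend of the historical best
and the final prediction, anchored at the original noisy mask.

No external data is needed: the `synthetic` module generates vessel-like
phantoms with gold masks and corrupts them with polygonal
contour-approximation noise at three severity levels (LV1 < LV2 < LV3),
plus dilation/erosion and component-dropout surrogates.

Everything — including the network and its backprop — is plain NumPy, so
the whole pipeline runs (and is exactly reproducible) on one CPU.

## CLI

```bash
# build a synthetic noisy dataset (images/, gold/, noisy/, manifest.json)
noisyseg simulate --n 8 --size 96 --noise-kind contour_approx --level LV2 --seed 0 --out data/

# corrupt an existing directory of PNG masks
noisyseg corrupt --masks data/gold --level LV3 --seed 0 --out polluted/

# train + correct labels; writes model, per-cycle corrected masks,
# metrics.csv, report.json and curves.png
noisyseg train --config cfg.yaml --data data/ --out run/

# evaluate predictions against gold masks (macro-averaged F1 / PR score)
noisyseg evaluate --pred run/corrected --gold data/gold --out eval.json

# ablation variants: no_tml, q_is_s, q_is_sbest, full
noisyseg ablate --mode q_is_s --data data/ --out ablation/
```

`cfg.yaml` mirrors `TrainConfig` field-for-field (unknown keys are
rejected), e.g.:

```yaml
total_epochs: 100      # 50 init + 5 cycles x 10 epochs (defaults)
init_epochs: 50
n_cycles: 5
epochs_per_cycle: 10
warmup_epochs: 3       # plain supervised epochs while the bank accumulates
lambda_weight: 0.1
base_lr: 7.0e-3        # Adam
sgdr_start_epoch: 40   # cosine annealing with warm restarts, period 10
swa_enabled: true
model_width: 8
seed: 0
```

## Package layout

| module | responsibility |
| --- | --- |
| `noisyseg.synthetic` | phantom generation + label pollution (contour approximation, dilation/erosion, dropout) |
| `noisyseg.bank` | per-image, per-pixel historical best/worst prediction store |
| `noisyseg.losses` | soft-target BCE, warm-up loss, temporal memory loss |
| `noisyseg.correction` | confidence map, compensation blend, running-average label update |
| `noisyseg.trainer` | schedule (init / warm-up / TML), SGDR, SWA, flips, full run |
| `noisyseg.metrics` | pixel F1 and PR score (average precision), macro averaging |
| `noisyseg.model` | NumPy U-Net-style encoder-decoder with hand-written backprop + Adam |
| `noisyseg.data` | `SampleRecord` (with gold-mask access guard) and PNG dataset IO |
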