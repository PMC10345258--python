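# gcunet

A global-context attention encoder–decoder for cell-nuclei segmentation in
cytology/histology images, together with instance-level evaluation
(Aggregated Jaccard Index, Dice, Panoptic Quality) and a seeded synthetic
smear-image generator so the whole system is buildable and testable with no
dataset downloads.

The network runs on a small self-contained numpy autodiff engine
(`gcunet.nn`) — no deep-learning framework is required — so everything
trains and evaluates on a plain CPU.

## Components

| Module | Contents |
| --- | --- |
| `gcunet.nn` | Reverse-mode autodiff on numpy (conv / transposed conv / pooling / resizing / normalization layers, Adam), all gradients verified against finite differences |
| `gcunet.blocks` | Context-gating residual block (multi-kernel sigmoid gating, kernels 3/5/7/9), global-context attention (spatial-softmax pooled context vector with a bottleneck transform, r=16), multipath residual pooling (max-pool windows 2/3/5/7 concatenated back), decoder blocks, and a pyramid-pooling residual context module (bins 1/2/3/6) |
| `gcunet.network` | Densely connected encoder (full `densenet121` layout or a compact `densenet-mini` for CPU work), bottleneck composition, 4 decoder stages with skip connections, sigmoid head; combined BCE + dice loss; checkpoints with config-hash sidecars |
| `gcunet.metrics` | AJI, Dice, PQ/SQ/RQ with IoU>0.5 matching, instance extraction from probability maps (thresholding + connected components + size filter) |
| `gcunet.synthdata` | Seeded generator of smear-like scenes: rotated elliptical nuclei with controllable overlap, stain-like colors, clutter, noise and blur, plus exact instance ground truth |
| `gcunet.pipeline` | Pair loading, shared-transform augmentation (rotation/translation/normalization), seeded Adam training loop with exact checkpoint-resume, batch prediction with reflect padding |

## CLI

```bash
# generate a synthetic dataset (images + 16-bit instance maps + manifest)
gcunet --seed 1 synth --n 100 --out data/synth

# train (config file optional; every flag overrides its config key)
gcunet --config config.yaml --seed 1 train \
    --images data/synth --out runs/demo --epochs 100 --image-size 64

# predict on a directory (writes prob_*.tif, mask_*.png, inst_*.png)
gcunet predict --checkpoint runs/demo/checkpoint_0100.npz \
    --images data/synth --out runs/demo/pred

# score predictions against ground truth (JSON + CSV report)
gcunet evaluate --gt data/synth --pred runs/demo/pred --out report.json
```

A config YAML carries sections `model` / `train` / `augment` / `synth` /
`eval`; see `tests/test_pipeline.py::test_cli_train_and_predict` for a
worked example. Training defaults follow the reference configuration
(Adam, learning rate 1e-4, batch size 8, 200 epochs, 512×512 resize,
BCE + dice loss); tests and the desk-scale pipeline use 64×64 images and
the compact encoder to stay CPU-friendly.

## Conventions worth knowing

- Instance maps: integer arrays, 0 = background, ids ≥ 1; instance ids are
  assigned in raster-scan order of each component's first pixel.
- Degenerate metric cases: Dice and PQ of two empty maps are 1.0; a
  ground-truth instance with no intersecting prediction contributes its
  area to the AJI denominator only.
- Instance extraction uses 4-connectivity by default (8 available).
- Model inputs must be multiples of 32 in each spatial dimension;
  `pipeline.predict` reflect-pads arbitrary sizes and crops the output back.
- Everything is seeded: same seed ⇒ bit-identical synthetic data, initial
  parameters, and training records (including across checkpoint resume).
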