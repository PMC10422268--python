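# cropseg

Attention encoder–decoder semantic segmentation for multispectral crop
mapping (corn / soybean / other), built to run entirely on synthetic field
mosaics so the whole pipeline is testable offline.

The package provides:

- **`cropseg.synthgen`** — synthetic labeled scenes: rectangular plot
  mosaics, per-class 6-band reflectance signatures with within-field noise,
  box-averaged mixed pixels at plot boundaries, and per-band gain/offset
  shifts emulating acquisition differences between years.
- **`cropseg.features`** — the 8-channel network input (bands
  B02/B03/B04/B05/B06/B08 + NDVI + a red-edge normalized-difference index;
  EVI available as an alternative eighth channel) with per-channel z-score
  normalization and reusable statistics.
- **`cropseg.tiling`** — 6:4 spatial train/test split, random 256×256
  training crops (800 per scene, 600 train / 200 validation by default),
  and the edge-ignoring test grid: overlapping tiles whose context-poor
  borders are replaced by the central windows of neighbouring tiles, both
  when tiling and when stitching predictions.
- **`cropseg.attnseg`** — channel attention (global avg/max pooling through
  a shared two-layer perceptron), spatial attention (channel-wise avg/max
  pooling + 7×7 convolution), their sequential composition, and the
  five-stage encoder–decoder network with attention blocks between the
  convolutions and the pooling of every encoder stage and on every skip
  connection. For the default widths a 256×256×8 input produces the stage
  dimensions 128×128×64 → 64×64×128 → 32×32×256 → 16×16×512 → 8×8×512 and
  decoder concatenations 1024 / 768 / 384 / 192 / 256 channels.
- **`cropseg.train`** — Adam (batch 8, weight decay 0.001, up to 150
  epochs), reduce-on-plateau learning rate, early stopping after 30 epochs
  without training-accuracy improvement, best-checkpoint restore, and a
  batch-norm recalibration pass so short runs predict correctly in
  inference mode. No data augmentation.
- **`cropseg.evaluate`** — confusion-matrix metrics (overall accuracy,
  per-class and mean IoU, kappa), misclassification maps with a
  boundary-error diagnostic, t-SNE embeddings of raw vs. learned features
  with silhouette scores, and the cross-domain (year-shift) transfer
  harness.

The network runs on a small NumPy reverse-mode autodiff engine
(`cropseg.nn`) — no deep-learning framework is required.

## CLI

```bash
# synthetic labeled scene (+ *_labels raster and sidecar JSON)
cropseg generate --height 512 --width 512 --seed 1 --out scene.tif

# 8-channel normalized feature stack + statistics for reuse on test data
cropseg features --scene scene.tif --index rededge \
    --out stack.npy --stats-out stats.json

# training crops / edge-ignoring test tiles
cropseg tile train --stack stack.npy --labels scene_labels.tif \
    --size 256 --count 800 --train-count 600 --out tiles/

# architecture audit: per-stage shape table
cropseg model build --summary

# training, evaluation, cross-domain transfer
cropseg train --tiles tiles/ --out run/
cropseg evaluate --pred pred.npy --truth truth.npy --classes 3
cropseg transfer --model run/model.npz --stats stats.json \
    --scene other_year.tif --labels other_year_labels.tif
```

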