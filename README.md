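# macn — multi-magnification attention segmentation of bile-duct-like structures

`macn` implements a dual-magnification attention convolutional network
(MACN) for semantic segmentation of thin annular structures — bile ducts
in Masson-stained liver histology being the motivating case — together
with the full surrounding pipeline: bilinear image pyramids, co-centered
patch-pair extraction with a structure retention filter, focal-loss
training, a confusion-count metric suite, structural ablations, stitched
whole-image inference, and a seedable synthetic histology-like benchmark
with exact ground truth.

It is aimed at computational-pathology researchers who want a compact,
fully inspectable reference implementation of multi-magnification
attention fusion that runs on a plain CPU: the network is built on a
small NumPy reverse-mode autodiff engine shipped in `macn.nn`, so there
is no deep-learning-framework dependency and every operation (convolution,
batch norm, bilinear resampling) is a few lines of auditable NumPy.

## The model

A whole-slide-style image is downsampled 2× per pyramid level by bilinear
interpolation. A 256×256 window cut at high magnification (the prediction
target) is paired with the 256×256 window at half magnification centered
on the same tissue location, whose field of view is 4× larger. Two
independent residual encoders followed by DenseASPP blocks produce
bottleneck features H (high) and L (low). L is aligned by cropping its
central 1/r fraction (r = 2) and bilinearly resizing back — after which
position (i, j) in both maps sees the same tissue — and fused by a
sigmoid attention gate:

    Y = (1 + σ(L)) · H

Since σ(L) ∈ (0, 1), the wide-field branch can only enhance the target
features: for H ≥ 0, H ≤ Y ≤ 2H elementwise, and Y = 0 wherever H = 0.
A decoder upsamples Y, merges a projected low-level skip, and emits
per-pixel two-class softmax probabilities.

Training minimises the binary focal loss

    FL = mean[(1 − pt)^γ (−log pt)],  pt = p if y = 1 else 1 − p

(γ = 0 is exactly cross-entropy; default γ = 1). Evaluation reports
micro-averaged precision, recall, F1 = 2PR/(P+R) and
IoU = TP/(TP+FP+FN) = F1/(2−F1).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Train on a small synthetic dataset (case-level split; scenes contain
duct annuli, thicker-walled artery distractors in a similar hue,
fibrosis texture and noise) and evaluate on held-out scenes:

```python
import json
from macn.losses_metrics import LossConfig
from macn.macn_model import ModelConfig
from macn.pipeline import TrainConfig, evaluate, split_dataset, train
from macn.synthetic_data import generate_dataset

scenes, manifest = generate_dataset(8, seed=1)
train_pairs, test_pairs = split_dataset(scenes, manifest)
print(f"{len(train_pairs)} training / {len(test_pairs)} test patch pairs")

config = TrainConfig(model=ModelConfig(seed=1),
                     loss=LossConfig(kind="focal", gamma=1.0),
                     batch_size=4, max_steps=150, seed=1)
model, log = train(config, train_pairs)
print(f"focal loss: {log[0]['loss']:.3f} (step 0) -> {log[-1]['loss']:.4f} (step 149)")

metrics, _ = evaluate(model, test_pairs)
print(json.dumps({k: round(v, 3) for k, v in metrics.as_dict().items()
                  if isinstance(v, float)}, indent=2))
```

Output (a couple of minutes on one CPU core):

```
14 training / 16 test patch pairs
focal loss: 0.323 (step 0) -> 0.0035 (step 149)
{
  "precision": 0.891,
  "recall": 0.798,
  "f1": 0.842,
  "iou": 0.727
}
```

The loss drops two orders of magnitude and the held-out IoU of ~0.73
means the predicted duct walls overlap the true annuli well; precision >
recall indicates the model rarely fires on the artery distractors but
misses some thin wall pixels. (The retention filter keeps only patches
containing annotated structures, which is why 8 scenes yield 30 pairs.)

The same pipeline is scriptable from the shell:

```sh
macn generate-data --n-scenes 20 --seed 1 --out data/
macn train --data data/ --out run/ --seed 1
macn evaluate --checkpoint run/model.npz --data data/
macn ablate --data data/ --out ablation.csv --seed 1
macn predict --checkpoint run/model.npz --image data/scene_000.png --out mask.png
```

`macn ablate` retrains one variant per structural axis — attention vs
concatenation fusion, central crop vs none, DenseASPP vs ASPP, decoder
on/off, and the focal γ ∈ {0..4} sweep — from the same seed and data and
writes one precision/recall/F1/IoU row per variant.

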