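# Methods

## Problem and model

Bile ducts are thin annular epithelial structures that mark portal areas
in Masson-stained liver sections. They are hard to segment from a single
field of view: high magnification resolves the duct wall's cell-level
texture but loses surrounding context, while low magnification shows the
portal neighborhood but blurs the wall. The package implements a
dual-magnification attention network (MACN) over *co-centered patch
pairs*: a high-magnification 256×256 patch (the prediction target) and
the 256×256 patch at half magnification centered on the same tissue
location, whose field of view is four times larger.

Each patch passes through its own residual encoder (the branches share no
parameters), followed by a densely connected atrous pyramid block
(DenseASPP) that enlarges the receptive field at constant resolution. The
low-magnification bottleneck is then geometrically aligned: its central
1/r fraction (r = magnification ratio, 2 by default) covers exactly the
high patch's tissue, so that region is cropped and bilinearly resized
back to the full feature grid. Fusion is a sigmoid attention gate

    Y = (1 + σ(L)) · H

with H the high-magnification and L the aligned low-magnification
features. Because σ(L) ∈ (0, 1), the context branch can only *enhance*
the target features: for H ≥ 0 (post-ReLU), H ≤ Y ≤ 2H elementwise, and
Y = 0 wherever H = 0. This bound is what keeps the wide-field branch an
assistant rather than a competing predictor, and it is property-tested.
A concatenation + 1×1-convolution fusion is available as the ablation
alternative.

A light decoder bilinearly upsamples the fused bottleneck in ×2 steps to
the factor-4 grid, concatenates a 1×1-projected low-level skip from the
high-magnification encoder, merges with two 3×3 convolutions, classifies,
and bilinearly upsamples to per-pixel two-class logits at 256×256. With
the decoder disabled, a 1×1 classifier and a single bilinear upsample
replace it.

## Losses and metrics

Training minimises the binary focal loss on the per-pixel probability of
the true class pt:

    FL = mean[ (1 − pt)^γ · (−log pt) ],   pt = p if y=1 else 1−p

γ = 0 recovers cross-entropy exactly; at pt = 0.9 and γ = 2 a pixel
contributes 100× less than under cross-entropy. The loss is applied
symmetrically to both classes (background pixels must contribute, or the
all-background solution is a fixed point under extreme class imbalance).
Probabilities are clamped at ε = 1e−7 before the logarithm. The default
γ is 1; γ = 2 and the full sweep 0–4 are exposed for the ablation.

Evaluation uses pixelwise confusion counts and precision, recall,
F1 = 2PR/(P+R) and IoU = TP/(TP+FP+FN); TN-based scores are omitted as
uninformative under heavy imbalance. IoU = F1/(2−F1) is an exact identity
on pooled counts and is enforced as a property test. Dataset scores are
micro-averaged (counts pooled over patches before division); macro
averaging is available. Zero denominators return 0 and set a `degenerate`
flag; an `empty_agreement` policy flag scores an empty prediction of an
empty ground truth as 1 instead.

## Patch geometry

Pyramids downsample 2× per level by separable bilinear interpolation with
half-pixel sample centers and edge clamping (ceil division on odd sizes).
The same linear operator backs the differentiable resize inside the
network, so image-space and feature-space geometry share one convention;
it is cross-checked against `skimage.transform.resize(order=1)` in the
tests. Windows are 0-based, (row, col), half-open. The dataset-building
stride defaults to the window (non-overlapping tiles); stitched inference
defaults to half-window overlap with per-pixel probability averaging
(bounded and order-independent) and argmax ties breaking to background.
Low-magnification windows that extend past the image are
reflection-padded to avoid out-of-distribution borders. A patch pair is
retained for training iff its high-patch footprint contains at least
`min_pixels` (default 1) annotated pixels of any structure class (duct,
artery, vein, fibrosis); this mirrors the usual practice of discarding
plain-parenchyma tiles to curb the background fraction.

## Synthetic benchmark

The generator renders 512×512 base-magnification scenes: 3 bile-duct
annuli (lumen + wall; inner radius 8–20 px, wall 6–12 px — roughly one to
two epithelial cell layers at a 40×-like scale), 2 artery-like annuli
with thicker walls (inner 16–30 px, wall 12–20 px) in a deliberately
similar hue so they act as confusable distractors, a low-frequency
blue-green collagen field (amplitude 0.35, thresholded for the fibrosis
mask), and additive Gaussian noise (σ = 6 of 255). Structures are placed
by rejection sampling with a non-overlap constraint; overcrowded
specifications raise. Foreground prevalence is ~0.3–1% of pixels, the
imbalance regime that motivates focal loss. Per-scene seeds derive from
the master seed through `numpy.random.SeedSequence([master, index])`, so
datasets are bit-reproducible and order-independent; the train/test split
is by scene (case-level), never by patch.

What the generator does *not* emulate: stain variability and fading,
scanner color shifts, blur/fold artifacts, duct clustering and the long
tail of duct morphologies, tissue boundaries. Passing the end-to-end test
therefore shows the architecture, geometry, losses and training loop are
correct and that the model can exploit the multi-magnification signal —
not that clinical-grade accuracy would transfer to hospital slides.

## Numerical and design choices

- **Tensor framework.** The network runs on a compact NumPy reverse-mode
  autodiff engine written for this package (`macn.nn`): broadcasting
  arithmetic, strided/dilated convolution (shift-and-add formulation —
  one small GEMM per kernel tap, chosen after measuring it against
  im2col on one CPU core), batch normalisation, separable bilinear
  resampling as an explicit linear operator, log-softmax, Adam/SGD.
  Gradients are verified against central finite differences, and the
  convolution against `scipy.signal.correlate2d`.
- **Backbone.** A width-configurable residual network (stem /2, average
  pool /4, one residual stage per factor) stands in for a full
  ResNet-101: default stem width 8 (multiplier 0.5), output stride 16
  (8 available via dilation). This desk-scale also sets the training
  defaults: Adam, lr 1e−3, batch 4–8, a fixed step budget (200 steps for
  the benchmark run), He initialisation, all seeded from the config.
- **DenseASPP rates** default to (3, 6, 12, 18, 24) per the original
  design; rates ≥ the bottleneck size are clamped with a warning (at
  256/16 = 16² the top rates clamp to 15). The parallel (non-dense) ASPP
  ablation uses the same rates.
- **Both branches** get a pyramid block (symmetric processing); the
  decoder skip comes from the high-magnification branch only, at the
  factor-4 stage, following the DeepLabv3+ convention.
- **Upsampling path:** at output stride 16 the fused map is upsampled ×2
  twice to reach the factor-4 skip grid; at output stride 8, once.
- **Binarisation** is argmax over the two classes (threshold 0.5), ties
  to background.
- **Degenerate inputs:** odd feature sizes reject central cropping;
  images smaller than the window yield an empty patch list with a
  warning; missing annotations retain all patches with a warning;
  non-finite training loss aborts with a diagnostic.

## Known limitations

- The reduced backbone is randomly initialised; no pretrained weights are
  used, so absolute clinical performance figures are out of reach by
  design.
- Only two magnification branches and two classes are supported.
- Stitched whole-image inference is a convenience; the training/eval
  protocol is patch-level.
- The synthetic ablation table reproduces the *structure* of the variant
  comparison (which axes exist and that they train), not published effect
  sizes; at desk scale the variants' scores are close to one another.
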