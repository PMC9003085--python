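"""Training, evaluation, ablation and whole-image stitched inference.

Training optimises the focal (or cross-entropy) objective over co-centered
patch pairs with Adam at a fixed step budget; all randomness flows from a
single seed, so runs are reproducible. Evaluation micro-averages pixel
confusion counts over all test patches. The ablation driver retrains the
network once per structural variant — fusion mode, central crop, pyramid
block, decoder, and the focal γ sweep — from the same seed and data, and
reports one precision/recall/F1/IoU row per variant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .losses_metrics import (LossConfig, SegMetrics, compute_metrics,
                             confusion_counts)
from .macn_model import MACN, ModelConfig, preprocess
from .nn import Adam, SGD, Tensor, log_softmax
from .pyramid_patches import PatchPair, build_pyramid, extract_patch_pairs, \
    filter_patches
from .synthetic_data import Scene

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "AblationPlan", "default_ablation_plan",
           "focal_loss_logits", "scene_to_pairs", "split_dataset",
           "train", "evaluate", "ablate", "predict_stitch"]


@dataclass(frozen=True)
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer_name: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_steps: int = 300
    eval_every: int = 100
    seed: int = 0
    dataset_dir: str | None = None
    checkpoint_path: str | None = None
    report_path: str | None = None

    # -- round-trippable config file ------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TrainConfig":
        raw = dict(raw)
        mc = dict(raw.pop("model", {}))
        if "aspp_rates" in mc:
            mc["aspp_rates"] = tuple(mc["aspp_rates"])
        lc = dict(raw.pop("loss", {}))
        if lc.get("class_weights") is not None:
            lc["class_weights"] = tuple(lc["class_weights"])
        return cls(model=ModelConfig(**mc), loss=LossConfig(**lc), **raw)


# -- differentiable loss -------------------------------------------------------


def focal_loss_logits(logits: Tensor, labels: np.ndarray,
                      gamma: float = 1.0,
                      class_weights: tuple[float, float] | None = None) -> Tensor:
    """Focal loss on (B, 2, H, W) logits against (B, H, W) binary labels,
    differentiable through the autodiff graph; γ=0 is cross-entropy."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    onehot = np.stack([labels == 0, labels == 1], axis=1).astype(np.float32)
    log_pt = (log_softmax(logits, axis=1) * onehot).sum(axis=1)
    nll = -1.0 * log_pt
    if gamma > 0:
        loss_map = ((1.0 - log_pt.exp()) ** float(gamma)) * nll
    else:
        loss_map = nll
    if class_weights is not None:
        wmap = np.where(labels == 1, class_weights[1],
                        class_weights[0]).astype(np.float32)
        loss_map = loss_map * wmap
    return loss_map.mean()


# -- data plumbing -------------------------------------------------------------


def scene_to_pairs(scene: Scene, high_level: int = 0, low_level: int = 1,
                   window: int = 256, stride: int | None = None,
                   min_pixels: int = 1) -> list[PatchPair]:
    """Pyramid + co-centered extraction + structure retention filter for
    one synthetic scene."""
    pyramid = build_pyramid(scene.image, low_level + 1)
    pairs = extract_patch_pairs(pyramid, high_level, low_level,
                                window=window, stride=stride,
                                mask=scene.duct_mask)
    retained, _ = filter_patches(pairs, scene.structure_masks,
                                 min_pixels=min_pixels, window=window)
    return retained


def split_dataset(scenes: list[Scene], manifest: dict,
                  **pair_kwargs) -> tuple[list[PatchPair], list[PatchPair]]:
    """Scene-level (case-level) split into train/test patch pair lists."""
    train_pairs, test_pairs = [], []
    for i in manifest["train_scenes"]:
        train_pairs.extend(scene_to_pairs(scenes[i], **pair_kwargs))
    for i in manifest["test_scenes"]:
        test_pairs.extend(scene_to_pairs(scenes[i], **pair_kwargs))
    return train_pairs, test_pairs


def _batchify(pairs: list[PatchPair], idx: np.ndarray):
    high = np.concatenate([preprocess(pairs[i].high_patch) for i in idx])
    low = np.concatenate([preprocess(pairs[i].low_patch) for i in idx])
    labels = np.stack([np.asarray(pairs[i].mask_patch, dtype=np.int64)
                       for i in idx])
    return high, low, labels


# -- training -------------------------------------------------------------------


def train(config: TrainConfig, train_pairs: list[PatchPair],
          val_pairs: list[PatchPair] | None = None,
          log_path: str | Path | None = None) -> tuple[MACN, list[dict]]:
    """Optimise MACN on patch pairs; returns the model and the JSON-lines
    style log (one dict per step, plus periodic validation metrics)."""
    if not train_pairs:
        raise ValueError("empty training set")
    for p in train_pairs:
        if p.mask_patch is None:
            raise ValueError("training pairs need mask_patch ground truth")
    model = MACN(replace(config.model, seed=config.seed))
    params = model.parameters()
    if config.optimizer_name == "adam":
        opt = Adam(params, lr=config.learning_rate)
    elif config.optimizer_name == "sgd":
        opt = SGD(params, lr=config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer_name!r}")

    rng = np.random.default_rng(config.seed)
    gamma = config.loss.gamma if config.loss.kind == "focal" else 0.0
    log: list[dict] = []
    log_fh = open(log_path, "a") if log_path else None
    try:
        for step in range(config.max_steps):
            idx = rng.choice(len(train_pairs),
                             size=min(config.batch_size, len(train_pairs)),
                             replace=False)
            high, low, labels = _batchify(train_pairs, idx)
            model.train()
            logits = model.forward_logits(high, low)
            loss = focal_loss_logits(logits, labels, gamma=gamma,
                                     class_weights=config.loss.class_weights)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at step {step}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            entry = {"step": step, "loss": loss_val}
            if val_pairs and config.eval_every and \
                    (step + 1) % config.eval_every == 0:
                metrics, _ = evaluate(model, val_pairs)
                entry["val"] = metrics.as_dict()
            log.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
    finally:
        if log_fh:
            log_fh.close()
    model.eval()
    return model, log


# -- evaluation -----------------------------------------------------------------


def evaluate(model: MACN, pairs: list[PatchPair],
             csv_path: str | Path | None = None,
             empty_agreement: bool = False) -> tuple[SegMetrics, pd.DataFrame]:
    """Micro-averaged segmentation metrics over patch pairs, plus a
    per-patch row table (from whose pooled counts the aggregate is exactly
    recomputable)."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    model.eval()
    rows = []
    pooled = np.zeros(4, dtype=np.int64)
    for i, pair in enumerate(pairs):
        if pair.mask_patch is None:
            raise ValueError("evaluation pairs need mask_patch ground truth")
        probs = model.forward(pair)
        pred = (probs[0, 1] > probs[0, 0]).astype(np.uint8)  # tie → background
        counts = confusion_counts(pred, pair.mask_patch)
        pooled += counts
        m = compute_metrics(counts, empty_agreement=empty_agreement)
        rows.append({"patch": i, "center_row": pair.center_base[0],
                     "center_col": pair.center_base[1], **m.as_dict()})
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    return compute_metrics(tuple(pooled), empty_agreement=empty_agreement), df


# -- ablation --------------------------------------------------------------------


@dataclass
class AblationPlan:
    """Named deltas applied to the base configuration, one per variant.

    A valid plan covers the five structural axes: fusion mode,
    crop mode, pyramid block, decoder, and focal γ ∈ {0,...,4}.
    """

    variants: list[tuple[str, dict]]

    def validate(self) -> None:
        keys = [set(delta) for _, delta in self.variants]
        for axis in ("fusion_mode", "crop_mode", "aspp_mode", "decoder_enabled"):
            if not any(axis in k for k in keys):
                raise ValueError(f"plan misses ablation axis {axis!r}")
        gammas = {delta["focal_gamma"] for _, delta in self.variants
                  if "focal_gamma" in delta}
        if not {0, 1, 2, 3, 4} <= gammas:
            raise ValueError("plan must sweep focal_gamma over 0..4")


def default_ablation_plan() -> AblationPlan:
    variants = [
        ("attention (base)", {}),
        ("concatenation", {"fusion_mode": "concatenation"}),
        ("without_crop", {"crop_mode": "none"}),
        ("aspp", {"aspp_mode": "aspp"}),
        ("without_decoder", {"decoder_enabled": False}),
    ]
    variants += [(f"gamma_{g}", {"focal_gamma": g}) for g in range(5)]
    return AblationPlan(variants)


def _apply_delta(base: TrainConfig, delta: dict) -> TrainConfig:
    model_fields = set(ModelConfig.__dataclass_fields__)
    mc = {k: v for k, v in delta.items() if k in model_fields}
    cfg = replace(base, model=replace(base.model, **mc)) if mc else base
    if "focal_gamma" in delta:
        g = float(delta["focal_gamma"])
        cfg = replace(cfg, model=replace(cfg.model, focal_gamma=g),
                      loss=replace(cfg.loss, gamma=g))
    return cfg


def ablate(plan: AblationPlan, base: TrainConfig,
           train_pairs: list[PatchPair], test_pairs: list[PatchPair],
           csv_path: str | Path | None = None) -> pd.DataFrame:
    """Train/evaluate every variant from the same seed and data; one row
    per variant with precision/recall/F1/IoU. Identical resolved configs
    are trained once and reused (cache keyed on the resolved config)."""
    plan.validate()
    cache: dict[str, tuple[SegMetrics, pd.DataFrame]] = {}
    rows = []
    for name, delta in plan.variants:
        cfg = _apply_delta(base, delta)
        key = json.dumps(asdict(cfg), sort_keys=True)
        if key not in cache:
            model, _ = train(cfg, train_pairs)
            cache[key] = evaluate(model, test_pairs)
        metrics, _ = cache[key]
        rows.append({"variant": name,
                     "precision": metrics.precision, "recall": metrics.recall,
                     "f1": metrics.f1, "iou": metrics.iou,
                     "tp": metrics.tp, "fp": metrics.fp,
                     "fn": metrics.fn, "tn": metrics.tn})
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df


# -- stitched whole-image inference ----------------------------------------------


def predict_stitch(model: MACN, image: np.ndarray, n_levels: int = 2,
                   high_level: int = 0, low_level: int = 1,
                   window: int = 256, stride: int | None = None) -> np.ndarray:
    """Tile a full image into co-centered pairs, average per-pixel class
    probabilities over overlapping tiles, and argmax to a full-resolution
    binary mask (ties break to background)."""
    if image.shape[0] < window or image.shape[1] < window:
        raise ValueError(
            f"image {image.shape[:2]} smaller than the {window} px window")
    stride = window // 2 if stride is None else stride
    pyramid = build_pyramid(image, max(n_levels, low_level + 1))
    hi = pyramid.levels[high_level]
    h, w = hi.shape[:2]

    def origins(extent):
        out = list(range(0, extent - window + 1, stride))
        if out[-1] != extent - window:  # cover the remainder strip
            out.append(extent - window)
        return out

    model.eval()
    acc = np.zeros((2, h, w), dtype=np.float64)
    hits = np.zeros((h, w), dtype=np.int32)
    lo = pyramid.levels[low_level]
    half = window // 2
    lo_scale = 2**low_level
    hi_scale = 2**high_level
    from .pyramid_patches import _reflect_window
    for r0 in origins(h):
        for c0 in origins(w):
            center_base = ((r0 + half) * hi_scale, (c0 + half) * hi_scale)
            lo_r = int(round(center_base[0] / lo_scale - half))
            lo_c = int(round(center_base[1] / lo_scale - half))
            high = preprocess(hi[r0:r0 + window, c0:c0 + window])
            low = preprocess(_reflect_window(lo, lo_r, lo_c, window))
            probs = model.forward(high, low)[0]
            acc[:, r0:r0 + window, c0:c0 + window] += probs
            hits[r0:r0 + window, c0:c0 + window] += 1
    acc /= hits
    return (acc[1] > acc[0]).astype(np.uint8)
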