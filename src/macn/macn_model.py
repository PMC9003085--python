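"""Multi-magnification attention convolutional network (MACN).

Two parallel residual encoders process a co-centered high-magnification
(target) and low-magnification (context) patch. After an atrous spatial
pyramid block on each bottleneck, the low-magnification feature map is
aligned to the high one by cropping its central 1/r fraction and
bilinearly resizing back (r = magnification ratio), then fused by a
sigmoid attention gate:

    Y = (1 + sigmoid(L)) * H

so the context branch can only *enhance* the target features — for
nonnegative H the fused map lies between H and 2H elementwise. A light
decoder upsamples the fused map, concatenates a projected low-level skip
from the high-magnification encoder, and merges with convolutions before
the final per-pixel two-class softmax.

The desk-scale backbone is a width-configurable residual network with the
conventional stem + three strided stages (output stride 8 or 16); an
ImageNet-scale ResNet-101 backbone is out of scope here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, as_tensor, avg_pool2d, bilinear_resize, concat, \
    log_softmax
from .pyramid_patches import PatchPair

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "AttentionOutput", "MACN",
           "central_crop_align", "attention_fuse", "preprocess",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; every ablation axis is a field."""

    backbone: str = "reduced"                # only the reduced backbone is built
    backbone_width_multiplier: float = 0.5   # stem width = 16 * multiplier
    output_stride: int = 16                  # bottleneck downsampling: 8 or 16
    aspp_mode: str = "dense_aspp"            # dense_aspp | aspp | none
    fusion_mode: str = "attention"           # attention | concatenation
    crop_mode: str = "central_crop"          # central_crop | none
    decoder_enabled: bool = True
    magnification_ratio: int = 2
    num_classes: int = 2
    focal_gamma: float = 1.0
    aspp_rates: tuple[int, ...] = (3, 6, 12, 18, 24)
    input_size: int = 256
    seed: int = 0
    bias_free: bool = False                  # diagnostic: no additive terms anywhere

    def __post_init__(self):
        if self.backbone != "reduced":
            raise ValueError("only the reduced backbone is available")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if self.aspp_mode not in ("dense_aspp", "aspp", "none"):
            raise ValueError(f"unknown aspp_mode {self.aspp_mode!r}")
        if self.fusion_mode not in ("attention", "concatenation"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.crop_mode not in ("central_crop", "none"):
            raise ValueError(f"unknown crop_mode {self.crop_mode!r}")
        if self.magnification_ratio < 2 or \
                self.magnification_ratio & (self.magnification_ratio - 1):
            raise ValueError("magnification_ratio must be a power of two ≥ 2")

    @property
    def width(self) -> int:
        return max(4, int(round(16 * self.backbone_width_multiplier)))


@dataclass
class AttentionOutput:
    fused: Tensor   # (1 + gate) * high
    gate: Tensor    # sigmoid of the aligned low-magnification features


def preprocess(patch: np.ndarray) -> np.ndarray:
    """uint8 HWC (or BHWC) RGB patch → float32 NCHW in [-1, 1]."""
    x = np.asarray(patch, dtype=np.float32) / 255.0
    x = (x - 0.5) * 2.0
    if x.ndim == 3:
        x = x[None]
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# -- functional pieces ---------------------------------------------------------


def central_crop_align(low_feat: Tensor | np.ndarray, ratio: int) -> Tensor:
    """Crop the central 1/ratio fraction of a feature map and bilinearly
    resize back, so each position matches the field of view of the
    co-centered high-magnification features (for ratio 2 and size S the
    crop is rows/cols [S/4, 3S/4))."""
    x = as_tensor(low_feat)
    if x.ndim != 4:
        raise ValueError("expected a (B, C, H, W) feature map")
    _, _, h, w = x.shape
    if h % ratio or w % ratio or (h * (ratio - 1)) % (2 * ratio) \
            or (w * (ratio - 1)) % (2 * ratio):
        raise ValueError(
            f"spatial size ({h}, {w}) not divisible for central crop at "
            f"ratio {ratio}")
    rs = h * (ratio - 1) // (2 * ratio)
    cs = w * (ratio - 1) // (2 * ratio)
    cropped = x.slice2d(rs, rs + h // ratio, cs, cs + w // ratio)
    return bilinear_resize(cropped, h, w)


def attention_fuse(high_feat: Tensor | np.ndarray,
                   low_feat_aligned: Tensor | np.ndarray) -> AttentionOutput:
    """Sigmoid-gated enhancement Y = (1 + sigmoid(L)) * H.

    The gate lies in (0, 1): the context branch multiplicatively boosts
    (never suppresses or replaces) the target features, and contributes
    nothing where the high-magnification response is zero.
    """
    h = as_tensor(high_feat)
    low = as_tensor(low_feat_aligned)
    if h.shape != low.shape:
        raise ValueError(f"shape mismatch: high {h.shape} vs low {low.shape}")
    gate = low.sigmoid()
    fused = (gate + 1.0) * h
    return AttentionOutput(fused=fused, gate=gate)


# -- building blocks -----------------------------------------------------------


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, rng, stride=1, dilation=1, relu=True):
        super().__init__()
        pad = dilation * (k - 1) // 2
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=pad,
                              dilation=dilation, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.use_relu = relu

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.use_relu else x


class _ResBlock(nn.Module):
    def __init__(self, cin, cout, rng, stride=1, dilation=1):
        super().__init__()
        self.branch = nn.Sequential(
            _ConvBNReLU(cin, cout, 3, rng, stride=stride, dilation=dilation),
            _ConvBNReLU(cout, cout, 3, rng, dilation=dilation, relu=False),
        )
        self.skip = None
        if stride != 1 or cin != cout:
            self.skip = _ConvBNReLU(cin, cout, 1, rng, stride=stride, relu=False)

    def forward(self, x):
        identity = self.skip(x) if self.skip is not None else x
        return (self.branch(x) + identity).relu()


class _Encoder(nn.Module):
    """Reduced residual backbone: strided stem + average pool to factor 4
    (the ResNet stem convention), a residual stage there, then strided
    stages down to the bottleneck at the configured output stride."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        w = config.width
        self.stem = _ConvBNReLU(3, w, 3, rng, stride=2)
        self.stage1 = _ResBlock(w, 2 * w, rng)                  # factor 4
        self.stage2 = _ResBlock(2 * w, 4 * w, rng, stride=2)    # factor 8
        if config.output_stride == 16:
            self.stage3 = _ResBlock(4 * w, 8 * w, rng, stride=2)
        else:  # keep /8 resolution, enlarge the field with dilation instead
            self.stage3 = _ResBlock(4 * w, 8 * w, rng, stride=1, dilation=2)
        self.out_channels = 8 * w
        self.low_level_channels = 2 * w

    def forward(self, x):
        x = avg_pool2d(self.stem(x), 2)
        low_level = self.stage1(x)
        x = self.stage2(low_level)
        return low_level, self.stage3(x)


def _clamped_rates(rates, spatial: int):
    out = []
    for r in rates:
        if r >= spatial:
            logger.warning("dilation rate %d ≥ feature size %d; clamped to %d",
                           r, spatial, spatial - 1)
            r = spatial - 1
        out.append(max(1, r))
    return tuple(out)


class _DenseASPP(nn.Module):
    """Densely connected atrous pyramid: each dilated 3×3 branch consumes
    the concatenation of the input and all previous branch outputs."""

    def __init__(self, cin, config: ModelConfig, rng):
        super().__init__()
        spatial = config.input_size // config.output_stride
        self.rates = _clamped_rates(config.aspp_rates, spatial)
        inter = cin // 2
        growth = cin // 4
        self.branches = []
        cur = cin
        for rate in self.rates:
            self.branches.append(nn.Sequential(
                _ConvBNReLU(cur, inter, 1, rng),
                _ConvBNReLU(inter, growth, 3, rng, dilation=rate),
            ))
            cur += growth
        self.project = _ConvBNReLU(cur, cin, 1, rng)
        self.out_channels = cin

    def forward(self, x):
        feats = [x]
        for branch in self.branches:
            feats.append(branch(concat(feats, axis=1) if len(feats) > 1
                                else feats[0]))
        return self.project(concat(feats, axis=1))


class _ASPP(nn.Module):
    """Parallel (non-dense) dilated branches, concatenated and projected."""

    def __init__(self, cin, config: ModelConfig, rng):
        super().__init__()
        spatial = config.input_size // config.output_stride
        self.rates = _clamped_rates(config.aspp_rates, spatial)
        width = cin // 4
        self.branches = [_ConvBNReLU(cin, width, 1, rng)]
        self.branches += [_ConvBNReLU(cin, width, 3, rng, dilation=r)
                          for r in self.rates]
        self.project = _ConvBNReLU(width * len(self.branches), cin, 1, rng)
        self.out_channels = cin

    def forward(self, x):
        return self.project(concat([b(x) for b in self.branches], axis=1))


class _Identity(nn.Module):
    def __init__(self, cin):
        super().__init__()
        self.out_channels = cin

    def forward(self, x):
        return x


def _make_aspp(cin, config, rng):
    if config.aspp_mode == "dense_aspp":
        return _DenseASPP(cin, config, rng)
    if config.aspp_mode == "aspp":
        return _ASPP(cin, config, rng)
    return _Identity(cin)


class _Decoder(nn.Module):
    """Upsample the fused bottleneck to the factor-4 grid, concatenate the
    projected low-level skip, merge with convolutions, classify, and
    bilinearly upsample to full patch resolution."""

    def __init__(self, cin, low_level_ch, config: ModelConfig, rng):
        super().__init__()
        skip_ch = max(8, cin // 4)
        self.proj = _ConvBNReLU(low_level_ch, skip_ch, 1, rng)
        self.merge = nn.Sequential(
            _ConvBNReLU(cin + skip_ch, cin // 2, 3, rng),
            _ConvBNReLU(cin // 2, cin // 2, 3, rng),
        )
        self.classifier = nn.Conv2d(cin // 2, config.num_classes, 1,
                                    bias=not config.bias_free, rng=rng)
        self.size = config.input_size

    def forward(self, fused, low_level):
        _, _, th, tw = low_level.shape
        while fused.shape[2] < th:  # ×2 bilinear steps up to the skip grid
            fused = bilinear_resize(fused, fused.shape[2] * 2, fused.shape[3] * 2)
        x = concat([fused, self.proj(low_level)], axis=1)
        x = self.merge(x)
        return bilinear_resize(self.classifier(x), self.size, self.size)


class _NoDecoder(nn.Module):
    def __init__(self, cin, config: ModelConfig, rng):
        super().__init__()
        self.classifier = nn.Conv2d(cin, config.num_classes, 1,
                                    bias=not config.bias_free, rng=rng)
        self.size = config.input_size

    def forward(self, fused, low_level):
        return bilinear_resize(self.classifier(fused), self.size, self.size)


# -- the network ----------------------------------------------------------------


class MACN(nn.Module):
    """Dual-branch attention network over co-centered patch pairs."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.high_encoder = _Encoder(config, rng)
        self.low_encoder = _Encoder(config, rng)
        cin = self.high_encoder.out_channels
        self.aspp_high = _make_aspp(cin, config, rng)
        self.aspp_low = _make_aspp(cin, config, rng)
        self.fuse_proj = None
        if config.fusion_mode == "concatenation":
            self.fuse_proj = _ConvBNReLU(2 * cin, cin, 1, rng)
        if config.decoder_enabled:
            self.head = _Decoder(cin, self.high_encoder.low_level_channels,
                                 config, rng)
        else:
            self.head = _NoDecoder(cin, config, rng)

    # -- pieces exposed for inspection ------------------------------------
    def encode(self, patch: Tensor | np.ndarray, branch: str,
               strict: bool = True) -> tuple[Tensor, Tensor]:
        """Run one branch's encoder → (factor-4 low-level features,
        bottleneck at the configured output stride)."""
        x = as_tensor(patch)
        if strict and (x.shape[2] != self.config.input_size
                       or x.shape[3] != self.config.input_size):
            raise ValueError(
                f"expected {self.config.input_size}² input, got "
                f"{x.shape[2]}×{x.shape[3]}")
        if branch == "high":
            return self.high_encoder(x)
        if branch == "low":
            return self.low_encoder(x)
        raise ValueError(f"unknown branch {branch!r}")

    def dense_aspp(self, feature: Tensor | np.ndarray,
                   branch: str = "high") -> Tensor:
        block = self.aspp_high if branch == "high" else self.aspp_low
        return block(as_tensor(feature))

    # -- full forward -------------------------------------------------------
    def forward_logits(self, high: Tensor | np.ndarray,
                       low: Tensor | np.ndarray) -> Tensor:
        skip, h_bot = self.encode(high, "high")
        _, l_bot = self.encode(low, "low")
        h = self.aspp_high(h_bot)
        low_feat = self.aspp_low(l_bot)
        if self.config.crop_mode == "central_crop":
            low_feat = central_crop_align(low_feat, self.config.magnification_ratio)
        if self.config.fusion_mode == "attention":
            fused = attention_fuse(h, low_feat).fused
        else:
            fused = self.fuse_proj(concat([h, low_feat], axis=1))
        return self.head(fused, skip)

    def forward(self, pair_or_high, low=None) -> np.ndarray:
        """Per-pixel class probabilities (B, num_classes, H, W); accepts a
        PatchPair or a pair of preprocessed NCHW arrays."""
        if isinstance(pair_or_high, PatchPair):
            high = preprocess(pair_or_high.high_patch)
            low = preprocess(pair_or_high.low_patch)
        else:
            high = pair_or_high
        logits = self.forward_logits(high, low)
        return np.exp(log_softmax(logits, axis=1).data)


# -- checkpointing -----------------------------------------------------------


def _ckpt_paths(path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    return path, Path(str(path) + ".json")


def save_checkpoint(model: MACN, path: str | Path) -> None:
    """Serialize parameters+buffers to ``<path>.npz`` and the ModelConfig
    to a ``<path>.npz.json`` sidecar."""
    npz_path, json_path = _ckpt_paths(path)
    np.savez(npz_path, **model.state_dict())
    with open(json_path, "w") as fh:
        json.dump(asdict(model.config), fh, indent=2)


def load_checkpoint(path: str | Path) -> MACN:
    """Rebuild a MACN from a checkpoint; the config sidecar drives
    construction and the archive must match it shape-for-shape."""
    npz_path, json_path = _ckpt_paths(path)
    with open(json_path) as fh:
        cfg = json.load(fh)
    cfg["aspp_rates"] = tuple(cfg["aspp_rates"])
    model = MACN(ModelConfig(**cfg))
    with np.load(npz_path) as data:
        model.load_state_dict(dict(data))
    return model
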